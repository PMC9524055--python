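o
a
os
as
um
uma
de
do
da
dos
das
em
no
na
nos
nas
para
com
por
que
não
é
são
foi
ser
este
esta
estes
estas
ele
ela
eles
elas
nós
seu
sua
seus
suas
ao
aos
mais
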