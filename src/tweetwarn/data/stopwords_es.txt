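el
la
los
las
un
una
y
o
de
del
en
para
con
por
que
no
es
son
fue
ser
este
esta
estos
estas
él
ella
ellos
ellas
nosotros
su
sus
al
a
más
se
lo
le
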