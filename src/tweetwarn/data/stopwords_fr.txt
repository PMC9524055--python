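le
la
les
de
des
du
un
une
et
en
pour
avec
dans
sur
par
est
sont
été
être
ce
cette
ces
il
elle
ils
elles
nous
vous
je
tu
son
sa
ses
leur
leurs
au
aux
que
qui
ne
pas
plus
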