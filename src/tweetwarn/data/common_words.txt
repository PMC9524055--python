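the
a
an
and
or
of
in
on
at
to
for
with
from
by
is
are
was
were
be
been
this
that
these
those
it
its
new
more
most
today
now
news
update
updates
situation
monitoring
reported
reports
report
alert
alerts
outbreak
outbreaks
case
cases
confirmed
suspected
death
deaths
virus
disease
epidemic
pandemic
health
public
people
spread
vaccine
vaccination
symptoms
hospital
infection
infected
le
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
nouveaux
nouvelles
cas
signalés
signalée
épidémie
alerte
suivi
point
plus
em
no
na
os
as
um
uma
para
com
por
surto
casos
novos
relatado
relatados
atualização
sobre
mais
acompanhando
el
los
las
y
o
del
brote
nuevos
reportado
reportados
actualización
más
siguiendo
están
hay
hoy
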