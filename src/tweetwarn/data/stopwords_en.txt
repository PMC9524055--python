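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
not
no
as
i
you
he
she
we
they
his
her
their
our
your
what
which
who
will
would
can
could
just
like
about
over
under
after
before
between
all
any
some
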