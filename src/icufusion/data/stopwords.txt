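a
an
and
are
as
at
be
been
but
by
for
from
had
has
have
he
her
his
i
if
in
into
is
it
its
no
not
of
on
or
our
s
she
so
t
that
the
their
then
there
these
they
this
to
was
we
were
which
who
will
with
would
you
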