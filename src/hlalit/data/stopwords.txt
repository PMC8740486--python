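a
an
the
and
or
but
if
of
in
on
at
by
for
with
from
to
into
onto
as
is
are
was
were
be
been
being
am
do
does
did
have
has
had
having
this
that
these
those
it
its
they
them
their
we
our
us
you
your
he
she
his
her
i
me
my
which
who
whom
whose
what
when
where
why
how
all
each
both
few
other
some
such
than
then
there
here
so
too
can
will
just
about
between
among
during
before
after
above
below
up
down
out
over
under
again
once
per
via
within
without
also
however
moreover
thus
therefore
whereas
while
because
since
although
et
al
etc
respectively
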