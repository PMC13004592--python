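# Pinned English stop-word list (lemma-form where applicable, since
# stop-word removal runs after lemmatization in this pipeline).
# One token per line; '#' starts a comment; blank lines ignored.
a
about
above
after
again
against
all
also
although
among
an
and
any
are
as
at
be
because
before
below
between
both
but
by
can
cannot
could
do
down
during
each
either
else
few
for
from
further
have
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
it
its
itself
just
may
me
might
more
most
must
my
myself
neither
no
nor
not
now
of
off
on
once
only
or
other
ought
our
ours
ourselves
out
over
own
same
shall
she
should
so
some
such
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
upon
us
very
we
what
when
where
which
while
who
whom
whose
why
will
with
within
without
would
you
your
yours
yourself
yourselves
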