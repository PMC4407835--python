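# English function-word stoplist used when folding raw tokens into vectors.
a
about
above
after
again
against
all
also
although
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
despite
did
do
does
doing
down
during
each
either
else
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
however
i
if
in
into
is
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
per
same
shall
she
should
since
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
though
through
to
too
under
unless
until
up
upon
us
very
was
we
were
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
yet
you
your
yours
yourself
yourselves
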