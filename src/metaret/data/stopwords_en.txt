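a
about
above
across
after
again
against
all
almost
along
already
also
although
always
am
among
an
and
another
any
anyone
anything
anywhere
are
as
at
be
became
because
become
becomes
been
before
being
below
between
beyond
both
but
by
can
cannot
could
did
do
does
doing
done
down
during
each
either
else
enough
etc
ever
every
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
least
less
many
may
me
might
more
most
much
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
often
on
once
only
onto
or
other
others
our
ours
ourselves
out
over
own
per
rather
same
she
should
since
so
some
something
sometimes
somewhere
still
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
thus
to
together
too
toward
towards
under
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
whether
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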