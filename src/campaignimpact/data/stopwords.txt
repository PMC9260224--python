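a
about
after
again
all
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
but
by
can
could
did
do
does
down
for
from
had
has
have
he
him
his
how
i
if
in
into
is
it
its
just
me
more
most
my
no
not
now
of
on
only
or
other
our
out
over
rt
so
some
such
than
that
the
their
them
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
up
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
why
will
with
would
you
your
amp
im
dont
u
via
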