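# Minimal English stop-word list used by the tokenizer.
a
about
above
after
again
all
also
among
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
between
both
but
by
can
could
did
do
does
during
each
few
for
from
further
had
has
have
here
how
however
if
in
into
is
it
its
may
might
more
most
no
nor
not
of
on
once
only
or
other
our
over
own
same
should
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
under
until
up
upon
was
we
were
what
when
where
which
while
who
whose
why
will
with
within
without
would
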