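a
an
the
and
or
but
of
in
on
at
to
for
from
by
with
without
as
is
are
was
were
be
been
being
has
have
had
this
that
these
those
it
its
his
her
their
which
who
whom
whose
what
when
where
while
also
such
than
then
there
may
might
can
could
will
would
shall
should
not
no
into
onto
through
during
between
among
over
under
about
other
some
any
each
per
via
most
more
both
if
so
do
does
did
done
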