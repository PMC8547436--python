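"""Exception hierarchy for npdiv.

Every operation that can fail on malformed input raises a subclass of
:class:`NPDivError`, so callers can catch package errors without masking
programming bugs.
"""


class NPDivError(Exception):
    """Base class for all npdiv errors."""


class InfeasibleConfigError(NPDivError):
    """Generator configuration cannot be satisfied (e.g. singleton target
    incompatible with pool sizes, or scaffold peak counts below the
    minimum matched-peak requirement)."""


class MalformedTableError(NPDivError):
    """A feature table violates its format contract (duplicate (m/z, rt)
    rows, non-numeric peak areas, samples missing from metadata)."""


class MalformedMGFError(NPDivError):
    """An MGF block is missing required fields (precursor mass)."""


class EmptySampleError(NPDivError):
    """A sample column has zero total abundance and cannot be normalized."""


class UndefinedDistanceError(NPDivError):
    """Bray-Curtis distance of two all-zero vectors is undefined."""


class DegenerateDataError(NPDivError):
    """Data do not support the requested statistic (all points identical,
    zero variance everywhere, a group equal to the whole sample, too few
    samples)."""
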