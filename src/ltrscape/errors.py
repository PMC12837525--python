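"""Exception hierarchy.

All errors derive from :class:`LtrscapeError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
contract categories used throughout (bad data vs bad parameters vs
model-domain violations).
"""


class LtrscapeError(Exception):
    """Base class for all ltrscape errors."""


class InputError(LtrscapeError, ValueError):
    """Malformed input data (non-ACGT sequence, duplicate ids, missing fields)."""


class ParameterError(LtrscapeError, ValueError):
    """Invalid or infeasible parameter combination."""


class CapacityError(LtrscapeError, ValueError):
    """Requested placements do not fit in the available sequence space."""


class SaturationError(LtrscapeError, ValueError):
    """Divergence beyond the domain of the requested distance model."""


class ContractError(LtrscapeError, ValueError):
    """A documented precondition of an analysis step was violated."""
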