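"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ProtodimerError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class ProtodimerError(Exception):
    """Base class for all package errors."""


class StructureParseError(ProtodimerError):
    """A coordinate file could not be parsed; message names the offending record."""


class TopologyMismatchError(ProtodimerError):
    """Models of an ensemble disagree in chain/residue/atom topology."""


class EmptySelectionError(ProtodimerError):
    """A selection matched no atoms."""


class UnknownRadiusError(ProtodimerError):
    """An atom has no entry in the radii table and no element fallback."""


class NoSideChainError(ProtodimerError):
    """Relative side-chain accessibility requested for a residue without one (Gly)."""


class ShiftTableError(ProtodimerError):
    """A chemical-shift table is malformed (missing column, duplicate residue, ...)."""


class AlignmentError(ProtodimerError):
    """A multiple sequence alignment is invalid (ragged, duplicate ids, ...)."""


class FitError(ProtodimerError):
    """Nonlinear fit failed to converge."""


class NoTransitionError(FitError):
    """Denaturation data contain no detectable two-state transition."""


class ConfigError(ProtodimerError):
    """Run configuration is invalid."""
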