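"""Exception hierarchy for the proxidiff pipeline."""


class ProxidiffError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ProxidiffError):
    """Malformed input table (duplicates, ragged rows, bad tokens, ...)."""


class ConsistencyError(ProxidiffError):
    """Two inputs that must describe the same samples/proteins do not."""


class DegenerateInputError(ProxidiffError):
    """Input is structurally valid but statistically unusable
    (e.g. a sample with zero total intensity)."""


class StateError(ProxidiffError):
    """Operation applied at the wrong pipeline stage."""


class ParameterError(ProxidiffError):
    """Simulation or configuration parameters violate their invariants."""


class StatisticsError(ProxidiffError):
    """A statistical contract is violated (e.g. group size < 2)."""


class ReproducibilityError(ProxidiffError):
    """A stochastic step was requested without a seed."""
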