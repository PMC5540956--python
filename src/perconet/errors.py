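"""Exception hierarchy for perconet."""


class PerconetError(Exception):
    """Base class for all perconet errors."""


class ParameterError(PerconetError, ValueError):
    """Invalid or infeasible parameter combination."""


class ShapeError(PerconetError, ValueError):
    """Input array has the wrong shape or is not symmetric."""


class MembershipError(PerconetError, ValueError):
    """Partition does not cover the network's node set."""


class DegenerateInputError(PerconetError, ValueError):
    """Input is degenerate for the requested operation (e.g. zero-variance
    series, edgeless network)."""


class ConvergenceError(PerconetError, RuntimeError):
    """Iterative procedure failed to converge within its cap."""


class BackendNotAvailableError(PerconetError, RuntimeError):
    """A configured external community-detection backend is unavailable."""
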