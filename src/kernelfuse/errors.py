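"""Exception hierarchy for kernelfuse."""


class KernelFuseError(Exception):
    """Base class for all kernelfuse errors."""


class ValidationError(KernelFuseError, ValueError):
    """Invalid input data (non-finite values, bad labels, bad shapes)."""


class AlignmentError(KernelFuseError, ValueError):
    """Subject orderings of two objects do not match."""


class ConvergenceError(KernelFuseError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""


class ConfigurationError(KernelFuseError, ValueError):
    """Unknown option value (tie rule, preset name, method tag, ...)."""
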