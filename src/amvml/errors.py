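"""Exception hierarchy shared across the package."""


class AmvmlError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(AmvmlError):
    """A disease DAG violates its structural invariants (cycle, dangling node)."""


class DegenerateInputError(AmvmlError):
    """An input is degenerate for the requested operation (e.g. constant
    score matrix for min-max normalization, all-zero association matrix
    for the interaction-profile kernel)."""


class NumericalError(AmvmlError):
    """A non-finite value appeared in an iterate of the solver."""


class ReconciliationError(AmvmlError):
    """Identifiers could not be reconciled across input sources."""


class UndefinedMetricError(AmvmlError):
    """A metric is undefined for the given labels (single class, zero diffs)."""
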