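"""Exception types shared across the package."""


class ConflictError(ValueError):
    """Duplicate keys where uniqueness is required (e.g. two records per cell)."""


class DimensionError(ValueError):
    """Shapes or sizes incompatible with the operation."""


class AlignmentError(ValueError):
    """Identifier sets that should match do not (lists the unmatched ids)."""


class DivergenceError(RuntimeError):
    """Gradient descent produced non-finite values; reduce the learning rate."""
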