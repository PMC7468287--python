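"""Exception hierarchy.

Every reader/operation rejects malformed input with one of these rather
than silently coercing.
"""


class MorphogrowthError(Exception):
    """Base class for all package errors."""


class GridError(MorphogrowthError):
    """Grids are incompatible (shape, spacing or origin mismatch) or degenerate."""


class FormatError(MorphogrowthError):
    """An on-disk artifact does not have the expected layout."""


class DimensionalityError(FormatError):
    """A volume is not 3-D (or a field does not carry 3 components)."""


class IntegrityError(MorphogrowthError):
    """Tabular data violates a uniqueness or sign constraint."""


class DiffeomorphismError(MorphogrowthError):
    """A transformation that must be diffeomorphic has non-positive Jacobian."""


class PipelineError(MorphogrowthError):
    """An orchestration-level failure; carries the stage name and pair index."""

    def __init__(self, stage: str, detail: str, pair: int | None = None):
        self.stage = stage
        self.pair = pair
        where = f"{stage}" if pair is None else f"{stage} (pair {pair})"
        super().__init__(f"pipeline stage failed: {where}: {detail}")
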