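"""Depth normalization (reads per million) and fold changes.

RPM(g, s) = count(g, s) / library_size(s) * 1e6, where library_size is the
total number of uniquely mapping reads of sample *s*. No pseudocount is used
anywhere: a fold change with a zero denominator is the explicit ``n/a``
sentinel, never a finite stand-in. Display rounding is half-up (25.65 ->
"25.7"); threshold comparisons elsewhere use unrounded values except where a
filter explicitly states a rounded reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .expression import ExpressionMatrix, ExpressionError, SampleMetadata


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at *ndigits* decimals (2.05 -> 2.1)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldChange:
    """Ratio of expression between two classes; undefined when the denominator
    is exactly zero (rendered ``n/a``)."""

    numerator_class: str
    denominator_class: str
    value: float | None  # None <=> undefined

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def display(self) -> str:
        if self.value is None:
            return "n/a"
        return f"{round_half_up(self.value, 1):.1f}"

    @property
    def rounded(self) -> float | None:
        """The one-decimal half-up rounding used by the rounded filter bounds."""
        return None if self.value is None else round_half_up(self.value, 1)


def fold_change(a: float, b: float,
                numerator_class: str = "a", denominator_class: str = "b") -> FoldChange:
    """Fold change a/b; undefined iff b == 0 (even when a == 0)."""
    if a < 0 or b < 0:
        raise ExpressionError("fold_change requires non-negative inputs")
    value = None if b == 0 else a / b
    return FoldChange(numerator_class, denominator_class, value)


def rpm_normalize(matrix: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Convert a raw-count matrix to reads per million.

    Each sample column is divided by its metadata library size and scaled by
    1e6. Refuses to run twice (unit must be ``counts``) and requires a
    positive library size for every sample.
    """
    if matrix.unit != "counts":
        raise ExpressionError("matrix is already depth-normalized (unit='rpm')")
    meta.validate_against(matrix)
    out = matrix.values.astype(float).copy()
    for sample in out.columns:
        out[sample] = out[sample] / meta.library_size(sample) * 1e6
    return ExpressionMatrix(out, unit="rpm")
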