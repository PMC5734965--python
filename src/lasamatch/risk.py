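"""Confusion-risk banding and summary statistics for match values.

Match values (percent scale) are banded with inclusive lower edges:
high ≥ 66, medium ≥ 33, low ≥ 1, and ``none`` below 1 (the sub-1% band is
unnamed in common usage; ``none`` is this package's label for it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .coding import ValidationError

__all__ = ["Thresholds", "SummaryStats", "classify", "summarize", "BAND_ORDER"]

BAND_ORDER = ("none", "low", "medium", "high")


@dataclass(frozen=True)
class Thresholds:
    """Inclusive lower band edges on the percent scale."""

    high: float = 66.0
    medium: float = 33.0
    low: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.medium < self.high <= 100):
            raise ValidationError(
                f"thresholds must satisfy 0 < low < medium < high <= 100, "
                f"got {self.low}/{self.medium}/{self.high}"
            )


DEFAULT_THRESHOLDS = Thresholds()


def classify(percent: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Band a match-value percent: high / medium / low / none.

    Bands partition [0, 100] with boundaries inclusive at the lower edge
    of each band, so 66 is high and 33 is medium.
    """
    if not (math.isfinite(percent) and 0.0 <= percent <= 100.0):
        raise ValidationError(f"percent must be in [0, 100], got {percent}")
    if percent >= thresholds.high:
        return "high"
    if percent >= thresholds.medium:
        return "medium"
    if percent >= thresholds.low:
        return "low"
    return "none"


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD and band counts of a scored pair table.

    ``sd_proportion`` is the standard deviation on the 0-1 scale (divide
    percents by 100), the scale on which such tables conventionally print
    their dispersion; ``sd_percent`` is the same number times 100.
    """

    n_scored: int
    n_missing: int
    mean_percent: float
    sd_proportion: float
    band_counts: Mapping[str, int]
    sample_sd: bool = False

    @property
    def sd_percent(self) -> float:
        return 100.0 * self.sd_proportion

    @property
    def n_total(self) -> int:
        return self.n_scored + self.n_missing


def summarize(
    percents: Sequence[float | None],
    printed_bands: Sequence[str | None] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    sample_sd: bool = False,
) -> SummaryStats:
    """Mean, SD and band counts over a column of match-value percents.

    ``None`` entries are missing values: excluded from the mean/SD, banded
    by their ``printed_bands`` label when one is given, otherwise counted
    under ``missing``.  Non-missing entries are banded by ``classify``
    (any printed label is ignored for them).  SD is population (divisor n)
    by default; ``sample_sd=True`` uses n-1.
    """
    if printed_bands is not None and len(printed_bands) != len(percents):
        raise ValidationError("printed_bands must align with percents")
    values = [p for p in percents if p is not None]
    if not values:
        raise ValidationError("no non-missing match values to summarize")
    n = len(values)
    mean = sum(values) / n
    if sample_sd and n < 2:
        raise ValidationError("sample SD needs at least two values")
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1)) if sample_sd else math.sqrt(ss / n)
    counts: dict[str, int] = {}
    for i, p in enumerate(percents):
        if p is not None:
            band = classify(p, thresholds)
        elif printed_bands is not None and printed_bands[i]:
            band = printed_bands[i].lower()
        else:
            band = "missing"
        counts[band] = counts.get(band, 0) + 1
    return SummaryStats(
        n_scored=n,
        n_missing=len(percents) - n,
        mean_percent=mean,
        sd_proportion=sd / 100.0,
        band_counts=counts,
        sample_sd=sample_sd,
    )
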