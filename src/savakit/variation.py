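"""The systematic component of variation (SCV) and auxiliary variation measures.

For k areas with observed counts y_i and indirectly standardized expected
counts e_i, the SCV is

    SCV = (1/k) * ( sum_i (y_i - e_i)^2 / e_i^2  -  sum_i 1/e_i ),

conventionally multiplied by 100.  The second term subtracts the variance
expected from Poisson noise alone, so the statistic estimates 100 times the
variance of the area-level relative risks; it can be negative in small
samples and is reported as computed, without truncation at zero.

Values below 1 are read as no systematic variation, 1-3 minimal, 3-6 medium,
6-10 high, and 10 or more very high.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .standardization import AreaCounts


class VariationLevel(enum.Enum):
    """Five-level reading of an SCV value, ordered from no variation up."""

    no_variation = 0
    minimal = 1
    medium = 2
    high = 3
    very_high = 4

    def __lt__(self, other: "VariationLevel") -> bool:
        return self.value < other.value

    def __le__(self, other: "VariationLevel") -> bool:
        return self.value <= other.value


#: Lower bounds of the classification levels above no_variation.  Intervals
#: are left-closed: [1,3) minimal, [3,6) medium, [6,10) high, [10,inf) very high.
CLASSIFICATION_BOUNDS: tuple[tuple[float, VariationLevel], ...] = (
    (10.0, VariationLevel.very_high),
    (6.0, VariationLevel.high),
    (3.0, VariationLevel.medium),
    (1.0, VariationLevel.minimal),
)


@dataclass(frozen=True)
class ScvResult:
    """SCV point estimate (x100 scale) with CI, classification and inputs."""

    scv: float
    ci_low: float
    ci_high: float
    k: int
    classification: VariationLevel
    per_area_ratio: dict[str, float]
    total_observed: int
    total_expected: float


@dataclass(frozen=True)
class VariationSummary:
    """Descriptive spread of area rates: range, extremal quotient, SD, CV."""

    range: float
    extremal_quotient: float | None  # None when the minimum rate is 0
    sd: float
    cv: float


def _as_arrays(counts, expected=None) -> tuple[np.ndarray, np.ndarray]:
    if expected is not None:
        y = np.asarray(counts, dtype=float)
        e = np.asarray(expected, dtype=float)
    else:
        y = np.array([c.observed for c in counts], dtype=float)
        e = np.array([c.expected for c in counts], dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise ValueError("observed and expected must be 1-d and of equal length")
    if len(y) < 2:
        raise ValueError("SCV needs at least 2 areas")
    if np.any(e <= 0):
        raise ValueError("every expected count must be > 0")
    if np.any(y < 0):
        raise ValueError("observed counts must be >= 0")
    return y, e


def scv(counts: Sequence[AreaCounts] | Sequence[float], expected=None) -> float:
    """SCV on the x100 scale.

    Accepts either a sequence of :class:`AreaCounts` or two parallel arrays
    ``scv(y, e)``.  May be negative; see module docstring.
    """
    y, e = _as_arrays(counts, expected)
    k = len(y)
    return 100.0 / k * float(np.sum((y - e) ** 2 / e**2) - np.sum(1.0 / e))


def classify_scv(value: float) -> VariationLevel:
    """Map an SCV value (x100 scale) to its five-level classification."""
    for bound, level in CLASSIFICATION_BOUNDS:
        if value >= bound:
            return level
    return VariationLevel.no_variation


def scv_confidence_interval(
    counts: Sequence[AreaCounts] | Sequence[float],
    expected=None,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval for the SCV.

    Replicates resample y_i* ~ Poisson(e_i * y_i/e_i) with e_i held fixed —
    i.e. Poisson at each area's fitted mean — and take the percentile
    interval of the replicated SCVs.  Deterministic given ``seed``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y, e = _as_arrays(counts, expected)
    k = len(y)
    rng = np.random.default_rng(seed)
    ystar = rng.poisson(lam=e * (y / e), size=(n_boot, k)).astype(float)
    reps = 100.0 / k * (
        np.sum((ystar - e) ** 2 / e**2, axis=1) - np.sum(1.0 / e)
    )
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def compute_scv(
    counts: Sequence[AreaCounts],
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> ScvResult:
    """Full SCV analysis of a set of area counts: estimate, CI, classification."""
    value = scv(counts)
    lo, hi = scv_confidence_interval(counts, level=level, n_boot=n_boot, seed=seed)
    return ScvResult(
        scv=value,
        ci_low=lo,
        ci_high=hi,
        k=len(counts),
        classification=classify_scv(value),
        per_area_ratio={c.area: c.ratio for c in counts},
        total_observed=int(sum(c.observed for c in counts)),
        total_expected=float(sum(c.expected for c in counts)),
    )


def variation_summary(rates: Sequence[float]) -> VariationSummary:
    """Range, extremal quotient, sample SD (n-1) and CV of area rates."""
    r = np.asarray(rates, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 area rates")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    rng_ = float(r.max() - r.min())
    eq = float(r.max() / r.min()) if r.min() > 0 else None
    sd = float(np.std(r, ddof=1))
    mean = float(r.mean())
    cv = sd / mean if mean > 0 else 0.0
    return VariationSummary(range=rng_, extremal_quotient=eq, sd=sd, cv=cv)
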