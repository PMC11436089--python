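"""Segmentation evaluation statistics.

Dice similarity for mask overlap, cavity-inclusion accounting (how much of
each resection cavity a predicted tumour mask wrongly labels), the exact
Clopper–Pearson binomial confidence interval for success proportions, and
percentile-bootstrap confidence intervals for median scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cavities import CavitySet
from .io import GeometryError

__all__ = [
    "DiceResult",
    "CavityInclusionReport",
    "BinomialCI",
    "dice",
    "cavity_inclusion",
    "clopper_pearson",
    "bootstrap_median_ci",
]


@dataclass(frozen=True)
class DiceResult:
    """Dice similarity between two masks: 2|A∩B| / (|A|+|B|).

    ``score`` is NaN and ``defined`` False when both masks are empty; such
    cases carry no overlap information and should be excluded from score
    distributions rather than scored 1.
    """

    score: float
    intersection_voxels: int
    size_a: int
    size_b: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


def dice(a: np.ndarray, b: np.ndarray) -> DiceResult:
    """Dice similarity coefficient of two binary masks on one grid."""
    a = np.asarray(a).astype(bool, copy=False)
    b = np.asarray(b).astype(bool, copy=False)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    size_a = int(a.sum())
    size_b = int(b.sum())
    inter = int((a & b).sum())
    if size_a + size_b == 0:
        score = float("nan")
    else:
        score = 2.0 * inter / (size_a + size_b)
    return DiceResult(score=score, intersection_voxels=inter, size_a=size_a, size_b=size_b)


@dataclass(frozen=True)
class CavityInclusionReport:
    """How much of each cavity a prediction mask includes.

    ``mean_included_cm3`` averages over cavities with nonzero inclusion
    (None when no cavity is touched); ``mean_included_cm3_all`` divides by
    the total cavity count instead.  Both denominators are reported because
    either can be meant by "average labelled volume per cavity".
    """

    per_cavity_included_mm3: tuple[float, ...]
    n_cavities_over_threshold: int
    threshold_cm3: float
    mean_included_cm3: float | None
    mean_included_cm3_all: float | None


def cavity_inclusion(
    prediction: np.ndarray,
    cavities: CavitySet,
    threshold_cm3: float = 1.0,
    voxel_volume_mm3: float | None = None,
) -> CavityInclusionReport:
    """Measure how much of each cavity a predicted mask wrongly labels.

    Per-cavity inclusion is |prediction ∩ cavity| × voxel volume.  A cavity
    counts toward ``n_cavities_over_threshold`` when its inclusion is at
    least ``threshold_cm3`` (default 1 cm³); below-threshold inclusions are
    still recorded per cavity.
    """
    prediction = np.asarray(prediction).astype(bool, copy=False)
    if voxel_volume_mm3 is None:
        spacing = np.linalg.norm(np.asarray(cavities.affine)[:3, :3], axis=0)
        voxel_volume_mm3 = float(np.prod(spacing))
    included: list[float] = []
    for mask, cavity_volume in zip(cavities.cavities, cavities.volumes_mm3):
        if mask.shape != prediction.shape:
            raise GeometryError(f"shape mismatch: {mask.shape} vs {prediction.shape}")
        vol = float((prediction & mask).sum()) * voxel_volume_mm3
        assert vol <= cavity_volume + 1e-9
        included.append(vol)
    over = sum(1 for v in included if v >= threshold_cm3 * 1000.0)
    nonzero = [v for v in included if v > 0]
    return CavityInclusionReport(
        per_cavity_included_mm3=tuple(included),
        n_cavities_over_threshold=over,
        threshold_cm3=threshold_cm3,
        mean_included_cm3=(sum(nonzero) / len(nonzero) / 1000.0) if nonzero else None,
        mean_included_cm3_all=(sum(included) / len(included) / 1000.0) if included else None,
    )


@dataclass(frozen=True)
class BinomialCI:
    """Exact binomial confidence interval for a success proportion."""

    successes: int
    trials: int
    confidence: float
    lower: float
    upper: float

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def clopper_pearson(
    successes: int,
    trials: int,
    confidence: float = 0.95,
) -> BinomialCI:
    """Clopper–Pearson (exact) confidence interval for a binomial proportion.

    With α = 1 − confidence:

    * lower = Beta(α/2; k, n−k+1) quantile, 0 when k = 0;
    * upper = Beta(1−α/2; k+1, n−k) quantile, 1 when k = n.

    The interval is conservative: its coverage is at least the nominal
    confidence for every true proportion, with no normal approximation.
    """
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not (0 <= successes <= trials):
        raise ValueError(f"successes must be in [0, {trials}], got {successes}")
    alpha = 1.0 - confidence
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return BinomialCI(
        successes=successes, trials=trials, confidence=confidence, lower=lower, upper=upper
    )


def bootstrap_median_ci(
    values,
    confidence: float = 0.95,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the median.

    Resamples with replacement ``n_resamples`` times and takes the α/2 and
    1−α/2 percentiles of the resampled medians.  Deterministic for a given
    seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if n_resamples < 1000:
        raise ValueError(f"n_resamples must be >= 1000, got {n_resamples}")
    if not (0 < confidence < 1):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = 1.0 - confidence
    lower, upper = np.percentile(medians, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return float(lower), float(upper)
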