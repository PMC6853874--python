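"""Population-level descriptive and inferential statistics.

Covers the per-experiment bookkeeping around the deconvolution and
enrichment analyses: control-mean normalization of fluorescence, fixed-
threshold outlier percentages and their fold changes across genotypes,
exact two-sample Kolmogorov–Smirnov comparison of small replicate sets,
coefficients of variation and dual-reporter correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_THRESHOLD",
    "OutlierReport",
    "NoiseStats",
    "KSResult",
    "FoldChange",
    "normalize_to_control",
    "denormalize_from_control",
    "percent_outliers",
    "outlier_report",
    "fold_outlier_effect",
    "ks_compare",
    "coefficient_of_variation",
    "dual_reporter_correlation",
    "noise_stats",
    "control_band",
]

#: Default outlier threshold on the normalized fluorescence scale (A.U.).
DEFAULT_THRESHOLD = 1250.0

# exact permutation enumeration is used up to this combined sample size
_EXACT_LIMIT = 20


@dataclass(frozen=True)
class OutlierReport:
    """Per-replicate outlier percentages above a fixed normalized threshold.

    The normalization reference mean is stored alongside the threshold so the
    report is reproducible on the original intensity scale.
    """

    reference_mean: float
    threshold: float
    percentages: dict
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        for p in self.percentages.values():
            if not (0.0 <= p <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")


@dataclass(frozen=True)
class NoiseStats:
    """CV per channel plus dual-reporter correlations."""

    cv: dict
    pearson_r: float
    spearman_rho: float
    n: int


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS statistic with an exact or asymptotic two-sided p-value."""

    statistic: float
    pvalue: float
    n1: int
    n2: int
    method: str
    ties: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= 1.0):
            raise ValueError("KS statistic must lie in [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class FoldChange:
    """Ratio of replicate-set means with first-order SEM propagation."""

    fold: float
    sem: float
    unbounded: bool = False
    diagnostics: dict = field(default_factory=dict)


def normalize_to_control(events, control_mean: float, reference_scale: float = 1.0):
    """Rescale intensities by the mean fluorescence of a control sample.

    Each intensity is divided by ``control_mean``; ``reference_scale`` maps
    the control mean onto a nominal reporting value (1.0 for control-mean
    units, ~100 for the instrument-baseline convention).  The transform is
    invertible given the stored reference.
    """
    if not (control_mean > 0):
        raise ValueError("control mean must be positive")
    return np.asarray(events, dtype=float) * (reference_scale / control_mean)


def denormalize_from_control(normalized, control_mean: float, reference_scale: float = 1.0):
    """Invert :func:`normalize_to_control` given the stored reference mean."""
    if not (control_mean > 0):
        raise ValueError("control mean must be positive")
    return np.asarray(normalized, dtype=float) * (control_mean / reference_scale)


def percent_outliers(normalized_events, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Percentage of events strictly above a fixed normalized threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(normalized_events, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute outlier percentage of an empty sample")
    return float(100.0 * np.count_nonzero(x > threshold) / x.size)


def outlier_report(
    replicates: Mapping,
    control_mean: float,
    threshold: float = DEFAULT_THRESHOLD,
    reference_scale: float = 1.0,
) -> OutlierReport:
    """Normalize each replicate to the control mean and count outliers.

    ``replicates`` maps replicate id -> raw intensity vector.  Returns the
    per-replicate percentages with their mean and SEM.
    """
    percentages = {
        rep: percent_outliers(
            normalize_to_control(values, control_mean, reference_scale), threshold
        )
        for rep, values in replicates.items()
    }
    values = np.array(list(percentages.values()), dtype=float)
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return OutlierReport(
        reference_mean=float(control_mean),
        threshold=float(threshold),
        percentages=percentages,
        mean=float(values.mean()),
        sem=sem,
    )


def fold_outlier_effect(percentages_a, percentages_b) -> FoldChange:
    """Fold change mean(A)/mean(B) of replicate outlier percentages.

    SEMs of the two means are propagated to the ratio at first order.  A zero
    denominator is reported as an unbounded fold change, not an error.
    """
    a = np.asarray(percentages_a, dtype=float)
    b = np.asarray(percentages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both replicate sets must be non-empty")
    mean_a, mean_b = a.mean(), b.mean()
    sem_a = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
    sem_b = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else 0.0
    if mean_b == 0:
        return FoldChange(
            fold=float("inf"),
            sem=float("nan"),
            unbounded=True,
            diagnostics={"mean_a": float(mean_a), "mean_b": 0.0},
        )
    fold = mean_a / mean_b
    rel = np.sqrt(
        (sem_a / mean_a) ** 2 + (sem_b / mean_b) ** 2
    ) if mean_a != 0 else 0.0
    return FoldChange(
        fold=float(fold),
        sem=float(abs(fold) * rel),
        diagnostics={
            "mean_a": float(mean_a),
            "mean_b": float(mean_b),
            "sem_a": float(sem_a),
            "sem_b": float(sem_b),
        },
    )


def _ks_statistic_pooled(order_mask: np.ndarray, values: np.ndarray, n1: int, n2: int) -> float:
    """KS D for one assignment of pooled sorted values to the first sample.

    ``order_mask`` marks which positions of the sorted pooled vector belong to
    sample 1.  With ties, ECDF differences are evaluated only at the last
    position of each tied run (the standard treatment).
    """
    cum1 = np.cumsum(order_mask) / n1
    cum2 = (np.arange(1, values.size + 1) - np.cumsum(order_mask)) / n2
    evaluate = np.ones(values.size, dtype=bool)
    evaluate[:-1] = values[:-1] != values[1:]
    return float(np.max(np.abs(cum1 - cum2)[evaluate]))


def ks_compare(frequencies_a, frequencies_b) -> KSResult:
    """Two-sided two-sample KS test with an exact small-sample p-value.

    Replicate measurements (e.g. outlier percentages) are treated as members
    of a distribution.  For combined sample size <= 20 the p-value is exact:
    every assignment of the pooled values to the two groups is enumerated and
    the p-value is the fraction of assignments whose D is at least the
    observed one.  Larger samples fall back to the asymptotic distribution,
    tagged in ``method``.  Tied pooled values are evaluated at distinct values
    only and flagged.
    """
    a = np.asarray(frequencies_a, dtype=float)
    b = np.asarray(frequencies_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each replicate set needs at least 2 values")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    values = pooled[order]
    ties = bool(np.unique(values).size < values.size)
    mask = (order < n1)
    d_observed = _ks_statistic_pooled(mask, values, n1, n2)

    if n1 + n2 <= _EXACT_LIMIT:
        total = 0
        at_least = 0
        template = np.zeros(values.size, dtype=bool)
        for idx in combinations(range(values.size), n1):
            template[:] = False
            template[list(idx)] = True
            total += 1
            if _ks_statistic_pooled(template, values, n1, n2) >= d_observed - 1e-12:
                at_least += 1
        pvalue = at_least / total
        method = "exact"
    else:
        pvalue = float(stats.ks_2samp(a, b, method="asymp").pvalue)
        pvalue = min(max(pvalue, np.nextafter(0, 1)), 1.0)
        method = "asymptotic"
    return KSResult(
        statistic=d_observed, pvalue=float(pvalue), n1=n1, n2=n2, method=method, ties=ties
    )


def coefficient_of_variation(intensities) -> float:
    """Unbiased-SD coefficient of variation; requires a positive mean."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(x.std(ddof=1) / mean)


def dual_reporter_correlation(channel1, channel2) -> tuple[float, float]:
    """Pearson r and Spearman rho between two reporter channels."""
    x = np.asarray(channel1, dtype=float)
    y = np.asarray(channel2, dtype=float)
    if x.size != y.size:
        raise ValueError("channels must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired events")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance channel: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho


def noise_stats(channel1, channel2, labels: tuple[str, str] = ("yfp", "mcherry")) -> NoiseStats:
    """Bundle CVs and correlations for a dual-reporter experiment."""
    r, rho = dual_reporter_correlation(channel1, channel2)
    return NoiseStats(
        cv={
            labels[0]: coefficient_of_variation(channel1),
            labels[1]: coefficient_of_variation(channel2),
        },
        pearson_r=r,
        spearman_rho=rho,
        n=int(np.asarray(channel1).size),
    )


def control_band(control_events, upper_quantile: float = 0.99) -> tuple[float, float]:
    """Annotation band [0, q99] of the autofluorescence control.

    Used to shade the autofluorescence range on plots; never used to filter
    events before moment computation.
    """
    x = np.asarray(control_events, dtype=float)
    if x.size == 0:
        raise ValueError("control events must be non-empty")
    return 0.0, float(np.quantile(x, upper_quantile))
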