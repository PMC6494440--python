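"""Statistical primitives shared by every pipeline stage.

Hypergeometric over-representation (the one-sided Fisher exact test for a
2x2 overlap table), fold enrichment, Benjamini-Hochberg adjustment, the
Grubbs single-outlier test, two-sample t-test power, and relative qPCR
quantification by the delta-delta-Ct method.

All functions are pure; enrichment p-values are computed in log space so
overlaps as extreme as p ~ 1e-300 remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "EnrichmentResult",
    "OutlierResult",
    "QpcrMeasurement",
    "hypergeom_tail",
    "log_hypergeom_tail",
    "fold_enrichment",
    "bh_adjust",
    "grubbs_outlier",
    "grubbs_critical_value",
    "power_two_sample_t",
    "ddct_relative_expression",
]


@dataclass(frozen=True)
class StatsConfig:
    """Significance conventions used throughout the pipeline.

    ``alpha`` is the per-test significance level, ``fdr_threshold`` the BH
    cutoff that defines a differential-expression signature, and
    ``effect_size_d`` the standardized mean difference the study is powered
    to detect.
    """

    alpha: float = 0.05
    fdr_threshold: float = 0.05
    effect_size_d: float = 2.5
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError(
                f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}"
            )
        if self.effect_size_d < 0:
            raise ValueError(f"effect_size_d must be >= 0, got {self.effect_size_d}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one gene set in another within a universe.

    ``fold_enrichment`` is observed/expected overlap; ``p_value`` the
    hypergeometric upper tail P(X >= overlap); ``adjusted_p`` the BH value
    within whatever family the caller adjusted over (equals ``p_value``
    for a single test).
    """

    overlap: int
    set1_size: int
    set2_size: int
    universe_size: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float = float("nan")
    name: str = ""

    def __post_init__(self) -> None:
        if self.overlap > min(self.set1_size, self.set2_size):
            raise ValueError("overlap exceeds a set size")
        if max(self.set1_size, self.set2_size) > self.universe_size:
            raise ValueError("set size exceeds universe size")


@dataclass(frozen=True)
class OutlierResult:
    """Grubbs test outcome: the flagged index (or None) plus G and its critical value."""

    flagged_index: Optional[int]
    statistic_G: float
    critical_value: float


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired Ct values for a target and a reference (housekeeping) gene."""

    ct_target: float
    ct_reference: float
    sample_label: str = ""
    calibrator: bool = False

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def _check_overlap_args(overlap: int, n1: int, n2: int, N: int) -> None:
    if N < 1:
        raise ValueError(f"universe size must satisfy N >= 1, got N={N}")
    if n1 > N or n2 > N:
        raise ValueError(
            f"set sizes must satisfy n1 <= N and n2 <= N, got n1={n1}, n2={n2}, N={N}"
        )
    if overlap < 0 or overlap > min(n1, n2):
        raise ValueError(
            f"overlap must satisfy 0 <= overlap <= min(n1, n2), "
            f"got overlap={overlap}, n1={n1}, n2={n2}"
        )
    if n1 + n2 - overlap > N:
        raise ValueError(
            f"union of sets exceeds universe: n1 + n2 - overlap = "
            f"{n1 + n2 - overlap} > N = {N}"
        )


def log_hypergeom_tail(overlap: int, n1: int, n2: int, N: int) -> float:
    """Natural log of the hypergeometric upper tail P(X >= overlap).

    X counts the intersection of a fixed n1-set with a uniformly random
    n2-set in a universe of N genes.
    """
    _check_overlap_args(overlap, n1, n2, N)
    if overlap == 0:
        return 0.0
    return float(sps.hypergeom.logsf(overlap - 1, N, n1, n2))


def hypergeom_tail(overlap: int, n1: int, n2: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    This is the one-sided Fisher exact test p-value for enrichment of the
    overlap between an n1-set and an n2-set in a universe of N genes.
    Computed via the log survival function; underflows below ~1e-308
    return 0.0 (use :func:`log_hypergeom_tail` when the magnitude matters).
    """
    return float(np.exp(log_hypergeom_tail(overlap, n1, n2, N)))


def fold_enrichment(overlap: int, n1: int, n2: int, N: int) -> float:
    """Observed/expected overlap: overlap * N / (n1 * n2)."""
    _check_overlap_args(overlap, n1, n2, N)
    if n1 == 0 or n2 == 0:
        raise ValueError(f"set sizes must be >= 1 for fold enrichment, got n1={n1}, n2={n2}")
    return overlap * N / (n1 * n2)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1. Monotone: output >= input elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)]
        raise ValueError(f"p-values must lie in [0, 1]; offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha.

    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student-t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs test requires n >= 3, got n={n}")
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values: Sequence[float], alpha: float = 0.05) -> OutlierResult:
    """Grubbs single-outlier test (extreme studentized deviate), two-sided.

    G = max_i |x_i - mean| / sd with the n-1 denominator in sd. Flags the
    single most extreme observation iff G exceeds the critical value; at
    most one index is ever flagged per call.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test requires >= 3 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs test undefined for a constant sample (zero variance)")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    crit = grubbs_critical_value(x.size, alpha)
    return OutlierResult(
        flagged_index=idx if g > crit else None,
        statistic_G=g,
        critical_value=crit,
    )


def power_two_sample_t(
    n_per_group: tuple[int, int] | int,
    effect_size_d: float,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> float:
    """Power of the two-sample t-test via the noncentral t distribution.

    Noncentrality ncp = d * sqrt(n1*n2/(n1+n2)), df = n1 + n2 - 2. At
    d = 0 the power equals alpha by construction.
    """
    if isinstance(n_per_group, (int, np.integer)):
        n1 = n2 = int(n_per_group)
    else:
        n1, n2 = (int(v) for v in n_per_group)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs n >= 2, got ({n1}, {n2})")
    if effect_size_d < 0:
        raise ValueError(f"effect size must be >= 0, got {effect_size_d}")
    df = n1 + n2 - 2
    ncp = effect_size_d * math.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = sps.t.ppf(1 - alpha, df)
        power = sps.nct.sf(tcrit, df, ncp)
    return float(power)


def ddct_relative_expression(
    sample: QpcrMeasurement, calibrator: QpcrMeasurement
) -> float:
    """Relative expression 2^-ddCt with ddCt = dCt_sample - dCt_calibrator.

    dCt is the target Ct minus the reference (housekeeping) Ct; base-2
    assumes perfect amplification efficiency every cycle.
    """
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))
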