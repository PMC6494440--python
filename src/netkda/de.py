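"""Counts to directional differential-expression signatures.

Implements the bulk RNA-seq chain used on the six-genotype mouse design:
expression filtering at CPM >= 1 in at least one sample, TMM
between-sample normalization, log2-CPM transformation, a per-gene
group-means linear model with empirical-Bayes variance moderation, and
FDR-thresholded up/down signatures per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special as spsp
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "GENOTYPES",
    "DEFAULT_CONTRASTS",
    "CountMatrix",
    "NormalizationFactors",
    "ModeratedFit",
    "Signature",
    "filter_expressed",
    "tmm_factors",
    "log_cpm",
    "residualize_covariates",
    "fit_moderated_model",
    "contrast_table",
    "call_signature",
]

#: The six genotypes of the cerebral-amyloidosis x driver-knockout cross.
GENOTYPES = (
    "WT",
    "Tyrobp_het",
    "Tyrobp_ko",
    "APP_PSEN1",
    "APP_PSEN1_het",
    "APP_PSEN1_ko",
)

#: The six reported pairwise contrasts (test group first, baseline second).
DEFAULT_CONTRASTS = (
    ("Tyrobp_het", "WT"),
    ("Tyrobp_ko", "WT"),
    ("APP_PSEN1", "WT"),
    ("APP_PSEN1_ko", "APP_PSEN1"),
    ("APP_PSEN1_ko", "WT"),
    ("APP_PSEN1_ko", "Tyrobp_ko"),
)


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample count matrix with per-sample genotype labels."""

    counts: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    genotype: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "genotype", tuple(self.genotype))
        n_genes, n_samples = counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match count rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if len(self.sample_ids) != n_samples or len(self.genotype) != n_samples:
            raise ValueError("sample_ids/genotype length does not match count columns")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Total mapped counts per sample (column sums)."""
        return self.counts.sum(axis=0)

    def cpm(self) -> np.ndarray:
        """Counts per million on raw library sizes."""
        lib = self.library_sizes.astype(float)
        if np.any(lib == 0):
            raise ValueError("sample with zero library size")
        return self.counts / lib * 1e6

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        return replace(
            self,
            counts=self.counts[keep],
            gene_ids=tuple(np.asarray(self.gene_ids, dtype=object)[keep]),
        )


@dataclass(frozen=True)
class NormalizationFactors:
    """TMM scaling factors; geometric mean constrained to 1."""

    tmm_factor: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.tmm_factor, dtype=float)
        if np.any(f <= 0):
            raise ValueError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"TMM factors must have geometric mean 1, got {gm}")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return np.asarray(self.library_sizes, dtype=float) * np.asarray(
            self.tmm_factor, dtype=float
        )


@dataclass(frozen=True)
class ModeratedFit:
    """Per-gene group means with empirical-Bayes moderated variances.

    ``posterior_variance`` is the weighted combination
    (d0*s0^2 + d_g*s_g^2) / (d0 + d_g); when the prior df d0 is infinite
    every posterior variance collapses to the prior variance s0^2.
    """

    coefficients: pd.DataFrame  # genes x groups, log2-CPM means
    group_sizes: dict[str, int]
    residual_variance: np.ndarray
    residual_df: float
    prior_df: float
    prior_variance: float
    posterior_variance: np.ndarray
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class Signature:
    """Directional DEG sets for one contrast at one FDR threshold."""

    up: frozenset[str]
    down: frozenset[str]
    contrast: str
    threshold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and downregulated")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up | self.down


def filter_expressed(counts: CountMatrix, min_cpm: float = 1.0) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least one sample (inclusive boundary)."""
    if counts.n_genes == 0:
        raise ValueError("empty count matrix")
    keep = (counts.cpm() >= min_cpm).any(axis=1)
    if not keep.any():
        raise ValueError("no gene passes the expression filter")
    return counts.subset_genes(keep)


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_expr_trim: float,
) -> float:
    """log2 TMM factor of one sample against the reference column."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValueError("no shared nonzero genes between sample and reference")
    o = obs[shared].astype(float)
    r = ref[shared].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # binomial asymptotic variance of M as inverse precision weight; floor
    # guards the degenerate one-gene library
    w = np.maximum((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r), 1e-24)

    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        return 0.0
    return float(f)


def tmm_factors(
    counts: CountMatrix,
    reference: Optional[int] = None,
    logratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors between samples.

    Per-gene log ratios (M) against a reference sample are double-trimmed
    (30% on M, 5% on average log abundance A), averaged with inverse
    binomial-variance precision weights, and exponentiated; factors are
    rescaled to geometric mean 1. The reference defaults to the sample
    whose 75th CPM percentile is closest to the mean across samples.
    """
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.library_sizes.astype(float)
    if reference is None:
        f75 = np.quantile(counts.counts / lib, 0.75, axis=0)
        reference = int(np.argmin(np.abs(f75 - f75.mean())))
    ref_col = counts.counts[:, reference]
    logf = np.array(
        [
            _tmm_pair_factor(
                counts.counts[:, k], ref_col, lib[k], lib[reference],
                logratio_trim, abs_expr_trim,
            )
            for k in range(counts.n_samples)
        ]
    )
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(tmm_factor=factors, library_sizes=lib)


def log_cpm(
    counts: CountMatrix,
    norm: Optional[NormalizationFactors] = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes with a prior count."""
    lib = (
        norm.effective_library_sizes
        if norm is not None
        else counts.library_sizes.astype(float)
    )
    vals = np.log2((counts.counts + prior_count) / (lib + 2 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=list(counts.gene_ids), columns=list(counts.sample_ids))


def residualize_covariates(
    expression: pd.DataFrame, covariates: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Least-squares residuals of each gene on the covariate design.

    The design always includes an intercept, so an empty covariate table
    mean-centers each gene. Categorical covariates are dummy-coded with the
    first level dropped. Raises on a rank-deficient design, naming the
    collinear columns.
    """
    y = expression.to_numpy(dtype=float).T  # samples x genes
    n_samples = y.shape[0]
    design_cols = [pd.Series(np.ones(n_samples), name="intercept")]
    if covariates is not None and covariates.shape[1] > 0:
        if covariates.shape[0] != n_samples:
            raise ValueError(
                f"covariate rows ({covariates.shape[0]}) do not match samples ({n_samples})"
            )
        coded = pd.get_dummies(covariates, drop_first=True, dtype=float)
        design_cols.extend(coded[c] for c in coded.columns)
    X = np.column_stack([np.asarray(c, dtype=float) for c in design_cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = [getattr(c, "name", str(i)) for i, c in enumerate(design_cols)]
        raise ValueError(f"rank-deficient covariate design (columns: {names})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.DataFrame(resid.T, index=expression.index, columns=expression.columns)


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = spsp.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / spsp.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-12):
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed residual variances.

    Returns (prior_df d0, prior_variance s0^2) following the classic
    empirical-Bayes log-variance moment equations: E[log s^2] and
    Var[log s^2] are matched through digamma/trigamma identities.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - spsp.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1)) - float(spsp.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(e_var))
        s0_sq = float(np.exp(e_mean + spsp.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def fit_moderated_model(
    logexpr: pd.DataFrame,
    genotype: Sequence[str],
    prior_df: Optional[float] = None,
) -> ModeratedFit:
    """Group-means linear model per gene with empirical-Bayes moderation.

    Fits a mean per genotype per gene on log2-CPM, pools the residual
    variance across samples, and shrinks per-gene variances toward a prior
    estimated by moment matching of log residual variances. ``prior_df``
    overrides the estimated d0 (0 disables moderation, numpy.inf forces
    full shrinkage to the prior variance).
    """
    genotype = list(genotype)
    if len(genotype) != logexpr.shape[1]:
        raise ValueError("genotype labels do not match expression columns")
    groups = sorted(set(genotype))
    sizes = {g: genotype.count(g) for g in groups}
    small = [g for g in groups if sizes[g] < 2]
    if len(groups) < 2 or small:
        raise ValueError(
            f"need >= 2 groups with >= 2 samples each; undersized groups: {small}"
        )
    y = logexpr.to_numpy(dtype=float)
    n_genes, n_samples = y.shape
    means = np.empty((n_genes, len(groups)))
    rss = np.zeros(n_genes)
    for j, g in enumerate(groups):
        cols = [i for i, lab in enumerate(genotype) if lab == g]
        sub = y[:, cols]
        means[:, j] = sub.mean(axis=1)
        rss += ((sub - means[:, j][:, None]) ** 2).sum(axis=1)
    df_resid = n_samples - len(groups)
    s2 = rss / df_resid
    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    return ModeratedFit(
        coefficients=pd.DataFrame(means, index=logexpr.index, columns=groups),
        group_sizes=sizes,
        residual_variance=s2,
        residual_df=float(df_resid),
        prior_df=float(d0),
        prior_variance=float(s0_sq),
        posterior_variance=s2_post,
        gene_ids=tuple(logexpr.index),
    )


def contrast_table(fit: ModeratedFit, contrast: tuple[str, str]) -> pd.DataFrame:
    """Moderated-t differential-expression table for one genotype pair.

    Columns: gene, log2FC (test minus baseline group mean), t, p
    (two-sided Student-t with d0 + d_g degrees of freedom), FDR
    (Benjamini-Hochberg within this contrast).
    """
    test, base = contrast
    for g in (test, base):
        if g not in fit.coefficients.columns:
            raise ValueError(f"unknown genotype label {g!r} in contrast")
    lfc = fit.coefficients[test].to_numpy() - fit.coefficients[base].to_numpy()
    n1, n2 = fit.group_sizes[test], fit.group_sizes[base]
    se = np.sqrt(fit.posterior_variance * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = fit.prior_df + fit.residual_df
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "gene": list(fit.gene_ids),
            "log2FC": lfc,
            "t": t,
            "p": p,
            "FDR": bh_adjust(p),
        }
    )
    table.attrs["contrast"] = f"{test}_vs_{base}"
    return table


def call_signature(
    table: pd.DataFrame, threshold: float = 0.05, contrast: Optional[str] = None
) -> Signature:
    """Directional signature: up = FDR <= threshold and log2FC > 0, down likewise < 0."""
    if table.shape[0] == 0:
        raise ValueError("empty differential-expression table")
    hits = table[table["FDR"] <= threshold]
    return Signature(
        up=frozenset(hits.loc[hits["log2FC"] > 0, "gene"]),
        down=frozenset(hits.loc[hits["log2FC"] < 0, "gene"]),
        contrast=contrast or table.attrs.get("contrast", ""),
        threshold=threshold,
    )
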