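"""Normalization and moderated differential expression against hand oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from netkda import (
    CountMatrix,
    call_signature,
    contrast_table,
    filter_expressed,
    fit_moderated_model,
    log_cpm,
    residualize_covariates,
    tmm_factors,
)
from netkda.simulate import SimulationConfig, simulate_counts


def tmm_factors_naive(counts: np.ndarray, ref: int) -> np.ndarray:
    """Independent TMM oracle: plain loops, sorting-based double trim.

    Follows the published formula directly: weighted trimmed mean of
    per-gene log ratios (M) against a reference, trimming 30% of genes on
    each side by M and 5% by average abundance (A), with inverse binomial
    asymptotic variance weights, rescaled to geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    n_samp = counts.shape[1]
    logf = np.zeros(n_samp)
    for k in range(n_samp):
        ms, as_, ws = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, k], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[k], r / lib[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                ws.append((lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(ms)
        order_m = sorted(range(n), key=lambda i: ms[i])
        order_a = sorted(range(n), key=lambda i: as_[i])
        rank_m = {i: j + 1 for j, i in enumerate(order_m)}
        rank_a = {i: j + 1 for j, i in enumerate(order_a)}
        lo_m, hi_m = math.floor(n * 0.30) + 1, n - math.floor(n * 0.30)
        lo_a, hi_a = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        f = num / den if den > 0 else 0.0
        logf[k] = 0.0 if abs(f) < 1e-6 else f
    factors = 2.0 ** logf
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilterExpressed:
    def test_all_zero_gene_removed_and_cpm_boundary(self):
        lib = 10**6
        counts = np.zeros((3, 2), dtype=int)
        counts[0] = [1, 0]  # CPM exactly 1 in sample 1 -> retained
        counts[1] = [0, 0]  # never expressed -> removed
        counts[2, 0] = lib - 1  # filler so library size is 1e6
        counts[2, 1] = 2 * 10**6
        cm = CountMatrix(counts, ["boundary", "silent", "filler"], ["s1", "s2"], ["A", "B"])
        kept = filter_expressed(cm)
        assert kept.gene_ids == ("boundary", "filler")

    def test_half_cpm_gene_removed(self):
        counts = np.array([[1, 0], [2 * 10**6 - 1, 10**6]])
        cm = CountMatrix(counts, ["low", "big"], ["s1", "s2"], ["A", "B"])
        # gene "low": count 1 in a 2e6-read sample -> CPM 0.5 -> removed
        assert filter_expressed(cm).gene_ids == ("big",)

    def test_everything_filtered_raises(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 0] = 10**7  # gives sample a library but gene 1 CPM is 1e6... keep
        cm = CountMatrix(counts, ["a", "b"], ["s1", "s2"], ["A", "B"])
        with pytest.raises(ValueError):
            filter_expressed(cm, min_cpm=1e7)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [30], [40]]), (1, 3))
        cm = CountMatrix(counts, list("abcd"), ["s1", "s2", "s3"], ["A", "A", "B"])
        assert tmm_factors(cm).tmm_factor == pytest.approx(np.ones(3))

    def test_pure_depth_change_unit_factors(self):
        base = np.array([[10], [20], [30], [40]])
        counts = np.hstack([base, base * 2])
        cm = CountMatrix(counts, list("abcd"), ["s1", "s2"], ["A", "B"])
        assert tmm_factors(cm).tmm_factor == pytest.approx(np.ones(2))

    def test_matches_independent_oracle(self, small_counts):
        """50-gene spiked fixture: factors equal a loop-based second implementation."""
        got = tmm_factors(small_counts, reference=0)
        want = tmm_factors_naive(small_counts.counts, ref=0)
        assert got.tmm_factor == pytest.approx(want, abs=1e-6)

    def test_gene_order_and_depth_invariance(self, small_counts, rng):
        base = tmm_factors(small_counts, reference=0).tmm_factor
        perm = rng.permutation(small_counts.n_genes)
        shuffled = CountMatrix(
            small_counts.counts[perm],
            [small_counts.gene_ids[i] for i in perm],
            small_counts.sample_ids,
            small_counts.genotype,
        )
        assert tmm_factors(shuffled, reference=0).tmm_factor == pytest.approx(base)
        scaled = CountMatrix(
            small_counts.counts * 3,
            small_counts.gene_ids,
            small_counts.sample_ids,
            small_counts.genotype,
        )
        assert tmm_factors(scaled, reference=0).tmm_factor == pytest.approx(
            base, abs=1e-9
        )

    def test_no_shared_genes_raises(self):
        counts = np.array([[5, 0], [0, 7]])
        cm = CountMatrix(counts, ["a", "b"], ["s1", "s2"], ["A", "B"])
        with pytest.raises(ValueError):
            tmm_factors(cm, reference=0)

    def test_geometric_mean_is_one(self, small_counts):
        f = tmm_factors(small_counts).tmm_factor
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


class TestResidualize:
    def test_intercept_only_mean_centers(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, size=(4, 6)))
        res = residualize_covariates(expr, None)
        assert res.to_numpy().mean(axis=1) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_gene_as_its_own_covariate(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 8)))
        cov = pd.DataFrame({"x": expr.iloc[0].to_numpy()})
        res = residualize_covariates(expr, cov)
        assert res.iloc[0].to_numpy() == pytest.approx(np.zeros(8), abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Random 10x8 fixture against an explicit (X'X)^-1 X'y projection."""
        expr = pd.DataFrame(rng.normal(size=(10, 8)))
        cov = pd.DataFrame(rng.normal(size=(8, 2)), columns=["pmi", "rin"])
        res = residualize_covariates(expr, cov)
        X = np.column_stack([np.ones(8), cov.to_numpy()])
        hat = X @ np.linalg.inv(X.T @ X) @ X.T
        want = expr.to_numpy().T - hat @ expr.to_numpy().T
        assert res.to_numpy() == pytest.approx(want.T, abs=1e-8)

    def test_collinear_design_raises(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 6)))
        cov = pd.DataFrame({"a": np.arange(6.0), "b": 2 * np.arange(6.0)})
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize_covariates(expr, cov)


def pooled_t_by_hand(x, y):
    nx_, ny = len(x), len(y)
    sp2 = ((nx_ - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx_ + ny - 2)
    return (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / nx_ + 1 / ny))


class TestModeratedFit:
    def test_identical_groups_t_zero(self):
        vals = np.tile([[1.0, 2.0, 1.0, 2.0]], (3, 1))
        le = pd.DataFrame(vals, index=["g1", "g2", "g3"])
        fit = fit_moderated_model(le, ["A", "A", "B", "B"])
        tab = contrast_table(fit, ("B", "A"))
        assert tab["t"].to_numpy() == pytest.approx(np.zeros(3))
        assert tab["p"].to_numpy() == pytest.approx(np.ones(3))

    def test_infinite_prior_df_collapses_to_prior_variance(self, rng):
        le = pd.DataFrame(rng.normal(size=(20, 6)))
        fit = fit_moderated_model(le, ["A"] * 3 + ["B"] * 3, prior_df=np.inf)
        assert fit.posterior_variance == pytest.approx(
            np.full(20, fit.prior_variance)
        )

    def test_disabled_moderation_equals_pooled_t(self, rng):
        x = rng.normal(1.0, 1.0, 3)
        y = rng.normal(0.0, 1.0, 3)
        le = pd.DataFrame([np.concatenate([x, y])], index=["g"])
        # a second gene so variance moment-matching has input, but d0=0 ignores it
        le.loc["g2"] = rng.normal(size=6)
        fit = fit_moderated_model(le, ["X"] * 3 + ["Y"] * 3, prior_df=0.0)
        tab = contrast_table(fit, ("X", "Y"))
        assert tab.loc[tab.gene == "g", "t"].iloc[0] == pytest.approx(
            pooled_t_by_hand(x, y), rel=1e-12
        )

    def test_posterior_variance_identity(self, rng):
        le = pd.DataFrame(rng.normal(size=(100, 8)) * rng.lognormal(0, 0.5, 100)[:, None])
        fit = fit_moderated_model(le, ["A"] * 4 + ["B"] * 4)
        want = (
            fit.prior_df * fit.prior_variance
            + fit.residual_df * fit.residual_variance
        ) / (fit.prior_df + fit.residual_df)
        assert fit.posterior_variance == pytest.approx(want)

    def test_undersized_group_raises(self, rng):
        le = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            fit_moderated_model(le, ["A", "A", "B"])


class TestContrastTable:
    def test_sign_flips_with_contrast_order(self, rng):
        le = pd.DataFrame(rng.normal(size=(30, 8)))
        fit = fit_moderated_model(le, ["A"] * 4 + ["B"] * 4)
        ab = contrast_table(fit, ("A", "B"))
        ba = contrast_table(fit, ("B", "A"))
        assert ab["log2FC"].to_numpy() == pytest.approx(-ba["log2FC"].to_numpy())
        assert ab["p"].to_numpy() == pytest.approx(ba["p"].to_numpy())

    def test_unknown_genotype_raises(self, rng):
        le = pd.DataFrame(rng.normal(size=(5, 4)))
        fit = fit_moderated_model(le, ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="unknown genotype"):
            contrast_table(fit, ("A", "C"))

    def test_planted_twofold_log2fc_recovered(self):
        """Median estimated log2FC of planted 2-fold genes lies within 0.25 of 1."""
        cfg = SimulationConfig(seed=1, planted_log2fc=1.0)
        cm, truth = simulate_counts(cfg)
        expressed = filter_expressed(cm)
        fit = fit_moderated_model(
            log_cpm(expressed, tmm_factors(expressed)), expressed.genotype
        )
        tab = contrast_table(fit, ("APP_PSEN1", "WT")).set_index("gene")
        planted = sorted(truth.planted_up_in_APP & set(expressed.gene_ids))
        assert abs(tab.loc[planted, "log2FC"].median() - 1.0) < 0.25


class TestCallSignature:
    def test_null_table_empty_signature(self):
        tab = pd.DataFrame(
            {"gene": ["a", "b"], "log2FC": [1.0, -1.0], "t": [0.1, -0.1],
             "p": [1.0, 1.0], "FDR": [1.0, 1.0]}
        )
        sig = call_signature(tab, 0.05)
        assert not sig.up and not sig.down

    def test_partition_of_deg_count(self, rng):
        n = 200
        tab = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "log2FC": rng.normal(size=n),
                "t": rng.normal(size=n),
                "p": rng.uniform(size=n),
            }
        )
        tab["FDR"] = tab["p"]
        sig = call_signature(tab, 0.3)
        n_deg = int((tab["FDR"] <= 0.3).sum())
        assert len(sig.up) + len(sig.down) == n_deg
        assert not (sig.up & sig.down)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            call_signature(pd.DataFrame(columns=["gene", "log2FC", "FDR"]))


def test_null_pvalues_approximately_uniform():
    """Under the global null the moderated p-values are near-uniform (KS < 0.05)."""
    from scipy.stats import kstest

    cfg = SimulationConfig(seed=99, planted_log2fc=0.0)
    cm, _ = simulate_counts(cfg)
    expressed = filter_expressed(cm)
    fit = fit_moderated_model(
        log_cpm(expressed, tmm_factors(expressed)), expressed.genotype
    )
    tab = contrast_table(fit, ("APP_PSEN1", "WT"))
    assert kstest(tab["p"], "uniform").statistic < 0.05
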