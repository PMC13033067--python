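import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from progsub import (
    bh_adjust,
    call_degs,
    de_counts,
    filter_by_expression,
    log_cpm,
    moderated_two_group_test,
    tmm_norm_factors,
)
from progsub.de import fit_f_dist, posterior_variances, trigamma_inverse


def count_frame(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)


# ---------------------------------------------------------------------------
# filtering


class TestFilterByExpression:
    def test_all_zero_feature_removed(self):
        counts = count_frame([[0, 0, 0, 0], [100, 120, 90, 110]])
        groups = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        kept = filter_by_expression(counts, groups)
        assert "f0" not in kept and "f1" in kept

    def test_high_count_feature_retained(self):
        counts = count_frame(np.full((3, 4), 1000.0))
        groups = pd.Series(["a", "a", "b", "b"], index=counts.columns)
        assert len(filter_by_expression(counts, groups)) == 3

    def test_matches_naive_rule(self, rng):
        counts = count_frame(rng.integers(0, 60, size=(10, 6)).astype(float))
        counts.iloc[0] = 0
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
        kept = filter_by_expression(counts, groups, min_count=10, min_total_count=15)
        # naive restatement of the rule
        lib = counts.sum(axis=0)
        cutoff = 10 / np.median(lib) * 1e6
        cpm = counts / lib * 1e6
        expected = [
            f for f in counts.index
            if (cpm.loc[f] >= cutoff).sum() >= 3 and counts.loc[f].sum() >= 15
        ]
        assert list(kept) == expected

    def test_empty_group_rejected(self):
        counts = count_frame([[1, 2]])
        groups = pd.Series(["a", None], index=counts.columns)
        with pytest.raises(ValueError):
            filter_by_expression(counts, groups)


# ---------------------------------------------------------------------------
# TMM


def tmm_bruteforce(counts: pd.DataFrame) -> np.ndarray:
    """Literal transcription of the doubly trimmed weighted mean of M-values."""
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(Y.shape[1]):
        y, yr = Y[:, j], Y[:, ref]
        ok = (y > 0) & (yr > 0)
        y, yr = y[ok], yr[ok]
        M = np.log2((y / lib[j]) / (yr / lib[ref]))
        A = 0.5 * np.log2((y / lib[j]) * (yr / lib[ref]))
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - yr) / (lib[ref] * yr)
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = M.size
        rm, ra = stats.rankdata(M), stats.rankdata(A)
        keep = (
            (rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
            & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05))
        )
        factors.append(2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = count_frame(np.tile([[10], [20], [30]], (1, 2)))
        nf = tmm_norm_factors(counts)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-12)

    def test_pure_depth_change_unit_factors(self):
        col = np.array([10.0, 25.0, 40.0, 5.0, 100.0, 20.0])
        counts = count_frame(np.column_stack([col, 2 * col]))
        nf = tmm_norm_factors(counts)
        np.testing.assert_allclose(nf.factors, 1.0, atol=1e-12)

    def test_matches_bruteforce_formula(self, rng):
        counts = count_frame(rng.integers(1, 500, size=(60, 3)).astype(float))
        nf = tmm_norm_factors(counts)
        np.testing.assert_allclose(nf.factors, tmm_bruteforce(counts), atol=1e-8)

    def test_depth_rescaling_invariance(self, rng):
        counts = count_frame(rng.integers(1, 300, size=(40, 4)).astype(float))
        nf1 = tmm_norm_factors(counts)
        nf2 = tmm_norm_factors(counts * 7)
        np.testing.assert_allclose(nf1.factors, nf2.factors, atol=1e-10)

    def test_all_zero_library_rejected(self):
        counts = count_frame([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(counts)

    def test_matches_edger_reference(self, rng, tmp_path):
        """Independent oracle: edgeR calcNormFactors on the same matrix."""
        if shutil.which("Rscript") is None:
            raise RuntimeError("Rscript is required for the edgeR cross-check")
        counts = count_frame(
            rng.negative_binomial(5, 0.1, size=(50, 5)).astype(float) + 1
        )
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'd <- calcNormFactors(DGEList(counts=x), method="TMM");'
            'cat(paste(d$samples$norm.factors, collapse=","))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(
            tmm_norm_factors(counts).factors, reference, atol=1e-10
        )


# ---------------------------------------------------------------------------
# log-CPM


class TestLogCpm:
    def test_zero_count_reference_value(self):
        counts = count_frame([[0.0], [1e6]], samples=["s1"])
        out = log_cpm(counts, None, prior=0.5)
        # libsize 1e6: log2(0.5 / (1e6 + 1) * 1e6)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5 / 1000001 * 1e6), abs=1e-9)

    def test_depth_doubling_cancels(self, rng):
        counts = count_frame(rng.integers(1000, 10000, size=(20, 3)).astype(float))
        a = log_cpm(counts)
        b = log_cpm(counts * 2)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-3

    def test_prior_limit_recovers_log2(self):
        lib = 3e6
        x = 128.0
        counts = count_frame([[lib / 1e6 * x], [lib - lib / 1e6 * x]], samples=["s1"])
        out = log_cpm(counts, None, prior=1e-12)
        assert out.iloc[0, 0] == pytest.approx(np.log2(x), abs=1e-5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(count_frame([[-1.0, 2.0]]))


# ---------------------------------------------------------------------------
# moderated test


class TestModeratedTest:
    def test_identical_groups_null_feature(self, rng):
        expr = count_frame(rng.normal(5, 1, size=(30, 8)))
        expr.iloc[0] = [3, 4, 5, 6, 3, 4, 5, 6]  # identical across groups
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=expr.columns)
        _, tab = moderated_two_group_test(expr, groups, "a")
        assert tab.iloc[0]["lfc"] == 0
        assert tab.iloc[0]["t"] == 0
        assert tab.iloc[0]["p"] == 1

    def test_shared_variance_degenerates_to_pooled_t(self, rng):
        # every feature has the same sample variance: shrinkage is a no-op
        base = rng.normal(0, 1, size=8)
        base = (base - base.mean()) / base.std(ddof=1)
        expr = count_frame(np.add.outer(rng.normal(0, 3, 40), base))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=expr.columns)
        fit, tab = moderated_two_group_test(expr, groups, "a")
        # posterior variances all equal the common variance
        np.testing.assert_allclose(fit.s2_post, fit.s2, rtol=1e-6)
        pooled_t = fit.coefficients / (
            np.sqrt(fit.s2) * np.sqrt(1 / 4 + 1 / 4)
        )
        np.testing.assert_allclose(tab["t"], pooled_t, rtol=1e-6)

    def test_d0_recovery_from_scaled_chisq_prior(self, rng):
        # variances drawn from the scaled inverse-chi-square prior with d0=4
        d0_true, s02_true, df = 4.0, 1.0, 6
        n_feat = 500
        sigma2 = s02_true * d0_true / rng.chisquare(d0_true, n_feat)
        X = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_feat, 8))
        expr = count_frame(X)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=expr.columns)
        fit, _ = moderated_two_group_test(expr, groups, "a")
        assert abs(fit.d0 - d0_true) < 1.5
        lo = np.minimum(fit.s2, fit.s02)
        hi = np.maximum(fit.s2, fit.s02)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()

    def test_moderated_t_limits_in_d0(self, rng):
        s2 = rng.chisquare(5, 100) / 5
        coef = rng.normal(size=100)
        se = np.sqrt(0.5)
        # d0 -> 0: ordinary t with the feature's own variance
        post_small = posterior_variances(s2, 6, 1e-6, 2.0)
        np.testing.assert_allclose(
            coef / (np.sqrt(post_small) * se), coef / (np.sqrt(s2) * se), rtol=1e-5
        )
        # d0 -> inf: t pooled at the prior variance
        post_big = posterior_variances(s2, 6, 1e6, 2.0)
        np.testing.assert_allclose(
            coef / (np.sqrt(post_big) * se), coef / (np.sqrt(2.0) * se), rtol=1e-4
        )

    def test_ln_input_rescales_lfc_only(self, rng):
        expr = count_frame(rng.normal(0, 1, size=(50, 10)))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=expr.columns)
        _, ln_tab = moderated_two_group_test(expr, groups, "a", input_scale="ln")
        _, log2_tab = moderated_two_group_test(expr, groups, "a", input_scale="log2")
        np.testing.assert_allclose(ln_tab["lfc"], log2_tab["lfc"] / np.log(2))
        np.testing.assert_allclose(ln_tab["t"], log2_tab["t"])
        np.testing.assert_allclose(ln_tab["p"], log2_tab["p"])

    def test_small_group_rejected(self, rng):
        expr = count_frame(rng.normal(size=(5, 3)))
        groups = pd.Series(["a", "a", "b"], index=expr.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_two_group_test(expr, groups, "a")

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: limma lmFit + eBayes on the same matrix."""
        if shutil.which("Rscript") is None:
            raise RuntimeError("Rscript is required for the limma cross-check")
        expr = count_frame(rng.normal(5, 1, size=(80, 10)))
        expr.iloc[:10, 5:] += 1.5
        path = tmp_path / "expr.tsv"
        expr.to_csv(path, sep="\t")
        script = (
            'suppressMessages(library(limma));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'grp <- factor(c(rep("a",5), rep("b",5)), levels=c("a","b"));'
            'f <- eBayes(lmFit(x, model.matrix(~grp)));'
            'res <- topTable(f, coef=2, number=Inf, sort.by="none");'
            'cat(paste(res$t, collapse=","), "\\n");'
            'cat(paste(res$P.Value, collapse=","), "\\n");'
            'cat(f$df.prior, f$s2.prior, "\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lines = out.stdout.strip().splitlines()
        ref_t = np.array([float(v) for v in lines[0].split(",")])
        ref_p = np.array([float(v) for v in lines[1].split(",")])
        ref_d0, ref_s02 = map(float, lines[2].split())
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=expr.columns)
        fit, tab = moderated_two_group_test(expr, groups, "a", input_scale="log2")
        assert fit.d0 == pytest.approx(ref_d0, rel=1e-5)
        assert fit.s02 == pytest.approx(ref_s02, rel=1e-5)
        np.testing.assert_allclose(tab["t"], ref_t, atol=1e-8)
        np.testing.assert_allclose(tab["p"], ref_p, atol=1e-10)


class TestTrigammaInverse:
    @given(st.floats(min_value=1e-4, max_value=1e4))
    @settings(deadline=None, max_examples=50)
    def test_inverts_trigamma(self, y):
        x = trigamma_inverse(y)
        assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)


# ---------------------------------------------------------------------------
# BH adjustment and calls


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        mine = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_order_preserving_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj <= 1.0).all() and (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,adj_p,expected",
        [
            (1.6, 0.01, "up"),
            (-1.5, 0.049, "down"),  # LFC boundary inclusive
            (1.4, 0.001, "ns"),
            (1.5, 0.05, "ns"),  # alpha boundary exclusive
            (-2.0, 0.2, "ns"),
        ],
    )
    def test_threshold_conventions(self, lfc, adj_p, expected):
        table = pd.DataFrame({"lfc": [lfc], "t": [0.0], "p": [adj_p]})
        out = call_degs(table, lfc_cutoff=1.5, alpha=0.05)
        assert out["call"].iloc[0] == expected

    def test_inclusive_alpha_for_count_branch(self):
        table = pd.DataFrame({"lfc": [1.2], "t": [0.0], "p": [0.05]})
        out = call_degs(table, lfc_cutoff=1.0, alpha=0.05, alpha_inclusive=True)
        assert out["call"].iloc[0] == "up"


# ---------------------------------------------------------------------------
# count branch end to end


class TestDeCounts:
    def test_recovers_planted_mirnas(self):
        from progsub.simulate import MirnaSimParams, simulate_mirna_counts

        counts, groups, planted = simulate_mirna_counts(MirnaSimParams(seed=5))
        table = de_counts(counts, groups, "control")
        called = set(table.index[table["call"] != "ns"])
        recall = len(called & set(planted)) / len(planted)
        assert recall >= 0.9
        assert (table.loc[sorted(called & set(planted)), "lfc"] > 0).all()
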