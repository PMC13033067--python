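"""Two-group differential expression with empirical-Bayes moderation.

One engine serves two branches of the pipeline:

* the mRNA branch tests progression-normalized values directly
  (continuous, natural-log scale; no count filtering or TMM), contrasting
  the smaller subtype S against the reference subtype L with thresholds
  |log2 FC| >= 1.5 and BH-adjusted p < .05;
* the miRNA branch runs the count machinery — expression filtering,
  TMM normalization, log2-CPM with a mean-variance precision weighting —
  and calls significance at |log2 FC| >= 1 and BH-adjusted p <= .05.

The moderation follows the classic empirical-Bayes recipe: per-feature
residual variances s_g^2 with d_g degrees of freedom are shrunk toward a
prior variance s0^2 with prior degrees of freedom d0, both estimated by
matching the moments of log s_g^2 to a scaled-F distribution; the
moderated t uses the posterior variance and d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger("progsub")

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# count preprocessing (miRNA branch)


def filter_by_expression(
    counts: pd.DataFrame,
    groups: pd.Series,
    *,
    min_count: float = 10.0,
    min_total_count: float = 15.0,
) -> pd.Index:
    """Feature filter for count matrices given a group design.

    Retains features whose CPM exceeds the cutoff implied by ``min_count``
    at the median library size in at least as many samples as the smallest
    group holds, and whose total count reaches ``min_total_count``.
    """
    groups = pd.Series(groups).reindex(counts.columns)
    sizes = groups.value_counts()
    if (sizes == 0).any() or groups.isna().any():
        raise ValueError("every sample must belong to a non-empty group")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    median_lib = float(np.median(lib))
    cpm_cutoff = min_count / median_lib * 1e6
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    min_group = int(sizes.min())
    # small tolerance mirrors the rounding slack of the reference rule
    keep_cpm = (cpm >= cpm_cutoff).sum(axis=1) >= min_group
    keep_total = counts.sum(axis=1).to_numpy(dtype=float) >= min_total_count
    return counts.index[keep_cpm & keep_total]


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geo-mean 1)."""

    lib_size: pd.Series
    factors: pd.Series

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if (f <= 0).any():
            raise ValueError("TMM factors must be positive")
        if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")


def _tmm_pair(
    y: np.ndarray, yr: np.ndarray, n: float, nr: float,
    *, trim_m: float = 0.30, trim_a: float = 0.05,
) -> float:
    """Doubly trimmed weighted mean of M-values of one sample vs the reference."""
    ok = (y > 0) & (yr > 0)
    y, yr = y[ok], yr[ok]
    if y.size == 0:
        return 1.0
    p, pr = y / n, yr / nr
    M = np.log2(p / pr)
    A = 0.5 * np.log2(p * pr)
    # asymptotic (delta-method) variance of M, used as inverse weights
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)
    finite = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
    M, A, w = M[finite], A[finite], w[finite]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    nkeep = M.size
    lo_m = np.floor(nkeep * trim_m) + 1
    hi_m = nkeep - np.floor(nkeep * trim_m)
    lo_a = np.floor(nkeep * trim_a) + 1
    hi_a = nkeep - np.floor(nkeep * trim_a)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_norm_factors(counts: pd.DataFrame) -> NormFactors:
    """Trimmed-mean-of-M-values between-sample normalization factors.

    Reference sample: the one whose upper-quartile CPM is closest to the
    mean upper-quartile. M-values are trimmed 30% and A-values 5% (the
    Robinson–Oshlack defaults); the weighted mean uses inverse
    delta-method variances. Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"all-zero library(ies): {bad}")
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [_tmm_pair(Y[:, j], Y[:, ref], lib[j], lib[ref]) for j in range(Y.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        lib_size=pd.Series(lib, index=counts.columns, name="lib_size"),
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
    )


def log_cpm(
    counts: pd.DataFrame, norm_factors: NormFactors | None = None, *, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count offset.

    log2((count + prior) / (lib_size * factor + 2 * prior) * 1e6)
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if norm_factors is None:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        fac = np.ones_like(lib)
    else:
        lib = norm_factors.lib_size.reindex(counts.columns).to_numpy(dtype=float)
        fac = norm_factors.factors.reindex(counts.columns).to_numpy(dtype=float)
    eff = lib * fac + 2.0 * prior
    out = np.log2((counts.to_numpy(dtype=float) + prior) / eff[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes machinery


def trigamma_inverse(y: float, *, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log variances to a scaled F distribution.

    Returns the prior degrees of freedom ``d0`` (may be ``inf``) and the
    prior variance ``s0^2`` such that s_g^2 ~ s0^2 * F(d_g, d0)
    approximately.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive finite variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # log-variances underdispersed relative to chi-square: infinitely
        # strong prior, located at the mean observed variance
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    return float(d0), float(s02)


def posterior_variances(s2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    """Shrink residual variances toward the prior: (d0 s0^2 + d s^2)/(d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + df * s2) / (d0 + df)


@dataclass
class ModeratedFit:
    """Hyperparameters and per-feature quantities of the moderated fit."""

    coefficients: pd.Series  # test-minus-reference group difference (input scale)
    s2: pd.Series  # residual variances
    df_residual: float
    d0: float  # prior degrees of freedom (inf allowed)
    s02: float  # prior variance
    s2_post: pd.Series  # posterior variances
    stdev_unscaled: float  # sqrt(1/n_test + 1/n_ref)


def moderated_two_group_test(
    expr: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    *,
    input_scale: str = "log2",
    weights: pd.DataFrame | None = None,
) -> tuple[ModeratedFit, pd.DataFrame]:
    """Empirical-Bayes moderated t-test of test group vs reference group.

    ``expr`` is features x samples on a log scale. The contrast is
    oriented test minus reference (the reference subtype is the baseline).
    ``input_scale="ln"`` declares natural-log input (as produced by the
    progression transform); reported log-fold-changes are then converted
    to the log2 scale so the usual thresholds apply. The statistics are
    scale-invariant, so the conversion affects only the ``lfc`` column.

    Optional ``weights`` (same shape as ``expr``) enable the
    mean-variance precision weighting of the count branch.
    """
    if input_scale not in ("log2", "ln"):
        raise ValueError("input_scale must be 'log2' or 'ln'")
    groups = pd.Series(groups).reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    if reference_group not in set(levels):
        raise ValueError(f"reference group {reference_group!r} not among {list(levels)}")
    test_group = [g for g in levels if g != reference_group][0]
    ref_mask = (groups == reference_group).to_numpy()
    test_mask = ~ref_mask
    n_ref, n_test = int(ref_mask.sum()), int(test_mask.sum())
    if min(n_ref, n_test) < 2:
        raise ValueError("each group needs >= 2 samples (no residual df otherwise)")

    Y = expr.to_numpy(dtype=float)
    if weights is None:
        mean_ref = Y[:, ref_mask].mean(axis=1)
        mean_test = Y[:, test_mask].mean(axis=1)
        fitted = np.where(test_mask[None, :], mean_test[:, None], mean_ref[:, None])
        resid = Y - fitted
        df_resid = n_ref + n_test - 2
        s2 = (resid ** 2).sum(axis=1) / df_resid
        stdev_unscaled = np.sqrt(1.0 / n_test + 1.0 / n_ref)
        se_unscaled = np.full(Y.shape[0], stdev_unscaled)
    else:
        W = weights.to_numpy(dtype=float)
        if W.shape != Y.shape or (W <= 0).any():
            raise ValueError("weights must be positive and match expr's shape")
        sw_ref = W[:, ref_mask].sum(axis=1)
        sw_test = W[:, test_mask].sum(axis=1)
        mean_ref = (W[:, ref_mask] * Y[:, ref_mask]).sum(axis=1) / sw_ref
        mean_test = (W[:, test_mask] * Y[:, test_mask]).sum(axis=1) / sw_test
        fitted = np.where(test_mask[None, :], mean_test[:, None], mean_ref[:, None])
        resid = Y - fitted
        df_resid = n_ref + n_test - 2
        s2 = (W * resid ** 2).sum(axis=1) / df_resid
        se_unscaled = np.sqrt(1.0 / sw_test + 1.0 / sw_ref)
        stdev_unscaled = float(np.median(se_unscaled))

    coef = mean_test - mean_ref
    pos = s2 > 0
    if pos.sum() >= 2:
        d0, s02 = fit_f_dist(s2[pos], df_resid)
    else:  # degenerate: (almost) no residual variability anywhere
        d0, s02 = np.inf, float(s2[pos].mean()) if pos.any() else 0.0
    s2_post = posterior_variances(s2, df_resid, d0, s02)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (np.sqrt(s2_post) * se_unscaled)
    t = np.where(coef == 0, 0.0, t)
    # total df capped at the pooled residual df of all features
    df_total = min(d0 + df_resid, len(s2) * df_resid)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(coef == 0, 1.0, p)

    lfc = coef / LN2 if input_scale == "ln" else coef
    table = pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p}, index=expr.index
    )
    fit = ModeratedFit(
        coefficients=pd.Series(coef, index=expr.index),
        s2=pd.Series(s2, index=expr.index),
        df_residual=float(df_resid),
        d0=d0,
        s02=s02,
        s2_post=pd.Series(s2_post, index=expr.index),
        stdev_unscaled=float(stdev_unscaled),
    )
    logger.debug(
        "moderated fit: %s vs %s (ref), d0=%.3g, s0^2=%.3g", test_group,
        reference_group, d0, s02,
    )
    return fit, table


# ---------------------------------------------------------------------------
# multiple testing and calls


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, scale p_(i) by n/i, enforce monotonicity by a
    cumulative minimum from the largest rank, cap at 1, restore order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def call_degs(
    table: pd.DataFrame,
    *,
    lfc_cutoff: float = 1.5,
    alpha: float = 0.05,
    alpha_inclusive: bool = False,
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and up/down/ns calls to a DE table.

    The fold-change cutoff is inclusive on both sides and the adjusted-p
    threshold is exclusive by default (``adj_p < alpha``); the count
    branch passes ``alpha_inclusive=True`` for its ``adj_p <= alpha``
    convention.
    """
    out = table.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    sig = out["adj_p"] <= alpha if alpha_inclusive else out["adj_p"] < alpha
    call = np.where(
        sig & (out["lfc"] >= lfc_cutoff),
        "up",
        np.where(sig & (out["lfc"] <= -lfc_cutoff), "down", "ns"),
    )
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# pipeline-facing wrappers


def de_continuous(
    expr: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    *,
    input_scale: str = "ln",
    lfc_cutoff: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """mRNA branch: moderated test on continuous (progression) values."""
    _, table = moderated_two_group_test(
        expr, groups, reference_group, input_scale=input_scale
    )
    return call_degs(table, lfc_cutoff=lfc_cutoff, alpha=alpha)


def _voom_weights(
    logcpm: pd.DataFrame, groups: pd.Series, lib_eff: np.ndarray
) -> pd.DataFrame:
    """Mean-variance precision weights (lowess trend of sqrt residual sd)."""
    groups = pd.Series(groups).reindex(logcpm.columns)
    Y = logcpm.to_numpy(dtype=float)
    fitted = np.empty_like(Y)
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        fitted[:, mask] = Y[:, mask].mean(axis=1)[:, None]
    df = Y.shape[1] - len(pd.unique(groups))
    sd = np.sqrt(((Y - fitted) ** 2).sum(axis=1) / df)
    mean_expr = Y.mean(axis=1)
    trend = lowess(np.sqrt(sd), mean_expr, frac=0.5, return_sorted=True)
    xs, ys = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    # per-observation predicted log-cpm: group mean shifted by library depth
    shift = np.log2(lib_eff / np.exp(np.mean(np.log(lib_eff))))
    pred = fitted + shift[None, :]
    w = 1.0 / np.interp(pred, xs, ys) ** 4
    return pd.DataFrame(w, index=logcpm.index, columns=logcpm.columns)


def de_counts(
    counts: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    *,
    min_count: float = 10.0,
    lfc_cutoff: float = 1.0,
    alpha: float = 0.05,
    voom: bool = True,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Count branch: filter, TMM-normalize, log2-CPM, moderated test.

    Defaults implement the miRNA analysis: ``min.count = 10`` filtering,
    TMM factors, precision-weighted moderated test, significance at
    BH-adjusted p <= .05 and |log2 FC| >= 1.
    """
    kept = filter_by_expression(counts, groups, min_count=min_count)
    counts = counts.loc[kept]
    nf = tmm_norm_factors(counts)
    y = log_cpm(counts, nf, prior=prior)
    weights = None
    if voom:
        lib_eff = (nf.lib_size * nf.factors).to_numpy(dtype=float)
        weights = _voom_weights(y, groups, lib_eff)
    _, table = moderated_two_group_test(
        y, groups, reference_group, input_scale="log2", weights=weights
    )
    return call_degs(
        table, lfc_cutoff=lfc_cutoff, alpha=alpha, alpha_inclusive=True
    )
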