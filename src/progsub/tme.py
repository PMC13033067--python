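"""Tumor-microenvironment analyses: reference-signature deconvolution of
immune cell fractions, subtype comparison of fractions, and the
immune–gene association layer (Spearman correlations, gene-set scores,
purity-adjusted linear models).

Deconvolution models each bulk sample as a non-negative combination of
reference cell-type expression profiles with the combination weights
constrained to sum to at most 1; the remainder (``otherCells``) absorbs
tumor and uncharacterized cell content and doubles as a purity covariate
in the association models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .de import bh_adjust

logger = logging.getLogger("progsub")

OTHER_CELLS = "otherCells"


def _validate_signature(sig: pd.DataFrame) -> pd.DataFrame:
    if sig.columns.has_duplicates:
        raise ValueError("cell-type names must be unique")
    if (sig.to_numpy(dtype=float) < 0).any():
        raise ValueError("signature expression must be non-negative")
    zero_cols = sig.columns[(sig != 0).sum(axis=0) == 0].tolist()
    if zero_cols:
        raise ValueError(f"all-zero signature column(s): {zero_cols}")
    return sig.astype(float)


class SignatureDeconvolver(BaseEstimator):
    """Constrained-regression estimation of cell-type fractions.

    For each bulk sample the solver minimizes

        sum_g w_g (b_g - sum_c f_c S_gc)^2   s.t. f_c >= 0, sum_c f_c <= 1

    over the genes shared between bulk and signature, after rescaling the
    bulk column and every signature column to a common total (which makes
    the estimates invariant to sequencing depth). The sum constraint is
    handled by a non-negative slack component appended to the design; the
    slack is reported as ``otherCells`` so every row of the fraction
    table sums to exactly 1.

    Parameters
    ----------
    signature : DataFrame, genes x cell types, non-negative.
    gene_weights : optional Series of per-gene weights w_g (default 1);
        inverse-variance weights are a typical choice.
    cell_weights : optional per-cell-type multipliers applied to the
        signature columns (mRNA-per-cell renormalization); default 1.
    """

    def __init__(self, signature: pd.DataFrame, gene_weights=None, cell_weights=None,
                 penalty: float = 1e4):
        self.signature = signature
        self.gene_weights = gene_weights
        self.cell_weights = cell_weights
        self.penalty = penalty

    def fit(self, X=None, y=None):
        sig = _validate_signature(self.signature)
        if self.cell_weights is not None:
            sig = sig * pd.Series(self.cell_weights).reindex(sig.columns)
        self.signature_ = sig
        return self

    def transform(self, bulk: pd.DataFrame) -> pd.DataFrame:
        """Estimate fractions for a genes x samples bulk matrix (linear scale)."""
        if not hasattr(self, "signature_"):
            self.fit()
        sig = self.signature_
        shared = bulk.index.intersection(sig.index)
        if len(shared) == 0:
            raise ValueError("no genes shared between bulk matrix and signature")
        B = bulk.loc[shared].to_numpy(dtype=float)
        if (B < 0).any():
            raise ValueError("bulk expression must be non-negative (linear scale)")
        S = sig.loc[shared].to_numpy(dtype=float)
        # rescale every column (bulk and signature) to a common total
        col_sums = S.sum(axis=0)
        if (col_sums == 0).any():
            bad = sig.columns[col_sums == 0].tolist()
            raise ValueError(f"signature column(s) all zero on shared genes: {bad}")
        S = S / col_sums[None, :]
        bulk_sums = B.sum(axis=0)
        if (bulk_sums == 0).any():
            bad = bulk.columns[bulk_sums == 0].tolist()
            raise ValueError(f"all-zero bulk sample(s): {bad}")
        B = B / bulk_sums[None, :]
        if self.gene_weights is not None:
            w = pd.Series(self.gene_weights).reindex(shared).to_numpy(dtype=float)
            if np.isnan(w).any() or (w < 0).any():
                raise ValueError("gene weights must be non-negative and cover shared genes")
        else:
            w = np.ones(len(shared))
        sqw = np.sqrt(w)
        n_cells = S.shape[1]
        # design: weighted signature plus slack column; a heavily weighted
        # extra row enforces sum(f) + slack = 1
        A = np.zeros((len(shared) + 1, n_cells + 1))
        A[:-1, :n_cells] = sqw[:, None] * S
        A[-1, :] = self.penalty
        rows = []
        for j in range(B.shape[1]):
            target = np.concatenate([sqw * B[:, j], [self.penalty]])
            sol, _ = nnls(A, target)
            f, slack = sol[:n_cells], sol[n_cells]
            total = f.sum() + slack
            if total <= 0:
                raise RuntimeError("degenerate deconvolution solution")
            rows.append(np.concatenate([f, [slack]]) / total)
        out = pd.DataFrame(
            rows, index=bulk.columns, columns=list(sig.columns) + [OTHER_CELLS]
        )
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-8)
        return out

    def fit_transform(self, bulk: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit().transform(bulk)


def deconvolve_fractions(
    bulk: pd.DataFrame, signature: pd.DataFrame, *, gene_weights=None
) -> pd.DataFrame:
    """Per-sample non-negative cell-type fractions plus ``otherCells``."""
    return SignatureDeconvolver(signature, gene_weights=gene_weights).fit_transform(bulk)


def compare_fractions(fractions: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Kruskal–Wallis comparison of every cell-type fraction across subtypes.

    Returns per cell type the rank-based H statistic (tie-corrected), the
    raw p-value and the BH-adjusted p across the cell types tested.
    """
    labels = pd.Series(labels).reindex(fractions.index)
    if labels.isna().any():
        raise ValueError("every sample in the fraction table needs a subtype label")
    groups = [g for g, _ in labels.groupby(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes to compare")
    records = []
    for cell in fractions.columns:
        arrays = [fractions.loc[labels == g, cell].to_numpy(dtype=float) for g in groups]
        if any(a.size == 0 for a in arrays):
            raise ValueError("empty subtype group")
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):  # scipy rejects the all-ties case
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*arrays)
        records.append({"cell_type": cell, "H": float(h), "p": float(p)})
    out = pd.DataFrame(records).set_index("cell_type")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman_assoc(
    fraction: pd.Series, expr: pd.DataFrame, features
) -> pd.DataFrame:
    """Tie-aware Spearman correlation of one cell fraction with each feature.

    ``expr`` is features x samples, matched to the fraction's samples.
    Constant vectors leave the correlation undefined: the record is
    flagged and excluded from the BH family.
    """
    fraction = pd.Series(fraction)
    samples = [s for s in expr.columns if s in fraction.index]
    if len(samples) < 4:
        raise ValueError("Spearman association needs at least 4 matched samples")
    f = fraction.reindex(samples).to_numpy(dtype=float)
    records = []
    for feat in features:
        if feat not in expr.index:
            raise KeyError(f"feature {feat!r} absent from expression matrix")
        x = expr.loc[feat, samples].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(f == f[0]):
            records.append({"feature": feat, "rho": np.nan, "p": np.nan, "defined": False})
            continue
        rho, p = stats.spearmanr(f, x)
        records.append({"feature": feat, "rho": float(rho), "p": float(p), "defined": True})
    out = pd.DataFrame(records).set_index("feature")
    out["adj_p"] = np.nan
    mask = out["defined"].to_numpy()
    if mask.any():
        out.loc[mask, "adj_p"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def gene_set_score(expr: pd.DataFrame, genes) -> pd.Series:
    """Per-sample mean of gene-wise z-scored expression over a gene set.

    The z-scoring is population-style (ddof = 0, scipy's default); scores
    consequently average to ~0 across samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("gene-set scoring needs at least 2 samples")
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("none of the set genes are present in the expression matrix")
    sub = expr.loc[present].to_numpy(dtype=float)
    z = stats.zscore(sub, axis=1, ddof=0)
    z = np.nan_to_num(z, nan=0.0)  # constant genes contribute 0
    return pd.Series(z.mean(axis=0), index=expr.columns, name="score")


@dataclass
class PurityModelResult:
    table: pd.DataFrame  # per response: beta/p for subtype and purity, adj_p


def purity_adjusted_model(
    responses: pd.DataFrame,
    subtype_indicator: pd.Series,
    other_cells: pd.Series,
) -> pd.DataFrame:
    """OLS fits ``response ~ subtype + otherCells`` per response row.

    ``responses`` is responses x samples (gene expression rows or gene-set
    score rows); the subtype indicator is 0/1 (1 = tested subtype) and
    ``other_cells`` is the deconvolution remainder used as a purity
    covariate. Two-sided coefficient t-tests; BH across the response
    family, separately per coefficient.
    """
    samples = list(responses.columns)
    subtype = pd.Series(subtype_indicator).reindex(samples).to_numpy(dtype=float)
    purity = pd.Series(other_cells).reindex(samples).to_numpy(dtype=float)
    if np.isnan(subtype).any() or np.isnan(purity).any():
        raise ValueError("subtype indicator and otherCells must cover all samples")
    n = len(samples)
    if n <= 3:
        raise ValueError("need more than 3 samples to fit the two-covariate model")
    X = sm.add_constant(np.column_stack([subtype, purity]), has_constant="add")
    if np.linalg.matrix_rank(X) < 3:
        detail = "otherCells is constant" if np.ptp(purity) == 0 else (
            "subtype indicator is constant" if np.ptp(subtype) == 0
            else "subtype and otherCells are collinear"
        )
        raise ValueError(f"rank-deficient design: {detail}")
    records = []
    for resp in responses.index:
        y = responses.loc[resp].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        records.append(
            {
                "response": resp,
                "beta_subtype": float(fit.params[1]),
                "p_subtype": float(fit.pvalues[1]),
                "beta_purity": float(fit.params[2]),
                "p_purity": float(fit.pvalues[2]),
            }
        )
    out = pd.DataFrame(records).set_index("response")
    out["adj_p_subtype"] = bh_adjust(out["p_subtype"].to_numpy())
    out["adj_p_purity"] = bh_adjust(out["p_purity"].to_numpy())
    return out
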