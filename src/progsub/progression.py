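"""Progression-tracking normalization of late-stage expression.

The transform references every late-stage (advanced) tumor profile against
the average early-stage profile of the same cohort: for gene *i* with early
matrix ``E`` over ``r`` early samples,

    m_i = (1/r) * sum_k E[i, k]

and each late-stage sample column ``A[:, j]`` becomes the natural-log
ratio

    L[i, j] = ln(A[i, j] / m_i).

Entries near 0 of ``L`` mean a gene has not moved since the early stage;
negative entries mean accumulated down-regulation along progression.
Inputs are expected on the count-plus-one scale (all entries >= 1) so the
ratio and logarithm are always defined — no pseudocount is added here.

``L`` is on the natural-log scale exactly as defined; any base conversion
for fold-change thresholds is owned by the differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

MIN_POSITIVE = 1.0  # count-plus-one floor protecting the ratio


@dataclass
class ReferenceMeans:
    """Per-gene mean early-stage expression (the denominator of the ratio)."""

    m: pd.Series  # indexed by gene id, strictly positive
    r: int  # number of early samples averaged

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("reference requires at least one early sample")
        if (self.m <= 0).any():
            raise ValueError("reference means must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.m.index)


def compute_reference_means(early: pd.DataFrame) -> ReferenceMeans:
    """Average each gene across the early-stage samples (genes x samples in).

    Raises if any entry is below the count-plus-one floor, which would let
    zeros or negatives reach the later ratio.
    """
    if early.shape[1] < 1:
        raise ValueError("early matrix has no samples")
    values = early.to_numpy(dtype=float)
    if values.min() < MIN_POSITIVE:
        i, j = map(int, np.argwhere(values < MIN_POSITIVE)[0])
        raise ValueError(
            f"early entry {values[i, j]} at gene {early.index[i]!r}, sample "
            f"{early.columns[j]!r} is below the minimum positive bound {MIN_POSITIVE}"
        )
    return ReferenceMeans(m=early.mean(axis=1), r=early.shape[1])


def progression_transform(late: pd.DataFrame, ref: ReferenceMeans) -> pd.DataFrame:
    """Natural-log ratio of each late-stage sample against the early means.

    Genes are aligned by identifier (not position); a mismatch between the
    two gene sets is an error listing the symmetric difference, never a
    silent drop. Output row order follows the late matrix.
    """
    late_genes = set(late.index)
    ref_genes = set(ref.m.index)
    if late_genes != ref_genes:
        only_late = sorted(late_genes - ref_genes)
        only_ref = sorted(ref_genes - late_genes)
        raise ValueError(
            "gene sets of late matrix and reference differ; "
            f"only in late: {only_late[:10]}, only in reference: {only_ref[:10]}"
        )
    values = late.to_numpy(dtype=float)
    if values.min() < MIN_POSITIVE:
        i, j = map(int, np.argwhere(values < MIN_POSITIVE)[0])
        raise ValueError(
            f"late entry {values[i, j]} at gene {late.index[i]!r}, sample "
            f"{late.columns[j]!r} is below the minimum positive bound {MIN_POSITIVE}"
        )
    m = ref.m.reindex(late.index).to_numpy(dtype=float)
    L = np.log(values / m[:, None])
    return pd.DataFrame(L, index=late.index, columns=late.columns)


class ProgressionNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: fit on early samples, transform late ones.

    Follows the sklearn orientation (samples x genes). ``fit`` stores the
    per-gene early means; ``transform`` returns the natural-log ratios.

    Attributes
    ----------
    reference_means_ : ndarray of shape (n_genes,)
    n_reference_samples_ : int
    """

    def fit(self, X, y=None):
        X = self._validate_data(X, ensure_min_samples=1)
        if X.min() < MIN_POSITIVE:
            raise ValueError("all entries must be >= 1 (count-plus-one scale)")
        self.reference_means_ = X.mean(axis=0)
        self.n_reference_samples_ = X.shape[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_means_")
        X = self._validate_data(X, reset=False)
        if X.min() < MIN_POSITIVE:
            raise ValueError("all entries must be >= 1 (count-plus-one scale)")
        return np.log(X / self.reference_means_[None, :])

    def _validate_data(self, X, reset=True, **kwargs):  # pragma: no cover - shim
        try:
            from sklearn.utils.validation import validate_data

            return validate_data(self, X=X, reset=reset, **kwargs)
        except ImportError:
            return super()._validate_data(X, reset=reset, **kwargs)
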