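"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-stage bulk RNA-seq tumor cohort: an
early-stage reference group and a late-stage group split into two latent
subtypes of unequal size (a larger subtype L and a smaller subtype S). A
block of genes is planted as down-regulated in the smaller subtype; gene
counts are negative-binomial with log-normally distributed gene means and
library sizes; bulk profiles are convex mixtures of a tumor profile and
immune cell-type reference signatures with recorded fractions; per-gene
somatic mutations are drawn Bernoulli at per-subtype frequencies. Every
piece of planted structure is returned as ground truth so each downstream
stage has a recovery test.

Default parameters match the cohort layout the pipeline is designed for:
47 early / 39 late samples, subtype sizes 23 and 16, 200 planted genes at
log2 fold change -2, and per-gene mutation frequencies in the range
reported for recurrently mutated colon-cancer genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MUTATION_FREQS = {
    # gene -> (frequency in larger subtype, frequency in smaller subtype)
    "APC": (0.83, 0.75),
    "TP53": (0.78, 0.50),
    "KRAS": (0.43, 0.44),
    "TTN": (0.26, 0.44),
    "SYNE1": (0.35, 0.12),
    "MUC16": (0.30, 0.12),
    "PIK3CA": (0.13, 0.19),
    "SMAD4": (0.09, 0.19),
}

VARIANT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Splice_Site",
)

CELL_TYPES = ("CD4_Tcells", "CD8_Tcells", "Bcells", "NKcells", "Monocytes", "Endothelial")


@dataclass
class SimulationParams:
    """Knobs of the cohort generator.

    ``deg_lfc`` is the planted tumor-level log2 effect in the smaller
    subtype (negative = down-regulated); ``immune_shift`` is the increase
    in mean T-cell fraction in the smaller subtype; ``n_cell_types = 0``
    disables immune mixing entirely (pure tumor profiles).

    All late-stage samples additionally share an accumulated-progression
    program: ``n_progression`` genes shifted by ``progression_lfc`` log2
    units (random sign per gene) with a per-sample magnitude drawn
    log-normal(0, ``progression_scale_sd``). This is the common
    early-to-late expression change the log-ratio transform is built to
    expose; it gives every late sample a coherent direction in log-ratio
    space (samples progress to varying depths along one axis), on top of
    which the subtype-specific block separates the two subtypes.
    """

    n_genes: int = 2000
    n_early: int = 47
    n_late: int = 39
    subtype_sizes: tuple[int, int] = (23, 16)
    n_deg: int = 200
    deg_lfc: float = -2.0
    n_progression: int = 300
    progression_lfc: float = 1.0
    progression_scale_sd: float = 0.15
    nb_dispersion: float = 0.08
    libsize_log_sd: float = 0.05
    n_cell_types: int = 4
    immune_fraction_mean: float = 0.2
    immune_shift: float = 0.08
    mutation_freqs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_FREQS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subtype_sizes) != self.n_late:
            raise ValueError(
                f"subtype_sizes {self.subtype_sizes} must sum to n_late={self.n_late}"
            )
        if len(self.subtype_sizes) != 2 or min(self.subtype_sizes) < 1:
            raise ValueError("exactly two non-empty subtypes are required")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ValueError("n_deg must lie in [0, n_genes]")
        if self.n_deg + self.n_progression > self.n_genes:
            raise ValueError("n_deg + n_progression may not exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.n_cell_types <= len(CELL_TYPES):
            raise ValueError(f"n_cell_types must be in [0, {len(CELL_TYPES)}]")
        if not 0 <= self.immune_fraction_mean < 1:
            raise ValueError("immune_fraction_mean must lie in [0, 1)")
        for gene, (f1, f2) in self.mutation_freqs.items():
            if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
                raise ValueError(f"mutation frequencies for {gene!r} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    subtype_labels: pd.Series  # late sample -> "L" / "S"
    deg_genes: list[str]
    progression_genes: list[str]
    fractions: pd.DataFrame  # samples x (cell types + otherCells), sums to 1
    signature: pd.DataFrame  # genes x cell types (linear scale)
    mutations: pd.DataFrame  # the planted MAF


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + disp * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(params: SimulationParams):
    """Generate one cohort; returns (early, late, phenotypes, maf, signature, truth).

    Expression matrices are genes x samples on the count-plus-one scale
    (every entry >= 1), matching what the progression normalization
    expects. Identical parameters and seed give byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    early_ids = [f"E{i + 1:03d}" for i in range(params.n_early)]
    late_ids = [f"A{i + 1:03d}" for i in range(params.n_late)]

    base_mean = np.exp(rng.normal(4.0, 1.2, size=params.n_genes))

    n_large, n_small = params.subtype_sizes
    labels = np.array(["L"] * n_large + ["S"] * n_small)
    rng.shuffle(labels)
    subtype_labels = pd.Series(labels, index=late_ids, name="subtype")

    special = rng.choice(
        params.n_genes, size=params.n_deg + params.n_progression, replace=False
    )
    deg_idx = special[: params.n_deg]
    prog_idx = special[params.n_deg:]
    deg_genes = [genes[i] for i in sorted(deg_idx)]
    prog_genes = [genes[i] for i in sorted(prog_idx)]

    # tumor-level mean per gene per sample (early baseline; planted effect in S)
    early_mu = np.tile(base_mean[:, None], (1, params.n_early))
    late_mu = np.tile(base_mean[:, None], (1, params.n_late))
    s_mask = (labels == "S")
    fold = 2.0 ** params.deg_lfc
    late_mu[np.ix_(sorted(deg_idx), np.flatnonzero(s_mask))] *= fold

    # shared accumulated-progression program: one log-fold direction, with a
    # per-sample depth factor (how far along progression the tumor is)
    if params.n_progression:
        prog_sign = rng.choice([-1.0, 1.0], size=params.n_progression)
        depth = np.exp(rng.normal(0.0, params.progression_scale_sd, size=params.n_late))
        prog_effect = np.exp(
            np.log(2.0)
            * params.progression_lfc
            * prog_sign[:, None]
            * depth[None, :]
        )
        late_mu[prog_idx, :] *= prog_effect

    # immune reference signatures: baseline profile plus strong markers
    cell_types = list(CELL_TYPES[: params.n_cell_types])
    signature = pd.DataFrame(index=genes, columns=cell_types, dtype=float)
    marker_pool = [i for i in range(params.n_genes) if i not in set(special)]
    marker_ids = rng.choice(marker_pool, size=30 * len(cell_types), replace=False) if cell_types else np.array([], dtype=int)
    for c, cell in enumerate(cell_types):
        profile = base_mean * np.exp(rng.normal(0.0, 0.5, size=params.n_genes))
        profile[marker_ids[c * 30:(c + 1) * 30]] *= 8.0
        signature[cell] = profile
    all_ids = early_ids + late_ids

    if cell_types:
        # mixing happens in linear (non-log) space with signature columns on
        # the tumor profile's total scale, so recorded fractions match the
        # deconvolution model's convention
        sig_lin = signature.to_numpy()
        sig_scaled = sig_lin / sig_lin.sum(axis=0)[None, :] * base_mean.sum()
        fractions = np.zeros((len(all_ids), len(cell_types) + 1))
        mixed_mu = np.concatenate([early_mu, late_mu], axis=1)
        for j, sample in enumerate(all_ids):
            total = float(np.clip(rng.normal(params.immune_fraction_mean, 0.03), 0.02, 0.6))
            parts = rng.dirichlet(np.ones(len(cell_types)) * 30.0)
            f = parts * total
            if sample in late_ids and subtype_labels[sample] == "S":
                for t_cell in ("CD4_Tcells", "CD8_Tcells"):
                    if t_cell in cell_types:
                        f[cell_types.index(t_cell)] += params.immune_shift / 2.0
            f = np.clip(f, 0.0, None)
            if f.sum() >= 0.95:
                f = f / f.sum() * 0.95
            fractions[j, : len(cell_types)] = f
            fractions[j, -1] = 1.0 - f.sum()
            mixed_mu[:, j] = fractions[j, -1] * mixed_mu[:, j] + sig_scaled @ f
        fractions = pd.DataFrame(
            fractions, index=all_ids, columns=cell_types + ["otherCells"]
        )
        early_mu = mixed_mu[:, : params.n_early]
        late_mu = mixed_mu[:, params.n_early:]
    else:
        fractions = pd.DataFrame(
            np.ones((len(all_ids), 1)), index=all_ids, columns=["otherCells"]
        )

    lib_early = np.exp(rng.normal(0.0, params.libsize_log_sd, size=params.n_early))
    lib_late = np.exp(rng.normal(0.0, params.libsize_log_sd, size=params.n_late))
    early_counts = _nb_draw(rng, early_mu * lib_early[None, :], params.nb_dispersion)
    late_counts = _nb_draw(rng, late_mu * lib_late[None, :], params.nb_dispersion)

    early = pd.DataFrame(early_counts + 1.0, index=genes, columns=early_ids)
    late = pd.DataFrame(late_counts + 1.0, index=genes, columns=late_ids)

    phenotypes = pd.DataFrame(
        {
            "sample_id": all_ids,
            "stage": ["early"] * params.n_early + ["late"] * params.n_late,
            "age": rng.integers(40, 76, size=len(all_ids)),
            "diagnosis": "adenocarcinoma",
        }
    )

    maf_rows = []
    for gene, (f_large, f_small) in params.mutation_freqs.items():
        for sample in late_ids:
            freq = f_large if subtype_labels[sample] == "L" else f_small
            if rng.random() < freq:
                n_variants = 2 if rng.random() < 0.2 else 1
                for _ in range(n_variants):
                    maf_rows.append(
                        {
                            "Hugo_Symbol": gene,
                            "Tumor_Sample_Barcode": sample,
                            "Variant_Classification": VARIANT_CLASSES[
                                int(rng.integers(0, len(VARIANT_CLASSES)))
                            ],
                            "Variant_Type": "SNP",
                        }
                    )
    maf = pd.DataFrame(
        maf_rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "Variant_Type",
        ],
    )

    truth = SyntheticTruth(
        subtype_labels=subtype_labels,
        deg_genes=deg_genes,
        progression_genes=prog_genes,
        fractions=fractions,
        signature=signature,
        mutations=maf.copy(),
    )
    return early, late, phenotypes, maf, signature, truth


@dataclass
class MirnaSimParams:
    """Small count matrix with planted up-regulated features in one group."""

    n_features: int = 500
    n_group1: int = 20
    n_group2: int = 20
    n_planted: int = 25
    lfc: float = 3.0
    nb_dispersion: float = 0.2
    libsize_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_planted <= self.n_features:
            raise ValueError("n_planted must lie in [0, n_features]")
        if min(self.n_group1, self.n_group2) < 2:
            raise ValueError("each group needs at least 2 samples")


def simulate_mirna_counts(params: MirnaSimParams):
    """Generate (counts, groups, planted feature ids) for the count branch.

    Group "case" carries the planted |log2 FC| >= 1 features (up-regulated
    by ``params.lfc``); group "control" is the baseline.
    """
    rng = np.random.default_rng(params.seed)
    features = [f"mir{i + 1:04d}" for i in range(params.n_features)]
    samples = [f"C{i + 1:03d}" for i in range(params.n_group1)] + [
        f"T{i + 1:03d}" for i in range(params.n_group2)
    ]
    groups = pd.Series(
        ["control"] * params.n_group1 + ["case"] * params.n_group2,
        index=samples,
        name="group",
    )
    base_mean = np.exp(rng.normal(4.0, 1.5, size=params.n_features))
    planted_idx = rng.choice(params.n_features, size=params.n_planted, replace=False)
    planted = [features[i] for i in sorted(planted_idx)]
    mu = np.tile(base_mean[:, None], (1, len(samples)))
    case_cols = np.flatnonzero((groups == "case").to_numpy())
    mu[np.ix_(sorted(planted_idx), case_cols)] *= 2.0 ** params.lfc
    lib = np.exp(rng.normal(0.0, params.libsize_log_sd, size=len(samples)))
    counts = _nb_draw(rng, mu * lib[None, :], params.nb_dispersion)
    return pd.DataFrame(counts, index=features, columns=samples), groups, planted
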