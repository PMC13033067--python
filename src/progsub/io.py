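"""Readers and writers for the tabular formats used across the pipeline.

All on-disk formats are plain tab-delimited text:

* expression matrices — genes as rows, samples as columns (UCSC Xena
  ``genomicMatrix`` convention), first column holds gene identifiers;
* phenotype tables — one row per sample with at least ``sample_id`` and
  ``stage`` columns;
* somatic mutation tables — GDC-dialect MAF, ``#``-prefixed comment lines
  ignored;
* gene-set collections — standard GMT (name, description, members).

Gene identifiers are treated as opaque strings throughout; no identifier
translation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("progsub")

STAGES = ("early", "late")

MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
)


# ---------------------------------------------------------------------------
# validation helpers


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what} identifier(s): {', '.join(map(str, dups))}")


def validate_expression(df: pd.DataFrame, *, count_plus_one: bool = False) -> pd.DataFrame:
    """Validate an expression matrix (genes x samples).

    Checks identifier uniqueness, absence of missing values and — when
    ``count_plus_one`` is set — that every entry is >= 1 (the scale produced
    by undoing a log2(count + 1) transform), which keeps downstream ratios
    and logarithms defined.
    """
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first offending cell for the error message
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric value {df[col].iloc[i]!r} at gene "
                    f"{df.index[i]!r}, sample {col!r}"
                )
        df = df.astype(float)
        values = df.to_numpy()
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if count_plus_one and values.min() < 1:
        i, j = map(int, np.argwhere(values < 1)[0])
        raise ValueError(
            f"entry {values[i, j]!r} at gene {df.index[i]!r}, sample "
            f"{df.columns[j]!r} is < 1; expected count-plus-one scale"
        )
    return df


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path,
    *,
    samples_as_rows: bool = False,
    delog2: bool = False,
    count_plus_one: bool = False,
) -> pd.DataFrame:
    """Read a tab-delimited expression matrix into a genes x samples frame.

    Parameters
    ----------
    samples_as_rows:
        Set when the file is transposed (samples in rows); the returned
        frame is always genes x samples.
    delog2:
        Undo a log2(x) transform (Xena matrices store log2(count + 1); with
        this flag the values come back on the count-plus-one scale).
    count_plus_one:
        Additionally enforce that all (possibly de-logged) entries are >= 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if samples_as_rows:
        df = df.T
    df = validate_expression(df)
    if delog2:
        df = np.power(2.0, df)
    return validate_expression(df.astype(float), count_plus_one=count_plus_one)


def write_expression(df: pd.DataFrame, path, *, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# phenotype tables


def read_phenotypes(path) -> pd.DataFrame:
    """Read a sample phenotype table (``sample_id``, ``stage``, extras).

    Stage labels are normalized case-insensitively to ``early``/``late``;
    any other stage string is rejected. Extra columns pass through
    untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "stage"):
        if col not in df.columns:
            raise ValueError(f"phenotype table is missing required column {col!r}")
    if df.empty:
        logger.warning("phenotype table %s contains a header but no samples", path)
        return df
    _check_unique(df["sample_id"], "sample")
    stage = df["stage"].astype(str).str.strip().str.lower()
    bad = sorted(set(stage[~stage.isin(STAGES)]))
    if bad:
        raise ValueError(
            f"unmapped stage value(s) {bad}; expected one of {list(STAGES)} (case-insensitive)"
        )
    df = df.copy()
    df["stage"] = stage
    if "age" in df.columns and (pd.to_numeric(df["age"], errors="coerce") < 0).any():
        raise ValueError("negative age in phenotype table")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF


def read_maf(path) -> pd.DataFrame:
    """Read a tab-delimited MAF file, skipping ``#`` comment lines."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file is missing mandatory column(s): {', '.join(missing)}")
    sub = df[list(MAF_REQUIRED_COLUMNS)]
    if sub.isna().any().any() or (sub == "").any().any():
        raise ValueError("MAF records must have all four mandatory fields non-empty")
    return df


def write_maf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{set_name: (description, members)}``.

    Genes repeated within a set are stored once (set semantics, original
    order kept); duplicated set names and short lines are errors.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} (line {lineno})")
            members = list(dict.fromkeys(g for g in genes if g))
            if not members:
                raise ValueError(f"gene set {name!r} (line {lineno}) is empty")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as handle:
        for name, (desc, genes) in sets.items():
            handle.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Thresholds, clustering/RFE options and the one seed that drives
    every source of randomness downstream."""

    lfc_cutoff: float = 1.5
    alpha: float = 0.05
    k_min: int = 2
    k_max: int = 10
    ward_variant: str = "D2"
    svm_c: float = 5.0
    n_splits: int = 7
    n_repeats: int = 7
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_cutoff <= 0:
            raise ValueError("lfc_cutoff must be positive")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
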