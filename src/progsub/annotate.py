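"""Over-representation analysis over user-supplied gene sets, MAF mutation
landscape summaries, and miRNA–target interaction filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger("progsub")


def hypergeometric_ora(
    query, sets: dict[str, tuple[str, list[str]]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of N genes, a set of K (after intersection with the
    universe) and a query of n, the p-value is P(X >= k) for the observed
    overlap k under Hypergeometric(N, K, n). BH adjustment runs across
    the tested sets. The universe defaults, at call sites, to all genes
    of the expression matrix; it must contain the query.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        missing = sorted(query - universe)[:10]
        raise ValueError(f"query genes absent from universe, e.g. {missing}")
    N, n = len(universe), len(query)
    records = []
    for name, (_, members) in sets.items():
        members_in = set(members) & universe
        K = len(members_in)
        if K == 0:
            continue
        overlap = sorted(members_in & query)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    if not records:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(records).set_index("set")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class MutationSummary:
    """Per-gene mutation tallies over a fixed cohort.

    ``table`` rows: altered-sample count, frequency as percent of the
    cohort, total variant count, multi-hit sample count (samples carrying
    >= 2 variants of the gene) and per-variant-classification counts.
    Gene order is by descending total variant count (top_n kept).
    """

    table: pd.DataFrame
    cohort_size: int
    top_n: int


def maf_summary(maf: pd.DataFrame, cohort_sample_ids, *, top_n: int = 20) -> MutationSummary:
    """Mutation-landscape summary of a MAF over a cohort.

    Cohort samples absent from the MAF count as unmutated; MAF samples
    outside the cohort are an error (the summary would silently mix
    cohorts otherwise).
    """
    cohort = list(dict.fromkeys(cohort_sample_ids))
    if not cohort:
        raise ValueError("cohort sample ids must be non-empty")
    n = len(cohort)
    if maf.empty:
        logger.warning("empty MAF: returning an all-zero mutation summary")
        table = pd.DataFrame(
            columns=["altered_samples", "frequency_pct", "total_variants", "multi_hit_samples"]
        )
        return MutationSummary(table=table, cohort_size=n, top_n=top_n)
    extra = sorted(set(maf["Tumor_Sample_Barcode"]) - set(cohort))
    if extra:
        raise ValueError(f"MAF contains samples outside the cohort: {extra[:10]}")
    per_gene_sample = (
        maf.groupby(["Hugo_Symbol", "Tumor_Sample_Barcode"]).size().rename("n_variants")
    )
    records = {}
    for gene, sub in per_gene_sample.groupby(level=0):
        records[gene] = {
            "altered_samples": int(len(sub)),
            "frequency_pct": float(len(sub) / n * 100.0),
            "total_variants": int(sub.sum()),
            "multi_hit_samples": int((sub >= 2).sum()),
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    vc = (
        maf.groupby(["Hugo_Symbol", "Variant_Classification"]).size().unstack(fill_value=0)
    )
    vc.columns = [f"n_{c}" for c in vc.columns]
    table = table.join(vc)
    table = table.sort_values(
        ["total_variants", "frequency_pct"], ascending=False, kind="mergesort"
    ).head(top_n)
    table.index.name = "gene"
    return MutationSummary(table=table, cohort_size=n, top_n=top_n)


FUNCTIONAL_MTI = "Functional MTI"


def mti_network(
    de_mirnas: pd.DataFrame, interactions: pd.DataFrame, target_genes
) -> pd.DataFrame:
    """Filter a miRNA–target interaction table to high-confidence edges.

    Keeps edges whose miRNA is significant in the differential table
    (``call`` != "ns"), whose target gene is in the supplied list
    (typically tumor suppressor genes and oncogenes), and whose support
    type is exactly ``"Functional MTI"`` — weaker evidence categories
    such as ``"Functional MTI (Weak)"`` are dropped. Idempotent; the
    output is always a subset of the input rows.
    """
    required = {"mirna", "target", "support_type"}
    missing = required - set(interactions.columns)
    if missing:
        raise ValueError(f"interaction table missing column(s): {sorted(missing)}")
    significant = set(de_mirnas.index[de_mirnas["call"] != "ns"])
    targets = set(target_genes)
    keep = (
        interactions["support_type"].eq(FUNCTIONAL_MTI)
        & interactions["mirna"].isin(significant)
        & interactions["target"].isin(targets)
    )
    return interactions.loc[keep].copy()
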