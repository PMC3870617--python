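"""Local gene-set over-representation analysis with the pipeline's filters.

The query list (in the pipeline: targets of up-regulated miRNAs, read as
down-regulated genes) is tested against each gene set with the exact
hypergeometric upper tail — the standard over-representation statistic —
then adjusted by Benjamini-Hochberg. A set is retained iff its overlap k is
at least 5 AND its raw p < 0.05 AND its BH-adjusted p < 0.05; the minimum-
overlap filter is applied before the FDR ranking by default (configurable).

The gene universe defaults to whatever the collection declares (in the
pipeline: all genes appearing in the prediction ensemble) rather than the
whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "hypergeom_enrich",
    "bh_fdr",
    "term_overlap",
    "read_gmt",
    "write_gmt",
]

MIN_OVERLAP = 5
FDR_THRESH = 0.05
P_THRESH = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets with categories and an explicit gene universe."""

    sets: dict[str, tuple[str, str, set[str]]]  # id -> (name, category, genes)
    universe: set[str]

    def __post_init__(self) -> None:
        restricted = {}
        for sid, (name, cat, genes) in self.sets.items():
            inside = genes & self.universe
            if not inside:
                raise ValueError(f"gene set {sid} has no member in the universe")
            restricted[sid] = (name, cat, inside)
        self.sets = restricted

    @property
    def categories(self) -> set[str]:
        return {cat for _, cat, _ in self.sets.values()}


def hypergeom_enrich(genes: set[str], collection: GeneSetCollection,
                     min_overlap: int = MIN_OVERLAP,
                     fdr_thresh: float = FDR_THRESH,
                     p_thresh: float = P_THRESH,
                     filter_before_fdr: bool = True) -> pd.DataFrame:
    """Exact hypergeometric over-representation of ``genes`` in each set.

    p(set) = P[X >= k] with X ~ Hypergeometric(N, K, n) where N is the
    universe size, K the set size, n the query size and k the overlap —
    the exact tail, no normal approximation. Query genes outside the
    universe are dropped with a warning. Returns a DataFrame indexed by set
    id with columns name, category, k, K, n, N, p, fdr_p, retained; sets
    removed by the minimum-overlap filter carry fdr_p = NaN when the filter
    runs before FDR.
    """
    if not genes:
        return pd.DataFrame(columns=["name", "category", "k", "K", "n", "N",
                                     "p", "fdr_p", "retained"])
    outside = genes - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped",
                      RuntimeWarning)
    query = genes & collection.universe
    N = len(collection.universe)
    n = len(query)

    rows = []
    for sid in sorted(collection.sets):
        name, cat, members = collection.sets[sid]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P[X >= k]
        rows.append((sid, name, cat, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["set_id", "name", "category", "k", "K",
                                     "n", "N", "p"]).set_index("set_id")

    df["fdr_p"] = np.nan
    if filter_before_fdr:
        mask = df["k"] >= min_overlap
        if mask.any():
            df.loc[mask, "fdr_p"] = bh_fdr(df.loc[mask, "p"].to_numpy())
    else:
        df["fdr_p"] = bh_fdr(df["p"].to_numpy())
    df["retained"] = ((df["k"] >= min_overlap)
                      & (df["p"] < p_thresh)
                      & (df["fdr_p"] < fdr_thresh))
    return df


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def term_overlap(resA: pd.DataFrame, resB: pd.DataFrame) -> dict[str, int]:
    """Counts of retained set ids shared between two comparisons, split by
    category (GO vs pathway vs other). Both results must come from the same
    collection."""
    common_ids = set(resA.index) & set(resB.index)
    if len(common_ids) != len(resA.index) or len(common_ids) != len(resB.index):
        raise ValueError("enrichment results come from different collections")
    mismatch = (resA.loc[sorted(common_ids), "category"]
                != resB.loc[sorted(common_ids), "category"])
    if mismatch.any():
        raise ValueError("enrichment results come from different collections")

    keptA = set(resA.index[resA["retained"]])
    keptB = set(resB.index[resB["retained"]])
    shared = keptA & keptB
    out: dict[str, int] = {"total": len(shared)}
    for sid in shared:
        cat = str(resA.loc[sid, "category"])
        out[cat] = out.get(cat, 0) + 1
    return out


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read the standard GMT dialect: set_id <TAB> description <TAB> gene...

    Descriptions of the form ``CATEGORY|name`` populate the category field;
    otherwise the category is ``other``. Universe defaults to the union of
    all member genes.
    """
    sets: dict[str, tuple[str, str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sid, desc, genes = parts[0], parts[1], set(parts[2:]) - {""}
            if "|" in desc:
                cat, name = desc.split("|", 1)
            else:
                cat, name = "other", desc
            sets[sid] = (name, cat, genes)
    if universe is None:
        universe = set().union(*(g for _, _, g in sets.values())) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            name, cat, genes = collection.sets[sid]
            fh.write("\t".join([sid, f"{cat}|{name}", *sorted(genes)]) + "\n")
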