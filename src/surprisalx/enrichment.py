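"""Set-ratio gene-set enrichment.

For a gene set J and component alpha, the positive and negative
weights are the sums of squared gene weights split by sign,

    P = sum_{i in J, G_ia > 0} G_ia^2,
    N = sum_{i in J, G_ia < 0} G_ia^2,

and the set ratio SR = P / N measures the set's contribution to the
phenotype: SR above ``hi`` (default 2) marks the positive pole of the
constraint, SR below ``lo`` (default 0.5) the negative pole. SR is
+inf when every member weight is positive and 0 when every one is
negative; sets with fewer than ``min_size`` members present in the
fitted model are omitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SurprisalModel
from .io import GeneSetCollection

__all__ = ["set_weights", "call_enrichment", "rank_enrichment", "write_enrichment"]

#: columns of an enrichment table, in output order
COLUMNS = ["n_genes_used", "P", "N", "SR", "degenerate"]


def set_weights(
    model: SurprisalModel,
    alpha: int,
    sets: GeneSetCollection,
    min_size: int = 10,
) -> pd.DataFrame:
    """Per-pathway P, N and SR for one component.

    Member genes absent from the model are ignored and excluded from
    ``n_genes_used``; pathways with ``n_genes_used`` < ``min_size`` are
    dropped. Genes with exactly zero weight contribute to neither P nor
    N. A set whose members all have zero weight has no defined SR: it
    is kept with SR = NaN and ``degenerate`` = True, and excluded from
    calls and ranking.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    weights = model.weights(alpha)
    index = pd.Index(model.gene_ids)
    rows = {}
    any_overlap = False
    for name, members in sets.items():
        present = index.intersection(list(members))
        n_used = len(present)
        if n_used > 0:
            any_overlap = True
        if n_used < min_size:
            continue
        w = weights[present].to_numpy()
        P = float((w[w > 0] ** 2).sum())
        N = float((w[w < 0] ** 2).sum())
        if P == 0.0 and N == 0.0:
            sr, degenerate = np.nan, True
        elif N == 0.0:
            sr, degenerate = np.inf, False
        else:
            sr, degenerate = P / N, False
        rows[name] = (n_used, P, N, sr, degenerate)
    if not any_overlap:
        raise ValueError("no pathway shares any gene with the fitted model")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=COLUMNS)
    table.index.name = "pathway"
    table["n_genes_used"] = table["n_genes_used"].astype(int)
    table["degenerate"] = table["degenerate"].astype(bool)
    table.attrs["alpha"] = alpha
    return table


def call_enrichment(
    table: pd.DataFrame, hi: float = 2.0, lo: float = 0.5
) -> pd.DataFrame:
    """Threshold calls: SR > hi -> positive_phenotype, SR < lo ->
    negative_phenotype, else (or degenerate) none."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    out = table.copy()
    sr = out["SR"]
    call = np.where(sr > hi, "positive_phenotype",
                    np.where(sr < lo, "negative_phenotype", "none"))
    call = np.where(sr.isna(), "none", call)
    out["call"] = call
    return out


def rank_enrichment(table: pd.DataFrame, direction: str = "positive") -> pd.DataFrame:
    """Order pathways by how strongly they mark one pole.

    positive: all-positive sets (SR = inf) first, among themselves by P
    descending, then finite SR descending. negative: all-negative sets
    (SR = 0) first, among themselves by N descending, then positive SR
    ascending. Degenerate (all-zero-weight) sets are excluded. Ties
    break by pathway name, so the ordering is a pure function of the
    table contents.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive or negative, got {direction!r}")
    t = table[~table["degenerate"]].copy()
    sr = t["SR"]
    if direction == "positive":
        extreme = np.isinf(sr)
        # sort key: extremes first, extremes by P desc, rest by SR desc
        t["_block"] = np.where(extreme, 0, 1)
        t["_key"] = np.where(extreme, -t["P"], -sr)
    else:
        extreme = sr == 0
        t["_block"] = np.where(extreme, 0, 1)
        t["_key"] = np.where(extreme, -t["N"], sr)
    t["_name"] = t.index
    t = t.sort_values(["_block", "_key", "_name"]).drop(columns=["_block", "_key", "_name"])
    t["rank"] = np.arange(1, len(t) + 1)
    return t


def write_enrichment(table: pd.DataFrame, path) -> None:
    """Write a table as TSV, printing infinite set ratios as ``Inf``
    and undefined ones as an empty field."""
    out = table.copy()
    sr = out["SR"]
    out["SR"] = [
        "Inf" if np.isinf(v) else ("" if np.isnan(v) else repr(float(v)))
        for v in sr
    ]
    out.to_csv(path, sep="\t")
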