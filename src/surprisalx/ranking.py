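"""Gene ranking within phenotypes and balanced-state stability calls.

Each constraint's weight vector G_.a orders the genes; the n largest
and n smallest weights (default n = 100) are the differentially
expressed lists for that phenotype. The sign of the balanced-state
term G_i0 lambda_0 — equivalently of ln X_i0 — splits genes into
stable (baseline abundance above 1) and unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import SurprisalModel

__all__ = ["RankedPhenotype", "rank_genes", "classify_stability", "directionality"]


@dataclass
class RankedPhenotype:
    """Full weight ordering for one component plus the top/bottom lists."""

    alpha: int
    table: pd.DataFrame               # columns: weight, rank, set; index gene_id
    top_set: list[str]                # n largest weights, descending
    bottom_set: list[str]             # n smallest weights, ascending


def rank_genes(
    model: SurprisalModel,
    alpha: int,
    n: int = 100,
    mask: Iterable[str] | None = None,
) -> RankedPhenotype:
    """Order genes by weight G_i,alpha (descending; ties by gene ID).

    ``mask`` restricts ranking to a gene-ID subset (e.g. a list of
    regulatory genes). ``top_set``/``bottom_set`` hold the n most
    positive / most negative weights, truncated when fewer genes exist.
    """
    weights = model.weights(alpha)
    if mask is not None:
        mask = set(mask)
        weights = weights[[g in mask for g in weights.index]]
        if weights.empty:
            raise ValueError("mask excludes every gene in the model")
    df = weights.rename("weight").to_frame()
    df["gene_id"] = df.index
    df = df.sort_values(["weight", "gene_id"], ascending=[False, True])
    df = df.drop(columns="gene_id")
    df["rank"] = np.arange(1, len(df) + 1)
    n_eff = min(n, len(df))
    top = list(df.index[:n_eff])
    bottom = list(df.index[::-1][:n_eff])
    membership = pd.Series("none", index=df.index, name="set")
    membership[top] = "top"
    membership[bottom] = "bottom"
    # a gene in both (tiny matrices) keeps the label of the nearer pole
    overlap = set(top) & set(bottom)
    for g in overlap:
        r = df.loc[g, "rank"]
        membership[g] = "top" if r <= len(df) / 2 else "bottom"
    df["set"] = membership
    return RankedPhenotype(alpha=alpha, table=df, top_set=top, bottom_set=bottom)


def classify_stability(model: SurprisalModel) -> pd.Series:
    """Label each gene stable (G_i0 lambda_0 > 0) or unstable.

    lambda_0 is positive by convention, so the call reduces to the sign
    of the balanced-state weight G_i0, i.e. of ln X_i0. An exactly-zero
    term is labelled unstable (its baseline abundance sits at the
    ln X_i0 = 0 boundary).
    """
    g0 = model.weights(0)
    labels = np.where(g0 > 0, "stable", "unstable")
    out = pd.Series(labels, index=g0.index, name="stability")
    out.attrs["zero_weight_genes"] = list(g0.index[g0 == 0])
    return out


def directionality(model: SurprisalModel, alpha: int, sample: str) -> pd.Series:
    """Per-gene expression direction of one constraint in one sample.

    Sign of G_i,alpha lambda_alpha(s): +1 the constraint pushes the
    gene above its balanced level in this sample, -1 below, 0 no
    contribution. Flipping the sample to the opposite group (opposite
    multiplier sign) flips every gene's direction.
    """
    if sample not in model.sample_ids:
        raise ValueError(f"unknown sample {sample!r}")
    lam = model.lambdas(alpha)[sample]
    term = model.weights(alpha) * lam
    return pd.Series(np.sign(term).astype(int), index=term.index, name="direction")
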