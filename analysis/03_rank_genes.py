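#!/usr/bin/env python
"""Rank genes within each phenotype and classify baseline stability.

Reads the fitted model tables, writes the full per-constraint rankings
with top-100/bottom-100 membership, and reports how many genes the
balanced state marks stable (baseline abundance above 1).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import surprisalx as sx
from surprisalx.core import SurprisalModel

BASE = Path(__file__).resolve().parent.parent / "results"


def load_model() -> SurprisalModel:
    G = pd.read_csv(BASE / "fit" / "G.tsv", sep="\t", index_col=0)
    lam = pd.read_csv(BASE / "fit" / "lambda.tsv", sep="\t", index_col=0)
    return SurprisalModel(
        gene_ids=list(G.index), sample_ids=list(lam.columns),
        G=G.to_numpy(), lam=lam.to_numpy(),
        singular_values=np.linalg.norm(lam.to_numpy(), axis=1),
        n_constraints=2,
    )


def main() -> None:
    model = load_model()
    out = BASE / "ranking"
    out.mkdir(parents=True, exist_ok=True)
    for alpha in (1, 2):
        ranked = sx.rank_genes(model, alpha, n=100)
        ranked.table.to_csv(out / f"constraint{alpha}_ranking.tsv", sep="\t",
                            index_label="gene_id")
        print(f"constraint {alpha}: top gene {ranked.top_set[0]} "
              f"(weight {ranked.table['weight'].iloc[0]:.4f}), "
              f"bottom gene {ranked.bottom_set[0]} "
              f"(weight {ranked.table['weight'].iloc[-1]:.4f})")
    stability = sx.classify_stability(model)
    stability.to_frame().to_csv(out / "stability.tsv", sep="\t", index_label="gene_id")
    n_stable = int((stability == "stable").sum())
    print(f"stable genes (G_i0 lambda_0 > 0): {n_stable} of {len(stability)}")


if __name__ == "__main__":
    main()
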