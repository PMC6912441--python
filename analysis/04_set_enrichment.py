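#!/usr/bin/env python
"""Score gene sets with the set ratio for each constraint.

For the growth-phase and dose constraints, computes P, N and SR = P/N
per pathway (sets with fewer than 10 genes in the model are omitted),
calls SR > 2 / SR < 0.5 enrichment, and writes both direction-ranked
tables. The planted sets should surface at the extremes; the decoys
should not be called.
"""

from pathlib import Path

import surprisalx as sx
from surprisalx.enrichment import call_enrichment, rank_enrichment, set_weights, write_enrichment

import importlib.util

BASE = Path(__file__).resolve().parent.parent / "results"
_spec = importlib.util.spec_from_file_location(
    "rank_driver", Path(__file__).resolve().parent / "03_rank_genes.py"
)
_rank_driver = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_rank_driver)


def main() -> None:
    model = _rank_driver.load_model()
    sets = sx.read_gene_sets(BASE / "synthetic" / "gene_sets.gmt")
    out = BASE / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    for alpha in (1, 2):
        table = call_enrichment(set_weights(model, alpha, sets, min_size=10))
        for direction in ("positive", "negative"):
            ranked = rank_enrichment(table, direction)
            write_enrichment(ranked, out / f"constraint{alpha}_{direction}.tsv")
        called = table[table["call"] != "none"]
        print(f"constraint {alpha}: {len(table)} sets scored, "
              f"{len(called)} called: "
              + ", ".join(f"{n} (SR={table.loc[n, 'SR']:.3g}, {table.loc[n, 'call']})"
                          for n in called.index))


if __name__ == "__main__":
    main()
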