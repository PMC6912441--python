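"""Expression matrices, sample designs and gene-set collections.

The pipeline starts from a genes x samples table of non-negative
abundances (FPKM-like units). Samples belong to a condition grid of
C acetate (dose) levels x T time points with R biological replicates
per cell; conditions are labelled ``ac<k>t<m>`` (dose index k, time
index m). Gene sets are named pathways mapping to member gene IDs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "condition_label",
    "read_expression_table",
    "write_expression_table",
    "read_sample_design",
    "read_gene_sets",
    "write_gene_sets",
    "filter_genes",
    "collapse_replicates",
    "replicate_dispersion",
]


def condition_label(concentration_index: int, time_index: int) -> str:
    """Condition label for grid cell (k, m), e.g. ``ac1t1``."""
    return f"ac{concentration_index}t{time_index}"


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative abundances.

    ``data`` is a DataFrame with gene IDs on the index and sample IDs on
    the columns. Validation is strict: duplicate identifiers, negative
    entries and missing values are hard errors — nothing is silently
    coerced.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        values = df.to_numpy()
        if values.size == 0:
            raise ValueError("expression matrix is empty")
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric entries")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                "missing value at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r} "
                "(ragged or incomplete input)"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance {values[i, j]} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleDesign:
    """Maps each sample to its (dose, time, replicate) grid cell.

    ``table`` is indexed by sample_id with integer columns
    ``concentration_index`` (1..C), ``time_index`` (1..T) and
    ``replicate_index`` (>= 1); a derived ``condition`` column carries
    the ``ac<k>t<m>`` label.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"concentration_index", "time_index", "replicate_index"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample design missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID in design: {dup!r}")
        triples = t[["concentration_index", "time_index", "replicate_index"]]
        if triples.duplicated().any():
            row = triples[triples.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (concentration, time, replicate) triple: "
                f"{tuple(row)}"
            )
        if "condition" not in t.columns:
            self.table = t.assign(
                condition=[
                    condition_label(k, m)
                    for k, m in zip(t["concentration_index"], t["time_index"])
                ]
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in grid order (dose-major, then time)."""
        cells = (
            self.table[["concentration_index", "time_index"]]
            .drop_duplicates()
            .sort_values(["concentration_index", "time_index"])
        )
        return [condition_label(k, m) for k, m in cells.itertuples(index=False)]

    def replicates_of(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return list(self.table.index[mask])

    def condition_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "condition"])

    def condition_groups_by_time(
        self, times: Iterable[int]
    ) -> tuple[list[str], list[str]]:
        """Partition condition labels into (in-``times``, rest).

        Used for the exponential vs stationary phase grouping (e.g.
        ``times=(1, 2)`` marks the early, exponential time points).
        """
        times = set(times)
        inside, outside = [], []
        for label in self.conditions:
            m = int(label.split("t")[1])
            (inside if m in times else outside).append(label)
        return inside, outside

    def condition_groups_by_dose(
        self, high: Iterable[int]
    ) -> tuple[list[str], list[str]]:
        """Partition condition labels into (high-dose, low-dose)."""
        high = set(high)
        hi, lo = [], []
        for label in self.conditions:
            k = int(label.split("t")[0][2:])
            (hi if k in high else lo).append(label)
        return hi, lo


@dataclass
class GeneSetCollection:
    """Named pathways mapped to their member gene IDs."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path | Sequence[str | Path],
    dialect: str = "matrix_tsv",
) -> ExpressionMatrix:
    """Read an expression matrix.

    dialect ``matrix_tsv``: one TSV, genes on rows, first column gene ID,
    header row of sample IDs. dialect ``per_sample_two_column``: a list
    of per-sample files (or a directory of them), each two tab-separated
    columns gene_id / abundance; the sample ID is the file stem. Rows
    whose field count disagrees with the header are hard errors.
    """
    if dialect == "matrix_tsv":
        path = Path(path)  # type: ignore[arg-type]
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        df.index = df.index.astype(str)
        df.index.name = "gene_id"
        return ExpressionMatrix(df.astype(float))
    if dialect == "per_sample_two_column":
        if isinstance(path, (str, Path)) and Path(path).is_dir():
            files = sorted(Path(path).iterdir())
        else:
            files = [Path(p) for p in path]  # type: ignore[union-attr]
        columns = {}
        for f in files:
            col = pd.read_csv(
                f, sep="\t", header=None, names=["gene_id", "value"], dtype=str
            )
            series = pd.Series(
                col["value"].astype(float).to_numpy(),
                index=col["gene_id"].to_numpy(),
                name=f.stem,
            )
            if series.index.has_duplicates:
                dup = series.index[series.index.duplicated()][0]
                raise ValueError(f"duplicate gene ID: {dup!r} in {f}")
            columns[f.stem] = series
        df = pd.DataFrame(columns)
        df.index.name = "gene_id"
        return ExpressionMatrix(df)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a design CSV with columns sample_id, concentration_index,
    time_index, replicate_index."""
    t = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    for c in ("concentration_index", "time_index", "replicate_index"):
        t[c] = t[c].astype(int)
    return SampleDesign(t)


def write_sample_design(d: SampleDesign, path: str | Path) -> None:
    d.table.drop(columns=["condition"]).to_csv(path, index_label="sample_id")


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read gene sets from GMT or two-column (gene, pathway) TSV.

    Empty pathways are dropped with a warning; a duplicated pathway name
    is a hard error (two definitions of one set cannot be merged safely).
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [g for g in members if g]
            if name in sets:
                raise ValueError(f"duplicate pathway name: {name!r}")
            if not members:
                warnings.warn(f"dropping empty pathway {name!r}")
                continue
            sets[name] = frozenset(members)
            descriptions[name] = desc
    elif format == "two_column_tsv":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "pathway"], dtype=str
        )
        for name, group in df.groupby("pathway", sort=False):
            sets[str(name)] = frozenset(group["gene_id"])
    else:
        raise ValueError(f"unknown gene-set format: {format!r}")
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    lines = []
    for name, members in sets.items():
        desc = sets.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# filtering / replicate collapsing
# ---------------------------------------------------------------------------


def filter_genes(
    m: ExpressionMatrix,
    policy: str = "all_positive",
    threshold: float = 0.0,
) -> ExpressionMatrix:
    """Drop genes the log transform cannot handle.

    ``all_positive`` keeps a gene iff its abundance exceeds ``threshold``
    in every sample (default 0: strictly positive everywhere, since
    ln 0 is undefined). ``min_fraction_positive`` keeps a gene iff the
    fraction of samples with positive abundance is at least ``threshold``.
    Row order is preserved; the removed count is logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = m.values
    if policy == "all_positive":
        keep = (values > threshold).all(axis=1)
    elif policy == "min_fraction_positive":
        keep = (values > 0).mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown filter policy: {policy!r}")
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    removed = int((~keep).sum())
    logger.info("filter_genes(%s, %g): removed %d of %d genes",
                policy, threshold, removed, len(keep))
    return ExpressionMatrix(m.data.loc[keep])


def collapse_replicates(
    m: ExpressionMatrix,
    d: SampleDesign,
    method: str = "mean_linear",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average replicates into one column per condition cell.

    ``mean_linear`` takes the arithmetic mean of abundances;
    ``mean_log`` the geometric mean (mean of logs, exponentiated).
    Returns the collapsed matrix (columns ``ac<k>t<m>`` in grid order)
    and the per-gene replicate dispersion per condition — the standard
    deviation across replicates (ddof=1, 0 for singleton cells), taken
    in log space when method is ``mean_log``.
    """
    if method not in ("mean_linear", "mean_log"):
        raise ValueError(f"unknown collapse method: {method!r}")
    missing = set(m.sample_ids) - set(d.sample_ids)
    if missing:
        raise ValueError(f"samples not in design: {sorted(missing)}")
    collapsed = {}
    dispersion = {}
    for cond in d.conditions:
        reps = [s for s in d.replicates_of(cond) if s in m.data.columns]
        if not reps:
            raise ValueError(f"condition {cond!r} has no replicates in matrix")
        block = m.data[reps].to_numpy(dtype=float)
        if method == "mean_linear":
            collapsed[cond] = block.mean(axis=1)
            sd = block.std(axis=1, ddof=1) if block.shape[1] > 1 else np.zeros(len(block))
        else:
            with np.errstate(divide="raise"):
                logblock = np.log(block)
            collapsed[cond] = np.exp(logblock.mean(axis=1))
            sd = logblock.std(axis=1, ddof=1) if block.shape[1] > 1 else np.zeros(len(block))
        dispersion[cond] = sd
    cdf = pd.DataFrame(collapsed, index=m.data.index)
    sdf = pd.DataFrame(dispersion, index=m.data.index)
    return ExpressionMatrix(cdf), sdf


def replicate_dispersion(
    m: ExpressionMatrix,
    d: SampleDesign,
    floor: float = 0.01,
) -> pd.DataFrame:
    """Per-gene, per-condition standard deviation of ln(max(X, floor))
    across replicates — the log-space dispersion fed to the λ error
    bounds regardless of which collapse method produced the matrix."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = {}
    for cond in d.conditions:
        reps = [s for s in d.replicates_of(cond) if s in m.data.columns]
        if not reps:
            raise ValueError(f"condition {cond!r} has no replicates in matrix")
        block = np.log(np.maximum(m.data[reps].to_numpy(dtype=float), floor))
        out[cond] = (
            block.std(axis=1, ddof=1) if block.shape[1] > 1 else np.zeros(len(block))
        )
    return pd.DataFrame(out, index=m.data.index)
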