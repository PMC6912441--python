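"""Auxiliary analyses: k-means profile clustering and growth metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import DEFAULT_FLOOR, log_transform
from .io import ExpressionMatrix

__all__ = ["ClusterAssignment", "cluster_genes", "doublings_per_day"]


@dataclass
class ClusterAssignment:
    """Result of clustering per-gene expression profiles."""

    k: int
    labels: pd.Series                 # per gene, 1..k
    centers: pd.DataFrame             # k x samples, mean profile per cluster
    peak_sample: dict[int, str]       # sample where each center is highest
    seed: int


def cluster_genes(
    m: ExpressionMatrix,
    k: int = 3,
    standardize: bool = True,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
) -> ClusterAssignment:
    """K-means on per-gene log-expression profiles.

    Profiles are ln(max(X, floor)), z-scored across samples when
    ``standardize`` (constant genes map to all-zero profiles). Rows are
    processed in gene-ID order and cluster labels are renumbered by
    first member, so the assignment is reproducible and permuting the
    input gene order only permutes the output labels accordingly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.shape[0]:
        raise ValueError("k exceeds the number of genes")
    Y = log_transform(m, floor=floor)
    Y = Y.sort_index()  # canonical row order: gene ID
    profiles = Y.to_numpy()
    if standardize:
        mu = profiles.mean(axis=1, keepdims=True)
        sd = profiles.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        profiles = (profiles - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(profiles)
    # renumber clusters 1..k by order of first appearance along the
    # canonical gene ordering
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[l] for l in raw], index=Y.index, name="cluster")
    centers = {}
    peaks = {}
    raw_profiles = pd.DataFrame(profiles, index=Y.index, columns=Y.columns)
    for c in range(1, k + 1):
        mean_profile = raw_profiles[labels == c].mean(axis=0)
        centers[c] = mean_profile
        peaks[c] = str(mean_profile.idxmax())
    centers_df = pd.DataFrame(centers).T
    centers_df.index.name = "cluster"
    return ClusterAssignment(
        k=k,
        labels=labels.reindex(m.data.index),
        centers=centers_df,
        peak_sample=peaks,
        seed=seed,
    )


def doublings_per_day(
    series: pd.DataFrame | Sequence[tuple[float, float]],
    t_start: float,
    t_end: float,
) -> float:
    """Cell doublings per 24 h between two sampled time points.

    ``series`` is a (time_h, cells_per_ml) table with strictly
    increasing times and positive concentrations; the rate is
    log2(N_end / N_start) / ((t_end - t_start) / 24) and is invariant
    to rescaling all concentrations.
    """
    if isinstance(series, pd.DataFrame):
        times = series.iloc[:, 0].to_numpy(dtype=float)
        conc = series.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
        times, conc = arr[:, 0], arr[:, 1]
    if (times < 0).any() or (np.diff(times) <= 0).any():
        raise ValueError("times must be non-negative and strictly increasing")
    if (conc <= 0).any():
        raise ValueError("cell concentrations must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    lookup = dict(zip(times, conc))
    if t_start not in lookup or t_end not in lookup:
        raise ValueError("t_start and t_end must be sampled time points")
    return float(
        np.log2(lookup[t_end] / lookup[t_start]) / ((t_end - t_start) / 24.0)
    )
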