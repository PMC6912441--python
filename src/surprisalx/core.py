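"""Surprisal decomposition of log-expression matrices.

The model writes the natural log of the expression of gene i in sample
s as a balanced-state term common to all samples plus deviations
("constraints"), each a gene-weight pattern G_ia scaled by a per-sample
Lagrange multiplier lambda_a(s):

    Y_i(s) = ln X_i(s) = ln X_i0 + sum_a G_ia lambda_a(s),
    ln X_i0 = G_i0 lambda_0

Weights and multipliers are estimated by singular value decomposition
of Y: component 0 (largest singular value) is the balanced state, and
the sign pattern of lambda_a(s) for a >= 1 groups samples into
phenotypes (e.g. exponential vs stationary growth phase, low vs high
acetate dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleDesign, collapse_replicates

__all__ = [
    "SurprisalModel",
    "LambdaErrorBounds",
    "SeparationReport",
    "log_transform",
    "decompose",
    "fit_surprisal",
    "reconstruct",
    "lambda_error_bounds",
    "bootstrap_lambda_errors",
    "group_separation",
]

DEFAULT_FLOOR = 0.01


def log_transform(m: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Natural log of the abundances, floored at ``floor`` (> 0)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    Y = np.log(np.maximum(m.values, floor))
    if not np.isfinite(Y).all():
        raise ValueError("log transform produced non-finite values")
    return pd.DataFrame(Y, index=m.data.index, columns=m.data.columns)


@dataclass
class SurprisalModel:
    """Fitted surprisal decomposition.

    ``G`` holds one orthonormal gene-weight column per component
    (column 0 = balanced state); ``lam`` the matching per-sample
    multipliers (row 0 = lambda_0, positive for every sample). All
    min(genes, samples) components are stored; ``n_constraints`` is the
    number of deviation components retained for interpretation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    G: np.ndarray                     # genes x K
    lam: np.ndarray                   # K x samples
    singular_values: np.ndarray       # K, non-increasing
    n_constraints: int
    floor: float = DEFAULT_FLOOR

    @property
    def n_components(self) -> int:
        return self.G.shape[1]

    def weights(self, alpha: int) -> pd.Series:
        """Gene weights G_i,alpha for one component."""
        self._check_alpha(alpha)
        return pd.Series(self.G[:, alpha], index=self.gene_ids, name=f"G{alpha}")

    def lambdas(self, alpha: int) -> pd.Series:
        """Per-sample multipliers lambda_alpha(s)."""
        self._check_alpha(alpha)
        return pd.Series(self.lam[alpha], index=self.sample_ids, name=f"lambda{alpha}")

    def _check_alpha(self, alpha: int) -> None:
        if not 0 <= alpha < self.n_components:
            raise ValueError(f"component index {alpha} out of range")


def _orient(
    U: np.ndarray,
    lam: np.ndarray,
    sample_ids: Sequence[str],
    reference: Mapping[int, Iterable[str]] | None,
) -> None:
    """Fix the SVD sign ambiguity in place.

    Component 0: all multipliers made positive (a mixed-sign leading
    component means the data have no common balanced state — error).
    Components >= 1: the lexicographically smallest sample label in the
    declared reference group (default: all samples) gets a positive
    multiplier; an exactly-zero multiplier there falls through to the
    first nonzero entry.
    """
    row0 = lam[0]
    if (row0 > 0).any() and (row0 < 0).any():
        raise ValueError(
            "lambda_0 changes sign across samples: "
            "balanced-state assumption violated"
        )
    if (row0 < 0).any():
        lam[0] *= -1.0
        U[:, 0] *= -1.0
    reference = reference or {}
    order = np.argsort(np.asarray(sample_ids, dtype=object))
    for a in range(1, lam.shape[0]):
        group = reference.get(a)
        if group is None:
            candidates = [sample_ids[j] for j in order]
        else:
            group = set(group)
            candidates = sorted(s for s in sample_ids if s in group)
            if not candidates:
                raise ValueError(f"reference group for component {a} matches no sample")
        sign = 0.0
        for s in candidates:
            sign = np.sign(lam[a, list(sample_ids).index(s)])
            if sign != 0:
                break
        if sign == 0:  # whole reference row is zero; any nonzero entry decides
            nz = np.nonzero(lam[a])[0]
            sign = np.sign(lam[a, nz[0]]) if len(nz) else 1.0
        if sign < 0:
            lam[a] *= -1.0
            U[:, a] *= -1.0


def decompose(
    Y: pd.DataFrame,
    n_constraints: int | None = None,
    reference: Mapping[int, Iterable[str]] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> SurprisalModel:
    """Estimate the surprisal model by SVD of the log-expression matrix.

    Y = U S V^T; G_.a is column a of U and lambda_a(s) = S_aa V_sa.
    The full spectrum is always computed and stored; ``n_constraints``
    (default: all min(genes, samples) - 1 deviation components) only
    marks how many constraints downstream steps interpret.
    ``reference`` optionally maps a component index to the sample group
    whose smallest label is oriented positive (see `_orient`).
    """
    values = Y.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("decompose requires at least 2 samples")
    if not np.isfinite(values).all():
        raise ValueError("log-expression matrix contains non-finite values")
    try:
        U, s, Vt = np.linalg.svd(values, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy rarely fails
        raise RuntimeError("SVD did not converge") from exc
    lam = s[:, None] * Vt
    sample_ids = list(Y.columns)
    _orient(U, lam, sample_ids, reference)
    k_max = len(s) - 1
    if n_constraints is None:
        n_constraints = k_max
    if not 0 <= n_constraints <= k_max:
        raise ValueError(f"n_constraints must be in [0, {k_max}]")
    return SurprisalModel(
        gene_ids=list(Y.index),
        sample_ids=sample_ids,
        G=U,
        lam=lam,
        singular_values=s,
        n_constraints=n_constraints,
        floor=floor,
    )


def fit_surprisal(
    m: ExpressionMatrix,
    design: SampleDesign | None = None,
    collapse: str = "mean_linear",
    floor: float = DEFAULT_FLOOR,
    n_constraints: int | None = None,
    reference: Mapping[int, Iterable[str]] | None = None,
) -> SurprisalModel:
    """Convenience driver: optionally collapse replicates, log, decompose."""
    if design is not None:
        m, _ = collapse_replicates(m, design, method=collapse)
    Y = log_transform(m, floor=floor)
    return decompose(Y, n_constraints=n_constraints, reference=reference, floor=floor)


def reconstruct(model: SurprisalModel, k: int) -> pd.DataFrame:
    """Partial-sum reconstruction using components 0..k.

    k = 0 returns the balanced state alone; k = n_components - 1 the
    exact log matrix (to numerical precision).
    """
    if not 0 <= k < model.n_components:
        raise ValueError(f"k must be in [0, {model.n_components - 1}]")
    Y = model.G[:, : k + 1] @ model.lam[: k + 1, :]
    return pd.DataFrame(Y, index=model.gene_ids, columns=model.sample_ids)


# ---------------------------------------------------------------------------
# error bars on the multipliers
# ---------------------------------------------------------------------------


@dataclass
class LambdaErrorBounds:
    """Non-negative error bars on lambda_alpha(s), same indexing as
    ``SurprisalModel.lam`` (rows 0..n_constraints)."""

    values: pd.DataFrame              # (n_constraints + 1) x samples
    method: str

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("error bounds must be non-negative")


def lambda_error_bounds(
    model: SurprisalModel,
    replicate_dispersion: pd.DataFrame,
    method: str = "norm_bound",
) -> LambdaErrorBounds:
    """Error bars on the multipliers from per-gene log-space dispersion.

    ``norm_bound`` (default) is the upper bound: since the weight
    columns have unit norm, |delta lambda_a(s)| = |G_.a . dY(.,s)|
    <= ||dY(.,s)||, estimated as sqrt(sum_i sigma_i(s)^2) — the same
    bar for every component; the realised multiplier error is below it
    (far below, for matrices with many genes). ``propagated_sd`` is the
    first-order standard deviation sqrt(sum_i G_ia^2 sigma_i(s)^2)
    under independent per-gene errors — a typical-error scale, not a
    bound. Both are zero wherever the dispersion is zero and monotone
    non-decreasing in every sigma_i(s).
    """
    sigma = replicate_dispersion.reindex(
        index=model.gene_ids, columns=model.sample_ids
    ).to_numpy(dtype=float)
    if np.isnan(sigma).any():
        raise ValueError("dispersion does not cover the model's genes/samples")
    if (sigma < 0).any():
        raise ValueError("dispersion must be non-negative")
    n_rows = model.n_constraints + 1
    if method == "norm_bound":
        per_sample = np.sqrt((sigma**2).sum(axis=0))
        bounds = np.tile(per_sample, (n_rows, 1))
    elif method == "propagated_sd":
        G2 = model.G[:, :n_rows] ** 2
        bounds = np.sqrt(G2.T @ (sigma**2))
    else:
        raise ValueError(f"unknown error-bound method: {method!r}")
    df = pd.DataFrame(
        bounds,
        index=[f"lambda{a}" for a in range(n_rows)],
        columns=model.sample_ids,
    )
    return LambdaErrorBounds(df, method)


def bootstrap_lambda_errors(
    m: ExpressionMatrix,
    design: SampleDesign,
    n_boot: int = 200,
    collapse: str = "mean_linear",
    floor: float = DEFAULT_FLOOR,
    n_constraints: int | None = None,
    reference: Mapping[int, Iterable[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-over-replicates cross-check of the error bars.

    Resamples replicates with replacement within each condition cell,
    recollapses, redecomposes, and reports the standard deviation of
    each lambda_alpha(condition) over ``n_boot`` resamples.
    """
    rng = np.random.default_rng(seed)
    base = fit_surprisal(
        m, design, collapse=collapse, floor=floor,
        n_constraints=n_constraints, reference=reference,
    )
    n_rows = base.n_constraints + 1
    draws = np.empty((n_boot, n_rows, len(base.sample_ids)))
    for b in range(n_boot):
        cols = {}
        for cond in design.conditions:
            reps = [s for s in design.replicates_of(cond) if s in m.data.columns]
            pick = rng.choice(reps, size=len(reps), replace=True)
            block = m.data[list(pick)].to_numpy(dtype=float)
            if collapse == "mean_linear":
                cols[cond] = block.mean(axis=1)
            else:
                cols[cond] = np.exp(np.log(block).mean(axis=1))
        boot = ExpressionMatrix(pd.DataFrame(cols, index=m.data.index))
        fit = fit_surprisal(
            boot, None, floor=floor, n_constraints=base.n_constraints,
            reference=reference,
        )
        draws[b] = fit.lam[:n_rows]
    sd = draws.std(axis=0, ddof=1)
    return pd.DataFrame(
        sd,
        index=[f"lambda{a}" for a in range(n_rows)],
        columns=base.sample_ids,
    )


# ---------------------------------------------------------------------------
# sample grouping by multiplier sign
# ---------------------------------------------------------------------------


@dataclass
class SeparationReport:
    """Sign pattern of one constraint's multipliers against a two-group
    sample partition."""

    alpha: int
    signs: pd.Series                  # per sample: -1, 0, +1
    group_a: list[str]
    group_b: list[str]
    majority_sign_a: int
    majority_sign_b: int
    agreement_a: float
    agreement_b: float
    agreement: float                  # overall fraction matching own group majority
    separating: bool
    zero_samples: list[str] = field(default_factory=list)


def group_separation(
    model: SurprisalModel,
    alpha: int,
    grouping: tuple[Iterable[str], Iterable[str]],
) -> SeparationReport:
    """Does the sign of lambda_alpha(s) separate two sample groups?

    The partition is ``separating`` when every sample matches its
    group's majority sign, the two majority signs are opposite, and no
    multiplier is exactly zero (zeros count as non-matching and are
    flagged).
    """
    if alpha < 1:
        raise ValueError("group separation applies to constraints (alpha >= 1)")
    lam = model.lambdas(alpha)
    group_a = list(grouping[0])
    group_b = list(grouping[1])
    covered = set(group_a) | set(group_b)
    if covered != set(model.sample_ids):
        raise ValueError("grouping must cover all samples exactly")
    signs = np.sign(lam).astype(int)

    def majority(group: list[str]) -> int:
        s = signs[group]
        pos, neg = int((s > 0).sum()), int((s < 0).sum())
        if pos == neg:
            return 0
        return 1 if pos > neg else -1

    maj_a, maj_b = majority(group_a), majority(group_b)
    match_a = (signs[group_a] == maj_a) & (maj_a != 0)
    match_b = (signs[group_b] == maj_b) & (maj_b != 0)
    agreement_a = float(match_a.mean())
    agreement_b = float(match_b.mean())
    n = len(group_a) + len(group_b)
    agreement = (match_a.sum() + match_b.sum()) / n
    zeros = list(signs.index[signs == 0])
    separating = (
        agreement_a == 1.0
        and agreement_b == 1.0
        and maj_a == -maj_b
        and maj_a != 0
        and not zeros
    )
    return SeparationReport(
        alpha=alpha,
        signs=signs,
        group_a=group_a,
        group_b=group_b,
        majority_sign_a=maj_a,
        majority_sign_b=maj_b,
        agreement_a=agreement_a,
        agreement_b=agreement_b,
        agreement=float(agreement),
        separating=bool(separating),
        zero_samples=zeros,
    )
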