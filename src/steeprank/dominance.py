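"""David's-score cardinal ranks, hierarchy steepness and Landau linearity.

A dominance hierarchy is summarised from a square win-loss sociomatrix
(winners in rows).  Cardinal ranks are Dij-corrected normalized David's
scores; steepness is the absolute OLS slope of the sorted cardinal scores
against ordinal ranks 1..N; linearity is the (modified) Landau index with a
randomization test.
"""

from __future__ import annotations

import dataclasses


import numpy as np
import pandas as pd

__all__ = [
    "MatrixValidationError",
    "InteractionMatrix",
    "CardinalRanks",
    "OrdinalRanks",
    "SteepnessResult",
    "LinearityResult",
    "validate_matrix",
    "read_sociomatrix_csv",
    "dyadic_dominance_index",
    "davids_scores",
    "steepness_from_scores",
    "nds_steepness",
    "steepness_randomization_test",
    "ordinal_from_cardinal",
    "landau_h",
    "linearity_test",
]


class MatrixValidationError(ValueError):
    """Raised when a sociomatrix violates the input contract."""


@dataclasses.dataclass(frozen=True)
class InteractionMatrix:
    """Square non-negative integer matrix of dyadic wins.

    ``counts[i, j]`` is the number of interactions individual ``ids[i]``
    won against ``ids[j]``; the diagonal is zero.
    """

    ids: tuple[str, ...]
    counts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def total_interactions(self) -> int:
        return int(self.counts.sum())

    def dyad_totals(self) -> np.ndarray:
        """n_ij = s_ij + s_ji."""
        return self.counts + self.counts.T

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.ids), columns=list(self.ids))


@dataclasses.dataclass(frozen=True)
class CardinalRanks:
    """Continuous dominance scores, one per individual."""

    ids: tuple[str, ...]
    scores: np.ndarray
    method: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.ids), name=self.method)


@dataclasses.dataclass(frozen=True)
class OrdinalRanks:
    """Integer ranks 1..N, 1 = highest cardinal score."""

    ids: tuple[str, ...]
    rank: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.rank, index=list(self.ids), name="ordinal_rank")


@dataclasses.dataclass(frozen=True)
class SteepnessResult:
    estimate: float
    method: str
    n_individuals: int
    se: float | None = None
    ci: tuple[float, float] | None = None
    null_p: float | None = None


@dataclasses.dataclass(frozen=True)
class LinearityResult:
    h: float | None
    h_prime: float
    p_value: float
    is_linear: bool
    n_unknown_dyads: int = 0


def validate_matrix(raw: pd.DataFrame) -> InteractionMatrix:
    """Validate an id-labelled count table into an :class:`InteractionMatrix`.

    Raises :class:`MatrixValidationError` naming the offending cell for
    non-square tables, mismatched labels, duplicate ids, negative entries
    or a nonzero diagonal.  N >= 2 is required.
    """
    if raw.shape[0] != raw.shape[1]:
        raise MatrixValidationError(
            f"matrix is not square: {raw.shape[0]} rows x {raw.shape[1]} columns"
        )
    ids = [str(x) for x in raw.index]
    col_ids = [str(x) for x in raw.columns]
    if ids != col_ids:
        raise MatrixValidationError(
            f"row labels {ids} do not match column labels {col_ids}"
        )
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise MatrixValidationError(f"duplicate ids: {dupes}")
    if len(ids) < 2:
        raise MatrixValidationError("N < 2: at least two individuals are required")
    counts = raw.to_numpy()
    try:
        counts = np.asarray(counts, dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixValidationError(f"non-numeric entries: {exc}") from exc
    if not np.all(np.isfinite(counts)):
        i, j = np.argwhere(~np.isfinite(counts))[0]
        raise MatrixValidationError(f"non-finite entry at cell ({ids[i]}, {ids[j]})")
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise MatrixValidationError(
            f"negative entry {counts[i, j]} at cell ({ids[i]}, {ids[j]})"
        )
    diag = np.diag(counts)
    if np.any(diag != 0):
        i = int(np.argwhere(diag != 0)[0][0])
        raise MatrixValidationError(
            f"nonzero diagonal entry {diag[i]} at cell ({ids[i]}, {ids[i]})"
        )
    if np.any(counts != np.round(counts)):
        i, j = np.argwhere(counts != np.round(counts))[0]
        raise MatrixValidationError(
            f"non-integer entry {counts[i, j]} at cell ({ids[i]}, {ids[j]})"
        )
    out = counts.astype(np.int64)
    out.setflags(write=False)
    return InteractionMatrix(ids=tuple(ids), counts=out)


def read_sociomatrix_csv(path, losers_in_rows: bool = False) -> InteractionMatrix:
    """Read a labelled sociomatrix CSV (first row/column are ids).

    ``losers_in_rows=True`` transposes files whose rows hold the losers.
    """
    df = pd.read_csv(path, index_col=0)
    if losers_in_rows:
        df = df.T
    return validate_matrix(df)


def dyadic_dominance_index(m: InteractionMatrix) -> np.ndarray:
    """Dyadic dominance index Dij with the small-sample correction.

    Pij = s_ij / n_ij, Dij = Pij - (Pij - 0.5) / (n_ij + 1); dyads never
    observed interacting (n_ij = 0) get the chance value 0.5.  The diagonal
    is set to 0 so that row/column sums run over j != i.
    """
    s = m.counts.astype(float)
    n = s + s.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / np.where(n > 0, n, 1.0), 0.5)
    d = p - (p - 0.5) / (n + 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def davids_scores(m: InteractionMatrix) -> CardinalRanks:
    """Dij-based normalized David's scores (method ``NDS_Dij``).

    w_i = sum_j Dij, w2_i = sum_j w_j Dij, l_i = sum_j Dji,
    l2_i = sum_j l_j Dji; DS = w + w2 - l - l2;
    NormDS = (DS + N(N-1)/2) / N.
    """
    d = dyadic_dominance_index(m)
    n = m.n
    w = d.sum(axis=1)
    l = d.sum(axis=0)
    w2 = d @ w
    l2 = d.T @ l
    ds = w + w2 - l - l2
    norm_ds = (ds + n * (n - 1) / 2.0) / n
    return CardinalRanks(ids=m.ids, scores=norm_ds, method="NDS_Dij")


def _ols_slope(y_sorted_desc: np.ndarray) -> float:
    n = y_sorted_desc.size
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y_sorted_desc - y_sorted_desc.mean()) / (xc @ xc))


def steepness_from_scores(
    scores: CardinalRanks, scale: float = 1.0
) -> SteepnessResult:
    """Absolute OLS slope of descending-sorted scores against ranks 1..N.

    ``scale`` divides the slope for score scales on which a perfect
    hierarchy does not step by 1 per rank (NormDS and cumulative winning
    probabilities need scale = 1).  The estimate is clamped to [0, 1].
    """
    y = np.sort(np.asarray(scores.scores, dtype=float))[::-1]
    if y.size < 2:
        raise ValueError("steepness requires at least 2 scores")
    slope = _ols_slope(y) / scale
    est = min(1.0, max(0.0, abs(slope)))
    return SteepnessResult(estimate=est, method=scores.method, n_individuals=y.size)


def nds_steepness(m: InteractionMatrix) -> SteepnessResult:
    """NormDS-based steepness of a sociomatrix."""
    return steepness_from_scores(davids_scores(m))


def steepness_randomization_test(
    m: InteractionMatrix, reps: int = 2000, seed=None
) -> SteepnessResult:
    """Steepness with a right-tail randomization p-value.

    The null keeps every dyad's interaction count n_ij fixed and redraws
    the wins as Binomial(n_ij, 0.5); null_p uses the +1 continuity
    correction in numerator and denominator.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = nds_steepness(m)
    n_tot = m.dyad_totals()
    iu, ju = np.triu_indices(m.n, k=1)
    n_upper = n_tot[iu, ju]
    exceed = 0
    counts = np.zeros_like(m.counts)
    for _ in range(reps):
        wins = rng.binomial(n_upper, 0.5)
        counts[iu, ju] = wins
        counts[ju, iu] = n_upper - wins
        null_m = InteractionMatrix(ids=m.ids, counts=counts)
        if nds_steepness(null_m).estimate >= observed.estimate:
            exceed += 1
    null_p = (1 + exceed) / (reps + 1)
    return dataclasses.replace(observed, null_p=null_p)


def ordinal_from_cardinal(scores: CardinalRanks) -> OrdinalRanks:
    """Ordinal ranks: 1 = largest score; ties broken by input id order."""
    s = np.asarray(scores.scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    order = np.argsort(-s, kind="stable")
    rank = np.empty(s.size, dtype=np.int64)
    rank[order] = np.arange(1, s.size + 1)
    return OrdinalRanks(ids=scores.ids, rank=rank)


def landau_h(dominates: np.ndarray) -> float:
    """Landau's linearity index of a fully resolved dominance relation.

    ``dominates`` is a boolean/0-1 matrix with exactly one of (i,j), (j,i)
    true for every dyad.  h = 12/(N^3 - N) * sum_i (V_i - (N-1)/2)^2 with
    V_i the number of individuals i dominates.
    """
    d = np.asarray(dominates)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dominance relation must be square")
    both = d.astype(bool) | d.astype(bool).T
    if not np.all(both[~np.eye(n, dtype=bool)]):
        raise ValueError(
            "unresolved dyad present; use linearity_test for matrices with unknowns"
        )
    if np.any(d.astype(bool) & d.astype(bool).T):
        raise ValueError("dyad resolved in both directions")
    v = d.astype(float).sum(axis=1)
    return float(12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2))


def _h_from_v(v: np.ndarray, n: int) -> np.ndarray:
    return 12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2, axis=-1)


def linearity_test(
    m: InteractionMatrix,
    rand_unknown: int = 1000,
    rand_null: int = 10000,
    seed=None,
) -> LinearityResult:
    """Modified Landau linearity index h' with a randomization test.

    Dyads are resolved by majority of wins; tied or unobserved dyads are
    resolved uniformly at random ``rand_unknown`` times and h' is the mean
    Landau h over the completions.  The null distribution assigns every
    dyad a random direction; p is the right-tail proportion of null h >= h'
    (with the +1 continuity correction) and is_linear tests p < 0.05.
    """
    n = m.n
    if n < 3:
        raise ValueError("linearity requires N >= 3")
    rng = np.random.default_rng(seed)
    s = m.counts
    iu, ju = np.triu_indices(n, k=1)
    wins_i = s[iu, ju]
    wins_j = s[ju, iu]
    known_i_wins = wins_i > wins_j
    unknown = wins_i == wins_j
    n_unknown = int(unknown.sum())

    # V contribution from resolved dyads
    v_base = np.zeros(n)
    np.add.at(v_base, iu[known_i_wins], 1)
    np.add.at(v_base, ju[(~known_i_wins) & (~unknown)], 1)

    one_hot_i = np.zeros((iu.size, n))
    one_hot_i[np.arange(iu.size), iu] = 1.0
    one_hot_j = np.zeros((ju.size, n))
    one_hot_j[np.arange(ju.size), ju] = 1.0

    if n_unknown == 0:
        h_prime = float(_h_from_v(v_base, n))
        h = h_prime
    else:
        flips = (rng.random((rand_unknown, n_unknown)) < 0.5).astype(float)
        v = v_base + flips @ one_hot_i[unknown] + (1 - flips) @ one_hot_j[unknown]
        h_prime = float(_h_from_v(v, n).mean())
        h = None

    # whole-matrix null: every dyad's direction random
    flips = (rng.random((rand_null, iu.size)) < 0.5).astype(float)
    v_null = flips @ one_hot_i + (1 - flips) @ one_hot_j
    h_null = _h_from_v(v_null, n)
    p = (1 + int(np.sum(h_null >= h_prime))) / (rand_null + 1)
    return LinearityResult(
        h=h, h_prime=h_prime, p_value=p, is_linear=p < 0.05, n_unknown_dyads=n_unknown
    )
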