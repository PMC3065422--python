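"""Kendall's coefficient of concordance over unfolded distance matrices.

The statistic underlying the congruence test: each matrix's upper off-diagonal
distances are unfolded into a vector (one row of a p x n worktable,
n = m(m-1)/2), each row is rank-transformed with mid-ranks for ties, and
Kendall's W is the variance of the column rank sums R_j divided by its maximum
attainable value,

    W = 12 S / (p^2 (n^3 - n) - p T),

with S = sum_j (R_j - Rbar)^2 and the tie correction
T = sum over rows sum_k (t_k^3 - t_k) for tie groups of size t_k. W ranges
from 0 (complete disagreement among the rankings) to 1 (identical rankings).
The pivot used for permutation testing is Friedman's chi^2 = p (n - 1) W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .matrices import DistanceMatrix, DistanceMatrixSet

__all__ = [
    "unfold",
    "rank_transform",
    "tie_group_sizes",
    "tie_correction",
    "RankTable",
    "CadmStatistic",
    "kendall_w",
    "friedman_chi2",
    "rank_matrix_correlation",
    "DegenerateRankingError",
]


class DegenerateRankingError(ValueError):
    """Raised when W is undefined: every row is a single tie group, so the
    maximum rank-sum variance (the denominator of W) is zero."""


def unfold(matrix: DistanceMatrix) -> np.ndarray:
    """Unfold the upper off-diagonal distances into a vector.

    Traversal is row-major over pairs (i, j) with i < j in the matrix's
    canonical (sorted-label) order, so the k-th entry refers to the same taxon
    pair in every matrix of a set. For m taxa the vector has m(m-1)/2 entries.
    """
    return matrix.condensed()


def rank_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Rank a vector 1..n, ties receiving mid-ranks (average of spanned ranks)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    return rankdata(values, method="average")


def tie_group_sizes(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Sizes t_k of the groups of tied values in a vector (all groups,
    including singletons)."""
    values = np.sort(np.asarray(values, dtype=float))
    _, counts = np.unique(values, return_counts=True)
    return counts


def tie_correction(values: Sequence[float] | np.ndarray) -> float:
    """Per-row tie correction sum_k (t_k^3 - t_k); zero for distinct values."""
    t = tie_group_sizes(values).astype(float)
    return float(np.sum(t**3 - t))


@dataclass(frozen=True)
class RankTable:
    """The p x n worktable of mid-ranks with tie bookkeeping.

    ``ranks[i]`` is the rank-transformed unfolded vector of matrix ``i``;
    ``row_ties[i]`` the tie-group sizes of that row. Row sums are n(n+1)/2 by
    construction of mid-ranks.
    """

    ranks: np.ndarray
    row_ties: tuple[np.ndarray, ...]

    @property
    def p(self) -> int:
        return self.ranks.shape[0]

    @property
    def n(self) -> int:
        return self.ranks.shape[1]

    @property
    def column_sums(self) -> np.ndarray:
        """Rank sums R_j per taxon pair j."""
        return self.ranks.sum(axis=0)

    @property
    def mean_sum(self) -> float:
        """Mean of the R_j, equal to p(n+1)/2."""
        return float(self.column_sums.mean())

    @property
    def tie_correction(self) -> float:
        """Total T = sum over rows of sum_k (t_k^3 - t_k)."""
        return float(sum(np.sum(t.astype(float) ** 3 - t) for t in self.row_ties))

    @classmethod
    def from_set(cls, dms: DistanceMatrixSet) -> "RankTable":
        rows = [rank_transform(unfold(dm)) for dm in dms]
        ties = tuple(tie_group_sizes(unfold(dm)) for dm in dms)
        return cls(ranks=np.array(rows), row_ties=ties)

    @classmethod
    def from_vectors(cls, vectors: Sequence[Sequence[float]]) -> "RankTable":
        vectors = [np.asarray(v, dtype=float) for v in vectors]
        if len(vectors) < 2:
            raise ValueError("need at least 2 rows")
        n = vectors[0].size
        if any(v.size != n for v in vectors):
            raise ValueError("rows must have equal length")
        rows = [rank_transform(v) for v in vectors]
        ties = tuple(tie_group_sizes(v) for v in vectors)
        return cls(ranks=np.array(rows), row_ties=ties)


@dataclass(frozen=True)
class CadmStatistic:
    """Descriptive output of the concordance computation."""

    W: float
    S: float
    T: float
    chi2: float
    p: int
    n: int
    p_value: float | None = None
    n_permutations: int | None = None
    extras: dict = field(default_factory=dict, compare=False)


def _w_denominator(p: int, n: int, T: float) -> float:
    return p * p * (n**3 - n) - p * T


def kendall_w(table: RankTable) -> CadmStatistic:
    """Compute W, S, T (and the chi^2 pivot) from a rank table.

    Raises :class:`DegenerateRankingError` when every row is entirely tied
    (denominator zero), rather than returning 0/0.
    """
    p, n = table.p, table.n
    if p < 2 or n < 2:
        raise ValueError(f"need p >= 2 matrices and n >= 2 distances, got p={p}, n={n}")
    R = table.column_sums
    S = float(np.sum((R - R.mean()) ** 2))
    T = table.tie_correction
    denom = _w_denominator(p, n, T)
    if denom <= 0:
        raise DegenerateRankingError(
            "all rows are completely tied; the concordance denominator is zero"
        )
    W = 12.0 * S / denom
    # guard against floating noise only; substantive overshoot is a bug
    if W > 1.0:
        if W > 1.0 + 1e-12:
            raise AssertionError(f"W = {W!r} exceeds 1 beyond floating noise")
        W = 1.0
    elif W < 0.0:  # pragma: no cover - S is a sum of squares
        W = 0.0
    return CadmStatistic(W=W, S=S, T=T, chi2=friedman_chi2(W, p, n), p=p, n=n)


def friedman_chi2(W: float, p: int, n: int) -> float:
    """Friedman's chi-square pivot, chi2 = p (n - 1) W."""
    if not 0.0 <= W <= 1.0:
        raise ValueError(f"W must lie in [0, 1], got {W}")
    return p * (n - 1) * W


def rank_matrix_correlation(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Spearman-type matrix correlation (rank-based Mantel statistic).

    Pearson correlation of the mid-rank transforms of the two unfolded
    distance vectors; in [-1, 1]. Used to suggest subsets of potentially
    congruent matrices before a posteriori testing.
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share the same taxa")
    ra = rank_transform(unfold(a))
    rb = rank_transform(unfold(b))
    return rank_vector_correlation(ra, rb)


def rank_vector_correlation(ra: np.ndarray, rb: np.ndarray) -> float:
    """Pearson correlation of two (already rank-transformed) vectors."""
    da = ra - ra.mean()
    db = rb - rb.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise DegenerateRankingError("constant ranking: correlation undefined")
    return float(da @ db / np.sqrt(va * vb))
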