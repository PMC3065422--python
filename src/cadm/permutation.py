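"""Permutation tests of congruence among distance matrices.

The null hypothesis of the global test is complete incongruence of all p
matrices; the alternative is that at least two share congruent structure. The
test statistic is Friedman's chi^2 = p (n - 1) W, referenced against its
distribution under random, independent taxon permutations of the matrices
(rows and columns permuted simultaneously — the Mantel-test convention this
test extends). In a posteriori tests a single matrix is permuted at a time: a
matrix congruent with others degrades the statistic substantially once
permuted, an incongruent one barely.

One-tailed p-values use the add-one convention with the observed value
included in the reference distribution: p = (count_ge + 1) / (p_n + 1), where
count_ge is the number of permuted statistics >= the observed one (ties count
as exceedances).

The hot path exploits the fact that ranking commutes with taxon relabeling:
a taxon permutation permutes a matrix's unfolded vector, hence its rank
vector, and leaves its tie structure (and the W denominator) unchanged. Ranks
are therefore computed once per matrix and each permutation round applies a
pair-index map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .concordance import (
    CadmStatistic,
    RankTable,
    friedman_chi2,
    kendall_w,
    rank_vector_correlation,
)
from .matrices import DistanceMatrix, DistanceMatrixSet

__all__ = [
    "TestConfig",
    "APosterioriResult",
    "permute_distance_matrix",
    "global_test",
    "a_posteriori_tests",
    "pvalue_from_counts",
    "adjust_pvalues",
    "CADM",
    "CADMResults",
]


@dataclass(frozen=True)
class TestConfig:
    """Settings of a permutation test.

    ``n_permutations`` defaults to 999 (permutation distributions estimated
    from 999 random permutations plus the observed value); ``alpha`` is the
    nominal significance level; ``adjust`` the multiple-testing correction
    applied to a posteriori p-values (``"holm"``, ``"bonferroni"`` or
    ``"none"``).
    """

    n_permutations: int = 999
    alpha: float = 0.05
    seed: int | None = None
    adjust: str = "holm"

    __test__ = False  # keep pytest from collecting this as a test class

    def __post_init__(self):
        if self.n_permutations < 99:
            raise ValueError("need at least 99 permutations")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.adjust not in ("holm", "bonferroni", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def pvalue_from_counts(count_ge: int, n_permutations: int) -> float:
    """Permutation p-value with the observed statistic included in the
    reference distribution: (count_ge + 1) / (n_permutations + 1)."""
    if not 0 <= count_ge <= n_permutations:
        raise ValueError("count_ge must lie in [0, n_permutations]")
    return (count_ge + 1) / (n_permutations + 1)


def adjust_pvalues(raw, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment of a vector of p-values.

    Holm step-down by default; Bonferroni and ``"none"`` selectable. Output is
    capped at 1 and never smaller than the input.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any((raw <= 0) | (raw > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none" or raw.size == 1:
        return raw.copy()
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {method!r}")
    _, adjusted, _, _ = multipletests(raw, method=method)
    return adjusted


def permute_distance_matrix(
    matrix: DistanceMatrix, rng: np.random.Generator
) -> DistanceMatrix:
    """Apply one uniformly random taxon permutation to rows and columns
    simultaneously; the multiset of off-diagonal distances is conserved."""
    perm = rng.permutation(matrix.n_taxa)
    return matrix.permuted(perm)


class _PairPermuter:
    """Maps taxon permutations to permutations of the unfolded pair index."""

    def __init__(self, m: int):
        self.m = m
        iu, ju = np.triu_indices(m, k=1)
        self.iu, self.ju = iu, ju
        pidx = np.zeros((m, m), dtype=np.intp)
        pidx[iu, ju] = np.arange(iu.size)
        pidx[ju, iu] = pidx[iu, ju]
        self.pidx = pidx

    def pair_permutation(self, taxon_perm: np.ndarray) -> np.ndarray:
        """Index map q with unfold(permuted)[k] = unfold(original)[q[k]]."""
        return self.pidx[taxon_perm[self.iu], taxon_perm[self.ju]]


def _permutation_engine(
    table: RankTable,
    m: int,
    rng: np.random.Generator,
    n_permutations: int,
    permute_rows: np.ndarray,
) -> tuple[CadmStatistic, float]:
    """Shared global / a posteriori reference-distribution computation.

    ``permute_rows`` flags which worktable rows receive a fresh random taxon
    permutation each round; the others stay fixed. All rounds are evaluated
    vectorized: row i contributes either its fixed rank vector or, per round,
    its rank vector re-indexed through the pair map of a random taxon
    permutation (ranking commutes with relabeling, so this equals re-ranking
    the permuted matrix).
    """
    observed = kendall_w(table)
    p, n = table.p, table.n
    denom = p * p * (n**3 - n) - p * table.tie_correction
    permuter = _PairPermuter(m)
    R_total = np.zeros((n_permutations, n))
    for i in range(p):
        if permute_rows[i]:
            # rows of argsorted uniforms are i.i.d. uniform permutations
            sigma = np.argsort(rng.random((n_permutations, m)), axis=1)
            maps = permuter.pidx[sigma[:, permuter.iu], sigma[:, permuter.ju]]
            R_total += table.ranks[i][maps]
        else:
            R_total += table.ranks[i][None, :]
    S_star = ((R_total - R_total.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    chi2_star = p * (n - 1) * np.minimum(12.0 * S_star / denom, 1.0)
    # ties count as exceedances; tiny slack guards float-noise from the
    # different summation order of the observed statistic
    count_ge = int(np.sum(chi2_star >= observed.chi2 * (1.0 - 1e-12) - 1e-12))
    return observed, pvalue_from_counts(count_ge, n_permutations)


def global_test(
    dms: DistanceMatrixSet,
    config: TestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CadmStatistic:
    """Global congruence test: every matrix permuted independently each round.

    Returns the observed statistic with its one-tailed permutation p-value.
    An explicit ``rng`` overrides the config's seed (used by the experiment
    harness to chain replicate streams).
    """
    config = config or TestConfig()
    table = RankTable.from_set(dms)
    if rng is None:
        rng = config.rng()
    observed, p_value = _permutation_engine(
        table, dms.n_taxa, rng, config.n_permutations,
        permute_rows=np.ones(dms.n_matrices, dtype=bool),
    )
    return replace(observed, p_value=p_value, n_permutations=config.n_permutations)


@dataclass(frozen=True)
class APosterioriResult:
    """Per-matrix decomposition of congruence.

    ``congruence[j]`` is matrix j's mean rank matrix correlation with the
    other p-1 matrices (an estimate of its level of congruence);
    ``p_values[j]`` the one-tailed p-value from permuting only matrix j;
    ``adjusted[j]`` after multiple-testing correction.
    """

    names: tuple[str, ...]
    congruence: np.ndarray
    p_values: np.ndarray
    adjusted: np.ndarray
    method: str
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "matrix": list(self.names),
                "congruence": self.congruence,
                "p_value": self.p_values,
                "p_adjusted": self.adjusted,
            }
        )


def a_posteriori_tests(
    dms: DistanceMatrixSet,
    config: TestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> APosterioriResult:
    """Identify congruent members: permute one matrix at a time.

    With p = 2 this duplicates the global test (permuting either matrix
    references the same statistic against an equivalent distribution).
    """
    config = config or TestConfig()
    table = RankTable.from_set(dms)
    p = dms.n_matrices
    raw = np.empty(p)
    if rng is None:
        rng = config.rng()
    for j in range(p):
        flags = np.zeros(p, dtype=bool)
        flags[j] = True
        _, raw[j] = _permutation_engine(
            table, dms.n_taxa, rng, config.n_permutations, permute_rows=flags
        )
    congruence = np.empty(p)
    for j in range(p):
        others = [
            rank_vector_correlation(table.ranks[j], table.ranks[k])
            for k in range(p)
            if k != j
        ]
        congruence[j] = float(np.mean(others))
    return APosterioriResult(
        names=dms.names,
        congruence=congruence,
        p_values=raw,
        adjusted=adjust_pvalues(raw, config.adjust),
        method=config.adjust,
        n_permutations=config.n_permutations,
    )


class CADM:
    """Congruence-among-distance-matrices model bound to a set of matrices.

    Parameters
    ----------
    dms : DistanceMatrixSet or sequence of DistanceMatrix
        Two or more distance matrices over the same taxa.
    names : sequence of str, optional
        Display names (only when ``dms`` is a plain sequence).

    Examples
    --------
    >>> model = CADM([dm1, dm2, dm3])            # doctest: +SKIP
    >>> res = model.fit(n_permutations=999, seed=42, a_posteriori=True)
    >>> print(res.summary())                     # doctest: +SKIP
    """

    def __init__(self, dms, names=None):
        if not isinstance(dms, DistanceMatrixSet):
            dms = DistanceMatrixSet(dms, names=names)
        self.dms = dms

    @classmethod
    def from_files(cls, paths) -> "CADM":
        """Build from distance-matrix text files (square or lower-triangle)."""
        from .matrices import read_distance_matrix
        from pathlib import Path

        mats = [read_distance_matrix(p) for p in paths]
        return cls(DistanceMatrixSet(mats, names=[Path(p).stem for p in paths]))

    def statistic(self) -> CadmStatistic:
        """Descriptive W, S, T and chi^2 without any permutation test."""
        return kendall_w(RankTable.from_set(self.dms))

    def fit(
        self,
        n_permutations: int = 999,
        alpha: float = 0.05,
        seed: int | None = None,
        a_posteriori: bool = False,
        adjust: str = "holm",
    ) -> "CADMResults":
        """Run the global (and optionally the a posteriori) permutation test."""
        config = TestConfig(
            n_permutations=n_permutations, alpha=alpha, seed=seed, adjust=adjust
        )
        stat = global_test(self.dms, config)
        post = a_posteriori_tests(self.dms, config) if a_posteriori else None
        return CADMResults(self, config, stat, post)


class CADMResults:
    """Results of a congruence test.

    Attributes
    ----------
    W, S, T, chi2 : float
        Concordance, its numerator sum of squares, tie correction, pivot.
    p_value : float
        Global one-tailed permutation p-value.
    a_posteriori : APosterioriResult or None
    """

    def __init__(self, model: CADM, config: TestConfig, stat: CadmStatistic, post):
        self.model = model
        self.config = config
        self._stat = stat
        self.a_posteriori = post

    W = property(lambda self: self._stat.W)
    S = property(lambda self: self._stat.S)
    T = property(lambda self: self._stat.T)
    chi2 = property(lambda self: self._stat.chi2)
    p_value = property(lambda self: self._stat.p_value)
    n_permutations = property(lambda self: self._stat.n_permutations)

    @property
    def reject(self) -> bool:
        """Whether H0 (complete incongruence) is rejected at the nominal level."""
        return self.p_value <= self.config.alpha

    def summary(self) -> str:
        dms = self.model.dms
        lines = [
            "Congruence among distance matrices",
            "==================================",
            f"matrices (p):        {dms.n_matrices}",
            f"taxa (m):            {dms.n_taxa}",
            f"distances/matrix (n):{dms[0].n_distances:>6}",
            f"permutations:        {self.n_permutations}",
            "",
            f"Kendall's W:         {self.W:.6f}",
            f"Friedman chi2:       {self.chi2:.6f}",
            f"p-value (global):    {self.p_value:.6g}",
            f"H0 complete incongruence {'rejected' if self.reject else 'not rejected'}"
            f" at alpha = {self.config.alpha:g}",
        ]
        if self.a_posteriori is not None:
            lines += ["", "A posteriori tests (one matrix permuted at a time)",
                      self.a_posteriori.to_frame().to_string(index=False)]
        return "\n".join(lines)

    def to_report(self) -> str:
        """Tab-separated report: one global line, then one line per matrix."""
        out = [f"global\tW={self.W:.6f}\tchi2={self.chi2:.6f}\tp={self.p_value:.6g}"]
        if self.a_posteriori is not None:
            ap = self.a_posteriori
            for j, name in enumerate(ap.names):
                out.append(
                    f"{name}\tcongruence={ap.congruence[j]:.6f}"
                    f"\tp={ap.p_values[j]:.6g}\tp_adj={ap.adjusted[j]:.6g}"
                )
        return "\n".join(out) + "\n"

    def __repr__(self) -> str:
        return (
            f"<CADMResults W={self.W:.4f} chi2={self.chi2:.2f} "
            f"p={self.p_value:.4g}>"
        )
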