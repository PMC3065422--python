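"""Nucleotide sequence simulation under GTR + Gamma + invariant sites.

Simulates alignments along an unrooted tree under a general time-reversible
substitution model with continuous (or optionally discretized) gamma rate
variation across sites and a proportion of invariant sites. The root sequence
is drawn from the equilibrium frequencies at an arbitrary internal node;
reversibility makes the simulation law root-invariant.

Conventions
-----------
* The generator matrix is normalized to mean rate 1 at equilibrium before the
  global mutation-rate scale ``s`` multiplies branch lengths, so branch
  lengths are in expected substitutions per variable site.
* Invariant sites are rate-0 sites drawn i.i.d. with probability ``I``;
  gamma rates (shape ``alpha``, mean 1) apply to the remaining sites with no
  overall renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc

from .trees import PhyloTree

__all__ = [
    "GTRParameters",
    "Alignment",
    "build_rate_matrix",
    "transition_probabilities",
    "discrete_gamma_rates",
    "simulate_alignment",
    "write_fasta",
    "write_phylip",
    "read_alignment",
]

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}

# Empirical GTR + Gamma + I parameter set used throughout the simulation
# experiments (mammalian-like base composition, strong transition bias).
_DEFAULT_FREQS = (0.1776, 0.3336, 0.2595, 0.2293)
_DEFAULT_RATES = (3.297, 12.55, 1.167, 2.060, 13.01, 1.0)


@dataclass(frozen=True)
class GTRParameters:
    """GTR + Gamma + I model parameters.

    Parameters
    ----------
    freqs : (gA, gC, gG, gT)
        Equilibrium base frequencies, positive, summing to 1.
    rates : (rAC, rAG, rAT, rCG, rCT, rGT)
        Relative exchangeabilities (rGT conventionally 1).
    alpha : float
        Gamma shape of across-site rate variation (mean 1); large values
        (e.g. 200) approach rate homogeneity.
    p_invariant : float
        Proportion of invariant (rate-0) sites, in [0, 1).
    scale : float
        Global mutation-rate scale ``s`` multiplying branch lengths.
    gamma_categories : int or None
        ``None`` (default) draws continuous gamma rates; an integer uses that
        many equal-probability discrete categories (mean rate per bin).
    """

    freqs: tuple[float, float, float, float] = _DEFAULT_FREQS
    rates: tuple[float, float, float, float, float, float] = _DEFAULT_RATES
    alpha: float = 0.8168
    p_invariant: float = 0.5447
    scale: float = 1.0
    gamma_categories: int | None = None

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError(f"frequencies sum to {f.sum()!r}, not 1")
        if r.shape != (6,) or np.any(r <= 0):
            raise ValueError("need 6 positive exchange rates")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("invariant proportion must lie in [0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def with_(self, **kwargs) -> "GTRParameters":
        return replace(self, **kwargs)

    @property
    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


def build_rate_matrix(params: GTRParameters) -> np.ndarray:
    """GTR generator Q with Q[i,j] = r_ij * g_j (i != j), rows summing to 0,
    normalized to mean substitution rate 1 at equilibrium; satisfies detailed
    balance g_i Q[i,j] = g_j Q[j,i]."""
    g = params.freq_array
    rAC, rAG, rAT, rCG, rCT, rGT = params.rates
    R = np.array(
        [
            [0.0, rAC, rAG, rAT],
            [rAC, 0.0, rCG, rCT],
            [rAG, rCG, 0.0, rGT],
            [rAT, rCT, rGT, 0.0],
        ]
    )
    Q = R * g[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(g @ np.diag(Q))
    return Q / mean_rate


class _SpectralGTR:
    """Eigendecomposition of a reversible generator in the pi-weighted inner
    product: P(t) = A exp(Lambda t) B with A = Dg^{-1/2} V, B = V^T Dg^{1/2}."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        sq = np.sqrt(freqs)
        sym = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((sym + sym.T) / 2.0)
        self.lam = lam
        self.A = V / sq[:, None]
        self.B = V.T * sq[None, :]

    def probabilities(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)) @ self.B
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def rows_for_sites(self, states: np.ndarray, t_sites: np.ndarray) -> np.ndarray:
        """P(t_s)[states[s], :] for every site s, shape (n_sites, 4)."""
        ew = np.exp(np.outer(t_sites, self.lam))
        rows = (self.A[states] * ew) @ self.B
        np.clip(rows, 0.0, None, out=rows)
        return rows / rows.sum(axis=1, keepdims=True)


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition matrix exp(Q t) of a reversible generator via spectral
    decomposition; rows sum to 1, entries clipped against negative noise."""
    if not np.isfinite(t) or t < 0:
        raise ValueError("branch length must be finite and non-negative")
    from scipy.linalg import null_space

    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise ValueError("generator must have a unique stationary distribution")
    pi = ns[:, 0] / ns[:, 0].sum()
    return _SpectralGTR(Q, pi).probabilities(t)


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of a
    Gamma(shape=alpha, mean=1) distribution; averages to 1."""
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, n_categories + 1), a=alpha, scale=1.0 / alpha)
    # E[X ; X in bin] = F_{alpha+1}(edge * alpha) differences (mean-1 gamma)
    mass = gammainc(alpha + 1.0, edges[1:] * alpha) - gammainc(alpha + 1.0, edges[:-1] * alpha)
    return n_categories * mass


def draw_site_rates(
    L: int, params: GTRParameters, rng: np.random.Generator
) -> np.ndarray:
    """Per-site rate multipliers: 0 with probability I, else a gamma draw
    (continuous by default, or a random discrete category's mean rate)."""
    rates = np.empty(L)
    invariant = rng.random(L) < params.p_invariant
    n_var = int(L - invariant.sum())
    if params.gamma_categories is None:
        var_rates = rng.gamma(shape=params.alpha, scale=1.0 / params.alpha, size=n_var)
    else:
        cats = discrete_gamma_rates(params.alpha, params.gamma_categories)
        var_rates = cats[rng.integers(params.gamma_categories, size=n_var)]
    rates[invariant] = 0.0
    rates[~invariant] = var_rates
    return rates


@dataclass(frozen=True)
class Alignment:
    """Multiple sequence alignment over {A, C, G, T}.

    ``sequences`` is an (m, L) uint8 matrix with A,C,G,T encoded 0..3, rows
    ordered to match ``labels``.
    """

    labels: tuple[str, ...]
    sequences: np.ndarray

    def __post_init__(self):
        seqs = np.asarray(self.sequences)
        if seqs.ndim != 2 or seqs.shape[0] != len(self.labels):
            raise ValueError("sequences must be an (m, L) matrix matching labels")
        if seqs.shape[1] < 1:
            raise ValueError("alignment has zero length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def sequence_str(self, i: int) -> str:
        return "".join(NUCLEOTIDES[c] for c in self.sequences[i])

    @classmethod
    def from_strings(cls, labels, seqs) -> "Alignment":
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("ragged alignment: sequences differ in length")
        mat = np.zeros((len(seqs), L), dtype=np.uint8)
        for i, s in enumerate(seqs):
            try:
                mat[i] = [_CODE[c] for c in s.upper()]
            except KeyError as exc:
                raise ValueError(
                    f"unknown symbol {exc.args[0]!r} in sequence {labels[i]!r}"
                ) from exc
        return cls(tuple(str(x) for x in labels), mat)


def simulate_alignment(
    tree: PhyloTree,
    L: int,
    params: GTRParameters,
    rng: np.random.Generator,
) -> Alignment:
    """Simulate an alignment of length ``L`` along ``tree``.

    The root sequence is drawn from the equilibrium frequencies; each site
    carries one rate multiplier shared across the whole tree; a branch of
    length ``b`` uses transition matrix exp(Q * scale * b * rate); sites are
    independent.
    """
    if tree.n_leaves < 4:
        raise ValueError("need a tree with at least 4 leaves")
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    g = params.freq_array
    spectral = _SpectralGTR(build_rate_matrix(params), g)
    rates = draw_site_rates(L, params, rng)
    root, edges = tree.rooted_edges()
    states: dict[int, np.ndarray] = {
        root: rng.choice(4, size=L, p=g).astype(np.uint8)
    }
    for parent, child, length in edges:
        t_sites = params.scale * length * rates
        child_states = states[parent].copy()
        moving = t_sites > 0.0
        if np.any(moving):
            rows = spectral.rows_for_sites(child_states[moving], t_sites[moving])
            u = rng.random(int(moving.sum()))
            cdf = np.cumsum(rows, axis=1)
            child_states[moving] = (u[:, None] > cdf).sum(axis=1).astype(np.uint8)
        states[child] = child_states
    leaf_ids = sorted(tree.leaf_labels, key=tree.leaf_labels.__getitem__)
    labels = tuple(tree.leaf_labels[i] for i in leaf_ids)
    return Alignment(labels, np.array([states[i] for i in leaf_ids]))


# -- file formats ----------------------------------------------------------

def write_fasta(aln: Alignment, path=None) -> str:
    lines = []
    for i, lab in enumerate(aln.labels):
        lines.append(f">{lab}")
        seq = aln.sequence_str(i)
        lines.extend(seq[k : k + 70] for k in range(0, len(seq), 70))
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def write_phylip(aln: Alignment, path=None) -> str:
    """Relaxed sequential PHYLIP: header line, then 'label  sequence' rows."""
    width = max(len(x) for x in aln.labels)
    lines = [f"{aln.n_sequences} {aln.length}"]
    for i, lab in enumerate(aln.labels):
        lines.append(f"{lab:<{width}}  {aln.sequence_str(i)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def read_alignment(path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment (format inferred from the
    extension when ``fmt`` is None)."""
    from Bio import AlignIO

    if fmt is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        fmt = "fasta" if suffix in ("fa", "fasta", "fna") else "phylip-relaxed"
    elif fmt == "phylip":
        fmt = "phylip-relaxed"
    records = AlignIO.read(str(path), fmt)
    return Alignment.from_strings(
        [rec.id for rec in records], [str(rec.seq) for rec in records]
    )
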