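"""Genetic distances from alignments.

Two pairwise distances feed the congruence test: the uncorrected p distance
(proportion of differing sites) and a model-corrected distance — the
maximum-likelihood branch length separating two sequences under fixed
GTR + Gamma + I parameters (discrete-gamma mixture with a configurable
number of categories plus an invariant-sites class).

The corrected distance fixes the substitution-model parameters at the values
supplied (in the simulation experiments, the generating values) and optimizes
only the divergence time t per pair; all pairs are optimized simultaneously
by a vectorized golden-section search of the per-pair log-likelihood, which
depends on the data only through the 4 x 4 site-pattern count matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrices import DistanceMatrix
from .seqsim import (
    Alignment,
    GTRParameters,
    _SpectralGTR,
    build_rate_matrix,
    discrete_gamma_rates,
)

__all__ = ["p_distance", "corrected_distance"]


def _pair_counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4x4 site-pattern counts for every pair i < j."""
    m = aln.n_sequences
    iu, ju = np.triu_indices(m, k=1)
    seqs = aln.sequences.astype(np.intp)
    counts = np.empty((iu.size, 4, 4))
    for k in range(iu.size):
        joint = 4 * seqs[iu[k]] + seqs[ju[k]]
        counts[k] = np.bincount(joint, minlength=16).reshape(4, 4)
    return counts, iu, ju


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Uncorrected distance: proportion of sites at which two sequences
    differ."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    m, L = aln.n_sequences, aln.length
    values = np.zeros((m, m))
    for i in range(m):
        diff = (aln.sequences != aln.sequences[i]).mean(axis=1)
        values[i] = diff
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, list(aln.labels))


def _mixture_loglik(
    t: np.ndarray,
    counts: np.ndarray,
    spectral: _SpectralGTR,
    log_joint_weights: np.ndarray,
    cat_rates: np.ndarray,
    p_inv: float,
) -> np.ndarray:
    """Log-likelihood of each pair at its own divergence t.

    Site likelihood for pattern (a, b): g_a * [ I * delta_ab +
    (1 - I)/K * sum_c P(t r_c)[a, b] ]; summed over patterns with counts.
    """
    K = cat_rates.size
    npairs = t.size
    mix = np.zeros((npairs, 4, 4))
    for r in cat_rates:
        ew = np.exp(np.outer(t * r, spectral.lam))  # (npairs, 4)
        mix += (spectral.A[None, :, :] * ew[:, None, :]) @ spectral.B
    mix *= (1.0 - p_inv) / K
    if p_inv > 0.0:
        mix[:, np.arange(4), np.arange(4)] += p_inv
    np.clip(mix, 1e-300, None, out=mix)
    return np.einsum("pab,pab->p", counts, np.log(mix)) + log_joint_weights


def corrected_distance(
    aln: Alignment,
    params: GTRParameters,
    n_categories: int = 8,
    max_distance: float = 10.0,
    tol: float = 1e-8,
) -> DistanceMatrix:
    """Pairwise ML divergence under fixed GTR + Gamma + I parameters.

    Parameters
    ----------
    aln : Alignment
    params : GTRParameters
        The (known or assumed) substitution-model parameters; only the
        per-pair divergence is estimated. ``params.scale`` plays no role
        here — distances come out on the same per-variable-site scale the
        simulator uses for ``scale * branch_length``.
    n_categories : int
        Discrete-gamma resolution of the rate mixture.
    max_distance : float
        Saturation ceiling (substitutions/site); pairs whose likelihood keeps
        increasing to the ceiling are capped there with a warning.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    counts, iu, ju = _pair_counts(aln)
    spectral = _SpectralGTR(build_rate_matrix(params), params.freq_array)
    cat_rates = discrete_gamma_rates(params.alpha, n_categories)
    # constant term: log g_a contributions
    g = params.freq_array
    log_g_term = np.einsum("pab,a->p", counts, np.log(g))

    def loglik(t: np.ndarray) -> np.ndarray:
        return _mixture_loglik(t, counts, spectral, log_g_term, cat_rates, params.p_invariant)

    lo = np.full(iu.size, 1e-9)
    hi = np.full(iu.size, max_distance)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1, f2 = loglik(x1), loglik(x2)
    while np.max(hi - lo) > tol:
        shrink_right = f1 >= f2  # maximum in [lo, x2]
        hi = np.where(shrink_right, x2, hi)
        lo = np.where(shrink_right, lo, x1)
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1, f2 = loglik(x1), loglik(x2)
    t_hat = (lo + hi) / 2.0
    # identical pairs sit at the lower boundary: make them exactly zero
    off_diag = counts.sum(axis=(1, 2)) - np.einsum("paa->p", counts)
    t_hat[off_diag == 0] = 0.0
    saturated = t_hat > max_distance * (1.0 - 1e-6)
    if np.any(saturated):
        warnings.warn(
            f"{int(saturated.sum())} saturated pair(s) capped at {max_distance}",
            stacklevel=2,
        )
        t_hat[saturated] = max_distance
    m = aln.n_sequences
    values = np.zeros((m, m))
    values[iu, ju] = values[ju, iu] = t_hat
    return DistanceMatrix(values, list(aln.labels))
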