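"""Monte-Carlo experiment harness: type-I error and power grids.

One experiment cell fixes a data-generating condition — number of matrices M,
how many are congruent and how (identical tree vs. a partially
taxon-permuted tree), taxon count, sequence length, substitution-model
parameters per matrix — and estimates the rejection rate of the congruence
test over replicates, with a normal-approximation 95% confidence interval.

Replicate protocol (per replicate):
1. random additive distance matrices are generated (one shared base matrix
   for the congruent members, independent ones for the incongruent members);
2. neighbor-joining trees are inferred from them;
3. sequences are simulated on the trees and distances recomputed at the
   configured level (genetic corrected/p distance, path-length, or
   topological);
4. the global (and optionally a posteriori) permutation test is run.

Each replicate draws its generator from an independent child of the master
seed, so grids parallelize without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import corrected_distance, p_distance
from .matrices import DistanceMatrix, DistanceMatrixSet
from .permutation import TestConfig, a_posteriori_tests, global_test
from .seqsim import GTRParameters, simulate_alignment
from .trees import (
    neighbor_joining,
    permute_taxa_partial,
    random_additive_tree,
    tree_to_distances,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_replicate",
    "run_experiment",
    "rejection_rate",
    "run_grid",
    "load_experiment_configs",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of a simulation grid.

    ``n_congruent`` matrices derive from a single base tree — identically
    (``congruence="identical"``, CM_I) or with a fraction
    ``permuted_proportion`` of taxa label-permuted per matrix
    (``congruence="partial"``, CM_P) — and the remaining matrices from
    independent random trees. ``params`` may be a single parameter set or one
    per matrix (e.g. contrasting gamma shapes).
    """

    n_taxa: int = 10
    seq_length: int = 1000
    n_matrices: int = 5
    n_congruent: int = 0
    congruence: str = "identical"  # "identical" (CM_I) or "partial" (CM_P)
    permuted_proportion: float = 0.4
    permutation_scheme: str = "uniform"  # "uniform" | "derangement"
    params: GTRParameters | tuple[GTRParameters, ...] = field(
        default_factory=GTRParameters
    )
    level: str = "genetic"  # "genetic" | "path_length" | "topological"
    distance: str = "corrected"  # "corrected" | "p" (genetic level only)
    branch_length_mean: float = 0.1
    n_replicates: int = 100
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int | None = None
    a_posteriori: bool = False

    def __post_init__(self):
        if self.n_matrices < 2:
            raise ValueError("need at least 2 matrices per set")
        if not 0 <= self.n_congruent <= self.n_matrices:
            raise ValueError("n_congruent must lie in [0, n_matrices]")
        if self.n_congruent == 1:
            raise ValueError("a single 'congruent' matrix has no partner")
        if self.congruence not in ("identical", "partial"):
            raise ValueError(f"unknown congruence kind {self.congruence!r}")
        if self.level not in ("genetic", "path_length", "topological"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.distance not in ("corrected", "p"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if isinstance(self.params, Sequence):
            if len(self.params) != self.n_matrices:
                raise ValueError("per-matrix params must match n_matrices")
            object.__setattr__(self, "params", tuple(self.params))

    def params_for(self, k: int) -> GTRParameters:
        if isinstance(self.params, tuple):
            return self.params[k]
        return self.params

    def test_config(self) -> TestConfig:
        return TestConfig(
            n_permutations=self.n_permutations, alpha=self.alpha, adjust="none"
        )


@dataclass(frozen=True)
class ExperimentResult:
    """Rejection-rate estimate of one cell."""

    rate: float
    ci: tuple[float, float]
    n_replicates: int
    n_failed: int
    p_values: np.ndarray
    config: ExperimentConfig | None = None
    per_matrix_rates: np.ndarray | None = None

    @property
    def ci_half_width(self) -> float:
        return (self.ci[1] - self.ci[0]) / 2.0


def run_replicate(config: ExperimentConfig, rng: np.random.Generator) -> dict:
    """Simulate one replicate and run the congruence test; returns a record
    with W, chi2, p, the rejection flag and (optionally) a posteriori
    p-values."""
    m, M, CM = config.n_taxa, config.n_matrices, config.n_congruent
    source_dms: list[DistanceMatrix] = []
    if CM > 0:
        base = tree_to_distances(
            random_additive_tree(m, rng, config.branch_length_mean)
        )
    for k in range(M):
        if k < CM:
            if config.congruence == "identical":
                source_dms.append(base)
            else:
                source_dms.append(
                    permute_taxa_partial(
                        base,
                        config.permuted_proportion,
                        rng,
                        scheme=config.permutation_scheme,
                    )
                )
        else:
            source_dms.append(
                tree_to_distances(
                    random_additive_tree(m, rng, config.branch_length_mean)
                )
            )
    observed: list[DistanceMatrix] = []
    for k, dm in enumerate(source_dms):
        tree = neighbor_joining(dm)
        if config.level == "genetic":
            pk = config.params_for(k)
            aln = simulate_alignment(tree, config.seq_length, pk, rng)
            if config.distance == "corrected":
                observed.append(corrected_distance(aln, pk))
            else:
                observed.append(p_distance(aln))
        else:
            mode = "path_length" if config.level == "path_length" else "topological"
            observed.append(tree_to_distances(tree, mode))
    dms = DistanceMatrixSet(observed)
    tconf = config.test_config()
    stat = global_test(dms, tconf, rng=rng)
    record = {
        "W": stat.W,
        "chi2": stat.chi2,
        "p_value": stat.p_value,
        "reject": stat.p_value <= config.alpha,
    }
    if config.a_posteriori:
        post = a_posteriori_tests(dms, tconf, rng=rng)
        record["post_p_values"] = post.p_values
        record["post_congruence"] = post.congruence
    return record


def rejection_rate(
    p_values: Sequence[float],
    alpha: float = 0.05,
    *,
    n_failed: int = 0,
    config: ExperimentConfig | None = None,
    per_matrix_rates: np.ndarray | None = None,
    ci_method: str = "normal",
) -> ExperimentResult:
    """Proportion of replicates with p <= alpha, with a 95% CI.

    The default CI is the normal approximation rate +/- 1.96 sqrt(rate (1 -
    rate) / n) (degenerate at rates 0 and 1); ``ci_method="clopper-pearson"``
    gives the exact interval instead.
    """
    p_values = np.asarray(list(p_values), dtype=float)
    n = p_values.size
    if n == 0:
        raise ValueError("no successful replicates")
    k = int(np.sum(p_values <= alpha))
    rate = k / n
    if ci_method == "normal":
        half = 1.96 * np.sqrt(rate * (1.0 - rate) / n)
        ci = (rate - half, rate + half)
    elif ci_method == "clopper-pearson":
        from scipy.stats import beta

        lo = beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
        ci = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ExperimentResult(
        rate=rate,
        ci=ci,
        n_replicates=n,
        n_failed=n_failed,
        p_values=p_values,
        config=config,
        per_matrix_rates=per_matrix_rates,
    )


def run_experiment(
    config: ExperimentConfig, progress: bool = False
) -> ExperimentResult:
    """Run all replicates of a cell.

    Each replicate uses an independent stream spawned from the master seed;
    failed replicates are counted, never silently dropped.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    p_values: list[float] = []
    post: list[np.ndarray] = []
    n_failed = 0
    iterator = enumerate(streams)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="replicates")
    for _, stream in iterator:
        rng = np.random.default_rng(stream)
        try:
            record = run_replicate(config, rng)
        except Exception:
            n_failed += 1
            continue
        p_values.append(record["p_value"])
        if config.a_posteriori:
            post.append(record["post_p_values"])
    per_matrix = None
    if post:
        per_matrix = (np.array(post) <= config.alpha).mean(axis=0)
    return rejection_rate(
        p_values,
        config.alpha,
        n_failed=n_failed,
        config=config,
        per_matrix_rates=per_matrix,
    )


def run_grid(configs: Sequence[ExperimentConfig], progress: bool = False) -> pd.DataFrame:
    """Run a list of cells; one output row per cell, mirroring the layout of
    the published tables (rows m x L, columns CM or parameter contrast)."""
    rows = []
    for cfg in configs:
        res = run_experiment(cfg, progress=progress)
        rows.append(
            {
                "m": cfg.n_taxa,
                "L": cfg.seq_length,
                "M": cfg.n_matrices,
                "CM": cfg.n_congruent,
                "kind": cfg.congruence if cfg.n_congruent else "none",
                "level": cfg.level,
                "rate": res.rate,
                "ci_low": res.ci[0],
                "ci_high": res.ci[1],
                "replicates": res.n_replicates,
                "failures": res.n_failed,
            }
        )
    return pd.DataFrame(rows)


def _params_from_mapping(mapping: dict) -> GTRParameters:
    return GTRParameters(**mapping)


def load_experiment_configs(path) -> list[ExperimentConfig]:
    """Load a grid from a YAML file.

    Top-level keys are shared defaults (any :class:`ExperimentConfig` field;
    ``model`` maps to a shared GTRParameters, ``models`` to per-matrix ones);
    the ``grid`` key lists per-cell overrides.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cells = doc.pop("grid", [{}])
    configs = []
    for cell in cells:
        merged = {**doc, **(cell or {})}
        model = merged.pop("model", None)
        models = merged.pop("models", None)
        if models is not None:
            merged["params"] = tuple(_params_from_mapping(m) for m in models)
        elif model is not None:
            merged["params"] = _params_from_mapping(model)
        configs.append(ExperimentConfig(**merged))
    return configs
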