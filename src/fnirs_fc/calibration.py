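"""Self-validation routines: oracle comparisons and statistical calibration.

These functions re-derive the pipeline's key guarantees from scratch —
brute-force graph-metric oracles, null retention rates of the surrogate
threshold, type-I error and power of the repeated-measures ANOVA on
simulated cohorts, and sign recovery of the planted brain-behaviour
coupling.  They are used by the acceptance tests and the reproduction
script; the brute-force oracles are deliberately naive (edge counting,
triple enumeration, Floyd-Warshall) so they stay independent of the
production implementations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import connectivity as conn
from .graph_metrics import (
    clustering_coefficient, global_density, global_efficiency,
)
from .pipeline import PipelineConfig, surrogate_metric_table
from .simulate import SimulationSpec, generate_cohort
from .stats import (
    brain_behavior_correlation, delta_wd, log_transform, rm_anova,
    score_changes,
)


# ---------------------------------------------------------------------------
# brute-force graph oracles


def brute_force_density(adj: np.ndarray) -> float:
    n = adj.shape[0]
    edges = sum(adj[i, j] > 0 for i in range(n) for j in range(i + 1, n))
    return 2.0 * edges / (n * (n - 1))


def brute_force_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[u, v] > 0 for a, u in enumerate(nbrs)
                    for v in nbrs[a + 1:])
        total += 2.0 * links / (k * (k - 1))
    return total / n


def brute_force_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    total = sum(1.0 / dist[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(dist[i, j]))
    return total / (n * (n - 1))


def graph_metric_oracle_error(n_graphs: int = 200, n_nodes: int = 12,
                              seed: int = 0) -> float:
    """Max |implementation - brute force| over D, C, E on random graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        p = rng.uniform(0.1, 0.9)
        a = (rng.random((n_nodes, n_nodes)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        net = conn.ThresholdedNetwork(weights=a, scheme="absolute",
                                      parameter=0.5, binary=True)
        worst = max(
            worst,
            abs(global_density(net) - brute_force_density(a)),
            abs(clustering_coefficient(net) - brute_force_clustering(a)),
            abs(global_efficiency(net) - brute_force_efficiency(a)),
        )
    return worst


# ---------------------------------------------------------------------------
# thresholding calibration


def surrogate_null_retention(n_replicates: int = 200, n_channels: int = 48,
                             n_samples: int = 39, alpha: float = 0.05,
                             seed: int = 0) -> float:
    """Mean retained-edge fraction under channel-independent Gaussian noise.

    Only positive correlations with two-sided p < alpha survive, so the
    expected retention under the null is alpha/2.
    """
    rng = np.random.default_rng(seed)
    total_kept = 0
    total_edges = 0
    for _ in range(n_replicates):
        x = rng.standard_normal((n_samples, n_channels))
        cm = conn.pearson_matrix(x)
        net = conn.threshold_surrogate(cm, alpha)
        total_kept += net.n_edges
        total_edges += n_channels * (n_channels - 1) // 2
    return total_kept / total_edges


# ---------------------------------------------------------------------------
# cohort-level simulations


def null_spec(seed: int, n_subjects: int = 10) -> SimulationSpec:
    """Cohort with no planted task or sleep effects (full null).

    Calibration cohorts are generated artifact-free and analysed without
    the despiking stage (which is the identity on artifact-free data), so
    the simulated fast path matches the full pipeline.
    """
    base = SimulationSpec(n_subjects=n_subjects, seed=seed)
    plan = dataclasses.replace(base.plan(), task_modulation=0.0,
                               sd_modulation=0.0)
    return dataclasses.replace(base, connectivity_plan=plan,
                               subject_jitter_sd=0.0, pal_slope=0.0,
                               artifact_rate_per_min=0.0)


def large_effect_spec(seed: int, n_subjects: int = 20) -> SimulationSpec:
    """Cohort with a strong attenuation of the task effect after SD."""
    base = SimulationSpec(n_subjects=n_subjects, seed=seed)
    plan = dataclasses.replace(base.plan(), task_modulation=-0.30,
                               sd_modulation=0.25)
    return dataclasses.replace(base, connectivity_plan=plan,
                               artifact_rate_per_min=0.0)


def _interaction_p(spec: SimulationSpec, config: PipelineConfig) -> float:
    cohort = generate_cohort(spec)
    table = surrogate_metric_table(cohort.recordings, config)
    logged = log_transform(table)
    res = rm_anova(logged.select("surrogate", "avg_degree"))
    return res["sleep_state*task_state"].p_reported


def anova_interaction_type1(n_reps: int = 500, n_subjects: int = 10,
                            seed: int = 0, alpha: float = 0.05,
                            config: PipelineConfig | None = None) -> float:
    """Rejection rate of the sleep x task interaction on null cohorts."""
    config = config or PipelineConfig(wavelet_enabled=False)
    hits = 0
    for r in range(n_reps):
        if _interaction_p(null_spec(seed * 100_003 + r), config) < alpha:
            hits += 1
    return hits / n_reps


def anova_interaction_power(n_reps: int = 100, n_subjects: int = 20,
                            seed: int = 0, alpha: float = 0.05,
                            config: PipelineConfig | None = None) -> float:
    """Rejection rate under the large planted sleep x task effect."""
    config = config or PipelineConfig(wavelet_enabled=False)
    hits = 0
    for r in range(n_reps):
        spec = large_effect_spec(seed * 100_003 + r, n_subjects)
        if _interaction_p(spec, config) < alpha:
            hits += 1
    return hits / n_reps


def delta_wd_sign_recovery(n_reps: int = 20, n_subjects: int = 50,
                           seed: int = 0,
                           config: PipelineConfig | None = None) -> float:
    """Fraction of cohorts recovering the planted negative Delta-WD/PAL slope.

    Cohorts use the default (negative) coupling with low score noise; a rep
    counts as recovered when the estimated Pearson correlation between the
    pipeline's Delta-WD and the PAL change is negative.
    """
    config = config or PipelineConfig(wavelet_enabled=False)
    hits = 0
    for r in range(n_reps):
        spec = dataclasses.replace(
            SimulationSpec(n_subjects=n_subjects, seed=seed * 99_991 + r),
            score_noise_sd=0.2, artifact_rate_per_min=0.0,
        )
        cohort = generate_cohort(spec)
        table = surrogate_metric_table(cohort.recordings, config)
        dwd = delta_wd(table.select("surrogate", "WD"))
        corr = brain_behavior_correlation(
            dwd, score_changes(cohort.cognitive_scores)).set_index("test")
        if corr.loc["PAL", "r"] < 0:
            hits += 1
    return hits / n_reps
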