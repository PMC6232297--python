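"""Monte-Carlo benchmarks of the correlation-network pipeline.

Two standing experiments, both run on the synthetic generator with
seasonality disabled (so that the complement of the planted edges is a true
null):

* planted-edge recovery — 20 disjoint pairs planted at r = +0.8 among the 40
  most abundant OTUs of a 24-sample (one reservoir-block) survey, recovered
  through the full pipeline (relative abundance, abundance/prevalence filter,
  pairwise Pearson, BH FDR at 5%, signed networks);
* global-null false-discovery — the same pipeline with nothing planted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import build_networks, pairwise_correlations
from .preprocess import filter_network_otus, relative_abundance, zscore_env
from .simulate import SyntheticConfig, evaluate_recovery, generate_dataset

__all__ = ["RecoveryBenchmarkResult", "recovery_benchmark",
           "null_fdr_benchmark", "planted_benchmark_edges"]


def planted_benchmark_edges(n_pairs: int = 20, target_r: float = 0.8) -> list:
    """Disjoint planted pairs among the most abundant OTUs."""
    otus = [f"OTU_{i + 1:04d}" for i in range(2 * n_pairs)]
    return [(otus[2 * j], otus[2 * j + 1], target_r) for j in range(n_pairs)]


@dataclass
class RecoveryBenchmarkResult:
    mean_tpr: float
    mean_fdp: float
    mean_sign_accuracy: float
    n_replicates: int


def _run_pipeline_once(config: SyntheticConfig):
    otus, env, truth = generate_dataset(config)
    filtered = filter_network_otus(relative_abundance(otus))
    corr = pairwise_correlations(filtered, zscore_env(env))
    return corr, truth


def recovery_benchmark(n_replicates: int = 50, seed: int = 1000,
                       target_r: float = 0.8,
                       n_pairs: int = 20) -> RecoveryBenchmarkResult:
    """Mean TPR / FDP / sign accuracy over seeded replicate surveys."""
    edges = planted_benchmark_edges(n_pairs, target_r)
    tprs, fdps, signs = [], [], []
    for rep in range(n_replicates):
        config = SyntheticConfig(n_reservoirs=1, seasonal_amplitude=0.0,
                                 planted_edges=edges, seed=seed + rep)
        corr, truth = _run_pipeline_once(config)
        metrics = evaluate_recovery(truth, build_networks(corr))
        tprs.append(metrics.tpr)
        fdps.append(metrics.fdp)
        if metrics.sign_accuracy is not None:
            signs.append(metrics.sign_accuracy)
    return RecoveryBenchmarkResult(
        mean_tpr=float(np.mean(tprs)),
        mean_fdp=float(np.mean(fdps)),
        mean_sign_accuracy=float(np.mean(signs)) if signs else float("nan"),
        n_replicates=n_replicates,
    )


def null_fdr_benchmark(n_replicates: int = 15, seed: int = 5000,
                       n_otus: int = 50) -> dict:
    """Discovery behaviour under the global null (nothing planted)."""
    raw_fracs, discoveries, n_tests = [], [], []
    for rep in range(n_replicates):
        config = SyntheticConfig(n_reservoirs=1, n_otus=n_otus,
                                 seasonal_amplitude=0.0, seed=seed + rep)
        corr, _ = _run_pipeline_once(config)
        ok = corr["r"].notna()
        raw_fracs.append(float((corr.loc[ok, "p"] < 0.05).mean()))
        discoveries.append(int(corr["significant"].sum()))
        n_tests.append(int(ok.sum()))
    return {
        "mean_raw_p_fraction": float(np.mean(raw_fracs)),
        "se_raw_p_fraction": float(np.std(raw_fracs, ddof=1)
                                   / np.sqrt(n_replicates)),
        "mean_bh_discoveries": float(np.mean(discoveries)),
        "mean_n_tests": float(np.mean(n_tests)),
        "n_replicates": n_replicates,
    }
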