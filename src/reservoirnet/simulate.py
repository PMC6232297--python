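"""Synthetic community generator with planted correlation structure.

Emulates a two-reservoir monthly survey: per reservoir, two sites sampled
every month for a year (24 samples per reservoir).  OTU abundances are
log-normal latents coupled through a Gaussian copula; planted pairwise
correlations (OTU-OTU, OTU-env or env-env) target the Pearson correlation on
the latent abundance scale, so the copula correlation is obtained by
inverting the bivariate-lognormal correlation map and compensating for the
variance the seasonal and noise components add to environmental variables.
The realized Pearson correlation on the latent (pre-count-sampling) values is
then centered on the requested target; targets outside the achievable range
of a lognormal pair are rejected.  Counts are
drawn per sample by multinomial sampling at a Poisson sequencing depth, which
mimics the compositional nature of amplicon data.  Ground truth (planted
edges with realized correlations) is returned for recovery benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EnvTable, OTUTable

__all__ = [
    "DEFAULT_ENV_NAMES",
    "SyntheticConfig",
    "GroundTruth",
    "RecoveryMetrics",
    "generate_dataset",
    "evaluate_recovery",
]

#: the 15 environmental variables of the survey this generator emulates
DEFAULT_ENV_NAMES = (
    "chl_a", "pH", "turbidity", "TN", "TP", "TN_TP", "temperature",
    "chloride", "sulfate", "Ca", "Mg", "cyano_16S",
    "rain_1d", "rain_5d", "rain_30d",
)


@dataclass
class SyntheticConfig:
    """Design and statistical parameters of a synthetic survey.

    ``otu_log_mean_decay`` sets the rank-abundance slope of the mean log
    latent abundance (mu_i = -decay * i), ``otu_log_sd`` the month-to-month
    biological variability on the log scale.  ``seasonal_amplitude`` scales a
    sinusoidal seasonal driver added to every environmental variable on top
    of unit-variance noise.  ``planted_edges`` lists (node_a, node_b,
    target_r) correlations to impose; node names must be OTU ids
    ("OTU_0001", ...) or environmental variable names.
    """

    n_reservoirs: int = 2
    n_sites_per_reservoir: int = 2
    n_months: int = 12
    n_otus: int = 200
    n_env: int = 15
    sequencing_depth: int = 60000
    otu_log_mean_decay: float = 0.05
    otu_log_sd: float = 0.5
    seasonal_amplitude: float | Sequence[float] = 1.0
    env_noise_sd: float = 1.0
    planted_edges: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_reservoirs", "n_sites_per_reservoir", "n_months",
                     "n_otus", "n_env", "sequencing_depth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.otu_log_sd <= 0 or self.env_noise_sd <= 0:
            raise ValueError("otu_log_sd and env_noise_sd must be positive")
        for a, b, r in self.planted_edges:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation {r} for ({a}, {b}) "
                                 "outside [-1, 1]")
            if a == b:
                raise ValueError(f"self-edge on {a!r}")

    @property
    def otu_ids(self) -> list:
        width = max(4, len(str(self.n_otus)))
        return [f"OTU_{i + 1:0{width}d}" for i in range(self.n_otus)]

    @property
    def env_names(self) -> list:
        names = list(DEFAULT_ENV_NAMES[: self.n_env])
        names += [f"env_{i + 1}" for i in range(len(names), self.n_env)]
        return names

    @property
    def n_samples(self) -> int:
        return self.n_reservoirs * self.n_sites_per_reservoir * self.n_months

    def seasonal_amplitudes(self) -> np.ndarray:
        amp = np.asarray(self.seasonal_amplitude, dtype=float)
        if amp.ndim == 0:
            amp = np.full(self.n_env, float(amp))
        if amp.shape != (self.n_env,):
            raise ValueError("seasonal_amplitude must be scalar or length n_env")
        return amp


@dataclass
class GroundTruth:
    """Planted edges with their realized latent-scale Pearson correlations."""

    planted_edges: list  # (node_a, node_b, target_r, realized_r)
    nodes: set

    def planted_pairs(self) -> dict:
        return {frozenset((a, b)): r for a, b, r, _ in self.planted_edges}


@dataclass
class RecoveryMetrics:
    """How well a pair of signed networks recovers the planted edges."""

    tpr: Optional[float]
    fdp: float
    sign_accuracy: Optional[float]
    n_planted: int
    n_recovered: int
    n_network_edges: int


def _copula_correlation(config: SyntheticConfig, seasonal: np.ndarray,
                        amp: np.ndarray) -> np.ndarray:
    """Latent (copula-scale) correlation matrix realizing the planted targets.

    ``target_r`` is the Pearson correlation on the latent *abundance* scale
    (and on env values), so the Gaussian-copula correlation is obtained by
    inverting the bivariate-lognormal correlation map for OTU-OTU pairs, the
    lognormal-normal map for OTU-env pairs, and compensating environmental
    variables for the variance their seasonal component adds.  Targets
    outside the achievable range of these maps (e.g. strong negative
    correlations between lognormal abundances) are rejected explicitly.
    """
    otu_ids = config.otu_ids
    env_names = config.env_names
    index = {name: i for i, name in enumerate(otu_ids + env_names)}
    q = len(index)
    n_otus = config.n_otus
    noise = config.env_noise_sd
    s2 = config.otu_log_sd**2
    ln_excess = np.expm1(s2)  # e^{sigma^2} - 1 of the lognormal latents
    # population moments of the seasonal component over the sample design
    s_var = seasonal.var(axis=0)
    corr = np.eye(q)

    def _infeasible(target, a, b, detail):
        return ValueError(
            f"planted correlation {target} between {a!r} and {b!r} is "
            f"infeasible: {detail}"
        )

    for a, b, target in config.planted_edges:
        for name in (a, b):
            if name not in index:
                raise ValueError(f"planted edge references unknown node {name!r}")
        ia, ib = index[a], index[b]
        both_otu = ia < n_otus and ib < n_otus
        both_env = ia >= n_otus and ib >= n_otus
        if both_otu:
            arg = 1.0 + target * ln_excess
            if arg <= 0:
                raise _infeasible(
                    target, a, b,
                    "below the minimum correlation of lognormal abundances "
                    f"(-1/(e^sigma^2 - 1) = {-1 / ln_excess:.3f})",
                )
            r_z = np.log(arg) / s2
        elif both_env:
            va, vb = ia - n_otus, ib - n_otus
            sd_a = np.sqrt(amp[va] ** 2 * s_var[va] + noise**2)
            sd_b = np.sqrt(amp[vb] ** 2 * s_var[vb] + noise**2)
            s_cov = np.cov(seasonal[:, va], seasonal[:, vb], ddof=0)[0, 1]
            r_z = (target * sd_a * sd_b - amp[va] * amp[vb] * s_cov) / noise**2
        else:
            v = (ib if ib >= n_otus else ia) - n_otus
            sd_env = np.sqrt(amp[v] ** 2 * s_var[v] + noise**2)
            # corr(lognormal, normal) = r_z * sigma / sqrt(e^{sigma^2} - 1)
            r_z = (target * np.sqrt(ln_excess) / config.otu_log_sd
                   * sd_env / noise)
        if abs(r_z) > 1.0 + 1e-12:
            raise _infeasible(
                target, a, b,
                f"implied copula correlation |{r_z:.3f}| > 1 after "
                "lognormal/seasonal compensation",
            )
        corr[ia, ib] = corr[ib, ia] = float(np.clip(r_z, -1.0, 1.0))
    return corr


def _factor(corr: np.ndarray) -> np.ndarray:
    """PSD square root of the copula correlation; rejects infeasible sets."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8:
        raise ValueError(
            "planted correlation set is infeasible: implied latent "
            f"correlation matrix is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3g})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_dataset(config: SyntheticConfig):
    """Generate (OTUTable, EnvTable, GroundTruth) under ``config``.

    Byte-identical output under identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    otu_ids = config.otu_ids
    env_names = config.env_names
    amp = config.seasonal_amplitudes()

    # sample design
    sample_ids, meta_rows, months = [], [], []
    for ri in range(config.n_reservoirs):
        reservoir = chr(ord("A") + ri)
        for si in range(config.n_sites_per_reservoir):
            site = f"{reservoir}S{si + 1}"
            for mi in range(config.n_months):
                sample_ids.append(f"{reservoir}_{site}_M{mi + 1:02d}")
                meta_rows.append((reservoir, site, mi + 1))
                months.append(mi)
    months = np.asarray(months)
    n_samples = len(sample_ids)
    metadata = pd.DataFrame(meta_rows, columns=["reservoir", "site", "month"],
                            index=pd.Index(sample_ids, name="sample"))

    # deterministic seasonal drivers, one phase per variable
    phases = 2 * np.pi * np.arange(config.n_env) / config.n_env
    seasonal = np.sin(
        2 * np.pi * months[:, None] / config.n_months + phases[None, :]
    )

    corr = _copula_correlation(config, seasonal, amp)
    half = _factor(corr)
    z = rng.standard_normal((n_samples, corr.shape[0])) @ half.T

    # latent log abundances and relative abundances
    mu = -config.otu_log_mean_decay * np.arange(config.n_otus)
    log_latent = mu[None, :] + config.otu_log_sd * z[:, : config.n_otus]
    latent = np.exp(log_latent)
    latent_rel = latent / latent.sum(axis=1, keepdims=True)

    depths = np.maximum(rng.poisson(config.sequencing_depth, size=n_samples), 1)
    counts = np.empty((n_samples, config.n_otus), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(depths[s], latent_rel[s])

    env_values = (amp[None, :] * seasonal
                  + config.env_noise_sd * z[:, config.n_otus:])

    otu_table = OTUTable(
        pd.DataFrame(counts, index=metadata.index, columns=otu_ids),
        metadata=metadata,
    )
    env_table = EnvTable(
        pd.DataFrame(env_values, index=metadata.index, columns=env_names)
    )

    # realized correlations on the latent (pre-count-sampling) values:
    # latent relative abundances for OTUs, generated values for env variables
    latent_cols = {name: latent_rel[:, i] for i, name in enumerate(otu_ids)}
    latent_cols.update({name: env_values[:, v] for v, name in enumerate(env_names)})
    planted = []
    for a, b, target in config.planted_edges:
        realized = float(np.corrcoef(latent_cols[a], latent_cols[b])[0, 1])
        planted.append((a, b, float(target), realized))
    truth = GroundTruth(planted, nodes=set(otu_ids) | set(env_names))
    return otu_table, env_table, truth


def evaluate_recovery(truth: GroundTruth, networks) -> RecoveryMetrics:
    """Score a (co-occurrence, co-exclusion) graph pair against ground truth.

    TPR: fraction of planted edges present in either graph (undefined when
    nothing was planted); sign accuracy: fraction of recovered edges found in
    the graph matching the planted sign; FDP: fraction of network edges that
    were not planted.
    """
    pos, neg = networks
    offenders = sorted((set(pos.nodes) | set(neg.nodes)) - truth.nodes)
    if offenders:
        raise ValueError(f"network nodes absent from ground truth: {offenders}")
    pos_edges = {frozenset(e) for e in pos.edges}
    neg_edges = {frozenset(e) for e in neg.edges}
    all_edges = pos_edges | neg_edges
    planted = truth.planted_pairs()

    n_planted = len(planted)
    recovered = [pair for pair in planted if pair in all_edges]
    correct_sign = sum(
        1 for pair in recovered
        if pair in (pos_edges if planted[pair] > 0 else neg_edges)
    )
    false_edges = [e for e in all_edges if e not in planted]
    tpr = len(recovered) / n_planted if n_planted else None
    sign_acc = correct_sign / len(recovered) if recovered else None
    fdp = len(false_edges) / len(all_edges) if all_edges else 0.0
    return RecoveryMetrics(
        tpr=tpr, fdp=fdp, sign_accuracy=sign_acc, n_planted=n_planted,
        n_recovered=len(recovered), n_network_edges=len(all_edges),
    )
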