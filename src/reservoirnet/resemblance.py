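"""Resemblance matrices, ordination and permutation-based multivariate tests.

Bray-Curtis similarity (0-100 scale) on square-root-transformed relative
abundances and Euclidean distance on normalized environmental variables feed
non-metric MDS, PERMANOVA, ANOSIM, SIMPER, distance-based linear models
(DistLM, marginal and forward-selection), RELATE (matrix rank correlation)
and the BEST/BIOENV subset search.  All permutation p-values follow the
(count + 1)/(n_perm + 1) convention and are reproducible under a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from sklearn.isotonic import IsotonicRegression

from .containers import SQRT_RELATIVE, EnvTable, RelAbundanceTable

__all__ = [
    "ResemblanceMatrix",
    "OrdinationResult",
    "PermTestResult",
    "SelectionResult",
    "BestResult",
    "bray_curtis",
    "euclidean",
    "nmds",
    "permanova",
    "anosim",
    "simper",
    "distlm_marginal",
    "distlm_forward",
    "pseudo_f_from_prop",
    "relate",
    "bioenv_best",
]

BRAY_CURTIS = "bray-curtis-similarity"
EUCLIDEAN = "euclidean-distance"


@dataclass
class ResemblanceMatrix:
    """Square symmetric resemblance among samples.

    ``kind`` is either Bray-Curtis *similarity* on the PRIMER-style 0-100
    scale (diagonal 100) or Euclidean *distance* (diagonal 0).
    """

    ids: list
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("resemblance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("resemblance matrix must be symmetric")
        if self.kind == BRAY_CURTIS:
            if v.min() < -1e-9 or v.max() > 100 + 1e-9:
                raise ValueError("Bray-Curtis similarities must lie in [0, 100]")
            np.fill_diagonal(v, 100.0)
        elif self.kind == EUCLIDEAN:
            if v.min() < -1e-9:
                raise ValueError("distances must be nonnegative")
            np.fill_diagonal(v, 0.0)
        else:
            raise ValueError(f"unknown resemblance kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_distance(self) -> np.ndarray:
        """Dissimilarity form: 100 - S for Bray-Curtis, identity for distance."""
        if self.kind == BRAY_CURTIS:
            return 100.0 - self.values
        return self.values.copy()


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


@dataclass
class PermTestResult:
    statistic_name: str
    statistic: float
    n_perm: int
    p_perm: float


@dataclass
class SelectionResult:
    """Forward-selection path of a distance-based linear model."""

    steps: pd.DataFrame  # variable, ss_cond, pseudo_f, p_perm, cumulative_prop
    selected: list


@dataclass
class BestResult:
    selected: tuple
    rho: float
    table: pd.DataFrame  # one row per evaluated subset


# ---------------------------------------------------------------------------
# resemblance construction


def bray_curtis(rel: RelAbundanceTable) -> ResemblanceMatrix:
    """Bray-Curtis similarity S = 100 (1 - sum|x-y| / sum(x+y)).

    Expects the square-root-transformed relative abundances used throughout
    the community comparisons.
    """
    if rel.transform_tag != SQRT_RELATIVE:
        raise ValueError("bray_curtis expects a sqrt-transformed table")
    x = rel.values.to_numpy(dtype=float)
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        bad = [rel.sample_ids[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    sim = 100.0 * (1.0 - squareform(pdist(x, metric="braycurtis")))
    return ResemblanceMatrix(rel.sample_ids, sim, BRAY_CURTIS)


def euclidean(env: EnvTable) -> ResemblanceMatrix:
    """Euclidean distance on (normalized) environmental variables.

    Missing values are handled per pair with pairwise-complete variables and
    the classic rescaling d = sqrt(sum_used diff^2 * k_total / k_used).
    """
    x = env.values.to_numpy(dtype=float)
    n, k_total = x.shape
    d = np.zeros((n, n))
    mask = np.isfinite(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = mask[i] & mask[j]
            k_used = int(both.sum())
            if k_used == 0:
                raise ValueError(
                    f"samples {env.sample_ids[i]!r} and {env.sample_ids[j]!r} "
                    "share no observed variables"
                )
            diff = x[i, both] - x[j, both]
            d[i, j] = d[j, i] = np.sqrt(np.sum(diff**2) * k_total / k_used)
    return ResemblanceMatrix(env.sample_ids, d, EUCLIDEAN)


# ---------------------------------------------------------------------------
# non-metric MDS


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling used as one of the nMDS starts."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _kruskal_stress_fit(d: np.ndarray, x0: np.ndarray, max_iter: int = 300,
                        tol: float = 1e-9):
    """Minimize Kruskal stress-1 by alternating isotonic regression and
    Guttman transforms (nonmetric SMACOF)."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = x0.copy()
    last = np.inf
    stress = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(x))
        dist_vec = dist[iu]
        dhat = np.empty_like(dist_vec)
        dhat[order] = iso.fit_transform(np.arange(len(order)), dist_vec[order])
        denom = np.sum(dist_vec**2)
        if denom == 0:
            break
        stress = np.sqrt(np.sum((dist_vec - dhat) ** 2) / denom)
        if last - stress < tol:
            break
        last = stress
        # Guttman transform toward the disparities
        dh = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dh / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
    return x, float(stress)


def nmds(res: ResemblanceMatrix, k: int = 2, n_restarts: int = 50, seed=None,
         max_iter: int = 300) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    One start from classical metric scaling plus ``n_restarts - 1`` random
    starts; the lowest-stress configuration wins.
    """
    d = res.to_distance()
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for a {k}-d ordination")
    rng = np.random.default_rng(seed)
    best_x, best_stress = None, np.inf
    for restart in range(max(1, n_restarts)):
        x0 = _pcoa_coords(d, k) if restart == 0 else rng.normal(size=(n, k))
        x, stress = _kruskal_stress_fit(d, x0, max_iter=max_iter)
        if stress < best_stress:
            best_x, best_stress = x, stress
    coords = pd.DataFrame(
        best_x, index=pd.Index(res.ids, name="sample"),
        columns=[f"nmds{i + 1}" for i in range(k)],
    )
    return OrdinationResult(coords, best_stress, max(1, n_restarts),
                            converged=np.isfinite(best_stress))


# ---------------------------------------------------------------------------
# permutation tests


def _group_indices(groups) -> list:
    groups = np.asarray(groups)
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def _permanova_f(d2: np.ndarray, idx_groups: list, n: int) -> float:
    ss_total = d2.sum() / (2 * n)  # sum over i<j of d^2 / n
    ss_within = 0.0
    for idx in idx_groups:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub.sum() / (2 * len(idx))
    g = len(idx_groups)
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(res: ResemblanceMatrix, groups, n_perm: int = 9999, seed=None,
              method: str = "sampled") -> PermTestResult:
    """One-way PERMANOVA pseudo-F with permutation p-value.

    ``method="exact"`` enumerates all n! label permutations (small n only)
    and returns p = count(F_perm >= F_obs) / n!; the default samples
    ``n_perm`` permutations and uses (count + 1)/(n_perm + 1).
    """
    groups = np.asarray(groups)
    n = res.n
    if len(groups) != n:
        raise ValueError("groups length must match number of samples")
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(groups).value_counts()
    if (counts == 0).any():
        raise ValueError("empty group")
    d2 = res.to_distance() ** 2
    idx_groups = _group_indices(groups)
    f_obs = _permanova_f(d2, idx_groups, n)

    if method == "exact":
        total = 0
        hits = 0
        for perm in itertools.permutations(range(n)):
            perm = np.asarray(perm)
            permuted = groups[perm]
            f = _permanova_f(d2, _group_indices(permuted), n)
            hits += f >= f_obs - 1e-12
            total += 1
        return PermTestResult("pseudo-F", float(f_obs), total, hits / total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        permuted = groups[rng.permutation(n)]
        f = _permanova_f(d2, _group_indices(permuted), n)
        hits += f >= f_obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return PermTestResult("pseudo-F", float(f_obs), n_perm, p)


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, m: int) -> float:
    r_within = ranks[within_mask].mean()
    r_between = ranks[~within_mask].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(res: ResemblanceMatrix, groups, n_perm: int = 9999,
           seed=None) -> PermTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank)/(M/2)."""
    groups = np.asarray(groups)
    n = res.n
    if len(groups) != n:
        raise ValueError("groups length must match number of samples")
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    d = res.to_distance()
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = len(ranks)
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same, m)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        g = groups[rng.permutation(n)]
        hits += _anosim_r(ranks, g[iu[0]] == g[iu[1]], m) >= r_obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return PermTestResult("R", float(r_obs), n_perm, p)


def simper(rel: RelAbundanceTable, groups) -> pd.DataFrame:
    """SIMPER decomposition of average between-group Bray-Curtis dissimilarity.

    For each between-group sample pair the per-OTU contribution is
    100 |x - y| / sum(x + y); contributions are averaged over pairs and
    expressed as percents of the average dissimilarity.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("simper requires exactly 2 groups (pairwise mode)")
    x = rel.values.to_numpy(dtype=float)
    ia = np.flatnonzero(groups == levels[0])
    ib = np.flatnonzero(groups == levels[1])
    contrib = np.zeros(x.shape[1])
    n_pairs = 0
    for i in ia:
        for j in ib:
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                raise ValueError("pair of all-zero samples")
            contrib += 100.0 * np.abs(x[i] - x[j]) / denom
            n_pairs += 1
    avg = contrib / n_pairs
    total = avg.sum()
    pct = 100.0 * avg / total if total > 0 else np.zeros_like(avg)
    out = pd.DataFrame(
        {"average_contribution": avg, "percent": pct},
        index=pd.Index(rel.otu_ids, name="otu"),
    ).sort_values("average_contribution", ascending=False)
    out["cumulative_percent"] = out["percent"].cumsum()
    return out


# ---------------------------------------------------------------------------
# distance-based linear models


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _distlm_ss(g: np.ndarray, x: np.ndarray) -> float:
    """tr(H G H) for a single centered predictor: x'Gx / x'x."""
    return float(x @ g @ x / (x @ x))


def pseudo_f_from_prop(prop: float, df_resid: int) -> float:
    """Pseudo-F implied by an explained proportion and residual df.

    For a single predictor, F = prop * df_resid / (1 - prop); the identity
    used to check printed DistLM tables for internal consistency.
    """
    if not 0 <= prop < 1:
        raise ValueError("prop must lie in [0, 1)")
    return prop * df_resid / (1.0 - prop)


def distlm_marginal(res: ResemblanceMatrix, env: EnvTable, n_perm: int = 9999,
                    seed=None) -> pd.DataFrame:
    """Marginal DistLM test of each environmental variable on its own.

    For each variable the samples missing that variable are dropped, the
    (dis)similarity matrix is Gower-centered to G and the explained sum of
    squares is tr(HGH) for the centered predictor's hat matrix H;
    pseudo-F = SS / ((SS_total - SS) / (n - 2)).  P-values permute the raw
    predictor values.  Columns mirror the PRIMER output: ss_trace, pseudo_f,
    p_perm, prop, plus ss_total and n_eff.
    """
    if list(res.ids) != list(env.sample_ids):
        raise ValueError("resemblance matrix and EnvTable must share sample order")
    d_full = res.to_distance()
    rng = np.random.default_rng(seed)
    rows = []
    for var in env.variables:
        xvar = env.values[var].to_numpy(dtype=float)
        keep = np.isfinite(xvar)
        n = int(keep.sum())
        if n < 3:
            raise ValueError(f"variable {var!r} has fewer than 3 observed samples")
        x = xvar[keep]
        if np.ptp(x) == 0:
            raise ValueError(f"variable {var!r} is constant")
        x = x - x.mean()
        g = _gower_center(d_full[np.ix_(keep, keep)])
        ss_total = float(np.trace(g))
        ss = _distlm_ss(g, x)
        resid = ss_total - ss
        # a perfectly fitting predictor leaves no residual: report F = inf
        pseudo_f = np.inf if resid <= 1e-12 * max(abs(ss_total), 1.0) \
            else ss / (resid / (n - 2))
        # vectorized permutations: columns of xp are permuted predictors
        xp = np.empty((n, n_perm))
        for c in range(n_perm):
            xp[:, c] = x[rng.permutation(n)]
        ss_perm = np.einsum("ij,ij->j", xp, g @ xp) / np.einsum("ij,ij->j", xp, xp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = ss_perm / ((ss_total - ss_perm) / (n - 2))
        p = (np.sum(f_perm >= pseudo_f - 1e-12) + 1) / (n_perm + 1)
        rows.append(
            {"variable": var, "ss_trace": ss, "pseudo_f": pseudo_f, "p_perm": p,
             "prop": ss / ss_total, "ss_total": ss_total, "n_eff": n}
        )
    return pd.DataFrame(rows).set_index("variable")


def _hat_ss(g: np.ndarray, x: np.ndarray) -> float:
    """tr(H G) for centered predictor matrix x (n x p) via least squares."""
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    return float(np.trace(h @ g))


def distlm_forward(res: ResemblanceMatrix, env: EnvTable,
                   entry_alpha: float = 0.05, n_perm: int = 9999,
                   seed=None) -> SelectionResult:
    """Forward step-wise DistLM with a permutation entry test.

    At each step the candidate adding the largest conditional SS is tested by
    permuting its values; it enters if p <= entry_alpha.  Samples with any
    missing environmental value are dropped once (complete-case).
    """
    if list(res.ids) != list(env.sample_ids):
        raise ValueError("resemblance matrix and EnvTable must share sample order")
    x_all = env.values.to_numpy(dtype=float)
    keep = np.all(np.isfinite(x_all), axis=1)
    x_all = x_all[keep]
    x_all = x_all - x_all.mean(axis=0)
    n = x_all.shape[0]
    g = _gower_center(res.to_distance()[np.ix_(keep, keep)])
    ss_total = float(np.trace(g))
    rng = np.random.default_rng(seed)

    variables = list(env.variables)
    selected: list = []
    sel_cols: list = []
    steps = []
    ss_sel = 0.0
    while True:
        best = None
        for vi, var in enumerate(variables):
            if var in selected:
                continue
            cols = sel_cols + [vi]
            ss_new = _hat_ss(g, x_all[:, cols])
            ss_cond = ss_new - ss_sel
            if best is None or ss_cond > best[2]:
                best = (var, vi, ss_cond, ss_new)
        if best is None:
            break
        var, vi, ss_cond, ss_new = best
        p_new = len(sel_cols) + 1
        if n - p_new - 1 <= 0:
            break
        resid = ss_total - ss_new
        f_cond = np.inf if resid <= 1e-12 * max(abs(ss_total), 1.0) \
            else ss_cond / (resid / (n - p_new - 1))
        # permutation entry test: permute the candidate's values
        hits = 0
        for _ in range(n_perm):
            cols = x_all[:, sel_cols]
            cand = x_all[rng.permutation(n), vi][:, None]
            ss_perm = _hat_ss(g, np.hstack([cols, cand]) if len(sel_cols) else cand)
            ss_cond_perm = ss_perm - ss_sel
            resid_perm = ss_total - ss_perm
            f_perm = np.inf if resid_perm <= 1e-12 * max(abs(ss_total), 1.0) \
                else ss_cond_perm / (resid_perm / (n - p_new - 1))
            hits += f_perm >= f_cond - 1e-12
        p = (hits + 1) / (n_perm + 1)
        if p > entry_alpha:
            break
        selected.append(var)
        sel_cols.append(vi)
        ss_sel = ss_new
        steps.append(
            {"variable": var, "ss_cond": ss_cond, "pseudo_f": f_cond,
             "p_perm": p, "cumulative_prop": ss_sel / ss_total}
        )
    cols = ["variable", "ss_cond", "pseudo_f", "p_perm", "cumulative_prop"]
    return SelectionResult(pd.DataFrame(steps, columns=cols), selected)


# ---------------------------------------------------------------------------
# RELATE / BEST


def _offdiag_vector(res: ResemblanceMatrix) -> np.ndarray:
    iu = np.triu_indices(res.n, k=1)
    return res.values[iu]


def relate(r1: ResemblanceMatrix, r2: ResemblanceMatrix, n_perm: int = 9999,
           seed=None) -> PermTestResult:
    """RELATE: Spearman rank correlation between two resemblance matrices.

    p-value from simultaneous row/column permutations of the second matrix.
    """
    if list(r1.ids) != list(r2.ids):
        raise ValueError("resemblance matrices must share ids and order")
    n = r1.n
    iu = np.triu_indices(n, k=1)
    v1 = r1.values[iu]
    rho_obs = spearmanr(v1, r2.values[iu]).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = r2.values[np.ix_(perm, perm)][iu]
        hits += spearmanr(v1, v2p).statistic >= rho_obs - 1e-12
    p = (hits + 1) / (n_perm + 1)
    return PermTestResult("rho", float(rho_obs), n_perm, p)


def bioenv_best(d_bio: ResemblanceMatrix, env: EnvTable,
                max_subset: int = 5) -> BestResult:
    """BEST/BIOENV: exhaustive search for the environmental-variable subset
    whose Euclidean distance matrix best rank-correlates with the biotic
    resemblance (RELATE rho)."""
    if max_subset < 1:
        raise ValueError("max_subset must be >= 1")
    if list(d_bio.ids) != list(env.sample_ids):
        raise ValueError("ids must match between biotic matrix and EnvTable")
    iu = np.triu_indices(d_bio.n, k=1)
    bio_vec = d_bio.to_distance()[iu]
    x = env.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("bioenv_best requires a complete environmental table")
    variables = list(env.variables)
    rows = []
    best = None
    for size in range(1, min(max_subset, len(variables)) + 1):
        for subset in itertools.combinations(range(len(variables)), size):
            d_env = squareform(pdist(x[:, subset]))[iu]
            rho = spearmanr(bio_vec, d_env).statistic
            names = tuple(variables[i] for i in subset)
            rows.append({"subset": names, "size": size, "rho": rho})
            if best is None or rho > best[1]:
                best = (names, rho)
    table = pd.DataFrame(rows).sort_values("rho", ascending=False,
                                           ignore_index=True)
    return BestResult(best[0], float(best[1]), table)
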