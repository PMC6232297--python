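"""Correlation-based co-occurrence / co-exclusion network analysis.

Pairwise Pearson correlations over the pooled set of abundant OTUs
(unaltered relative abundances) and normalized environmental variables,
Benjamini-Hochberg FDR control at 5%, signed network construction (positive
edges form the co-occurrence graph, negative edges the co-exclusion graph),
Louvain modularity modules, unnormalized shortest-path betweenness and a
circular-initialized Fruchterman-Reingold layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import RAW_RELATIVE, EnvTable, RelAbundanceTable

__all__ = [
    "pair_count",
    "pairwise_correlations",
    "bh_adjust",
    "build_networks",
    "ModulePartition",
    "detect_modules",
    "modularity_q",
    "betweenness",
    "fr_layout",
    "module_summary",
    "network_report",
]

OTU_KIND = "OTU"
ENV_KIND = "ENV"


def pair_count(n_vars: int) -> int:
    """Number of unordered variable pairs tested: n(n-1)/2."""
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    return n_vars * (n_vars - 1) // 2


def _pearson_p(r: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """Two-sided p from t = r sqrt(n-2)/sqrt(1-r^2) on n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    df = n_eff - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(t), p, 0.0)  # |r| == 1 -> p = 0


def pairwise_correlations(otus: RelAbundanceTable, env: EnvTable | None = None,
                          min_n: int = 5) -> pd.DataFrame:
    """All-pairs Pearson correlations over pooled OTU and env variables.

    OTU relative abundances enter unaltered; environmental variables are
    expected normalized.  Correlations use pairwise-complete samples with the
    effective n recorded; pairs with fewer than ``min_n`` complete samples or
    a zero-variance member get a missing r and are excluded from FDR.

    Returns one row per unordered pair with columns
    id_a, id_b, kind_a, kind_b, n_eff, r, p, q, significant.
    """
    if otus.transform_tag != RAW_RELATIVE:
        raise ValueError("network correlations use unaltered relative abundances")
    frames = [otus.values]
    kinds = {name: OTU_KIND for name in otus.otu_ids}
    if env is not None:
        env_vals = env.values.loc[otus.values.index]
        frames.append(env_vals)
        kinds.update({name: ENV_KIND for name in env.variables})
    data = pd.concat(frames, axis=1)
    names = list(data.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 variables to correlate")
    x = data.to_numpy(dtype=float)
    n_samples, m = x.shape

    complete = np.all(np.isfinite(x), axis=0)
    rows = []
    if complete.all():
        sd = x.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        for a in range(m):
            for b in range(a + 1, m):
                degenerate = sd[a] == 0 or sd[b] == 0 or n_samples < min_n
                r = np.nan if degenerate else float(np.clip(corr[a, b], -1, 1))
                rows.append((names[a], names[b], kinds[names[a]],
                             kinds[names[b]], n_samples, r))
    else:
        finite = np.isfinite(x)
        for a in range(m):
            for b in range(a + 1, m):
                both = finite[:, a] & finite[:, b]
                n_eff = int(both.sum())
                xa, xb = x[both, a], x[both, b]
                degenerate = (n_eff < min_n or n_eff < 2
                              or xa.std() == 0 or xb.std() == 0)
                r = np.nan if degenerate else float(
                    np.clip(np.corrcoef(xa, xb)[0, 1], -1, 1))
                rows.append((names[a], names[b], kinds[names[a]],
                             kinds[names[b]], n_eff, r))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "kind_a", "kind_b",
                                      "n_eff", "r"])
    out["p"] = np.nan
    ok = out["r"].notna()
    out.loc[ok, "p"] = _pearson_p(out.loc[ok, "r"].to_numpy(),
                                  out.loc[ok, "n_eff"].to_numpy(dtype=float))
    out["q"] = np.nan
    out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = ok & (out["q"] < 0.05)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_networks(corr: pd.DataFrame, alpha: float = 0.05,
                   use_raw_p: bool = False) -> tuple:
    """Split significant correlations into co-occurrence and co-exclusion graphs.

    Significance is BH-adjusted q < alpha (raw p < alpha with
    ``use_raw_p=True``).  Each graph contains only the nodes incident to at
    least one edge of its sign; edges carry r, p, q, sign and weight = |r|.
    """
    key = "p" if use_raw_p else "q"
    sig = corr[corr["r"].notna() & (corr[key] < alpha)]
    kinds = {}
    for _, row in corr.iterrows():
        kinds[row["id_a"]] = row["kind_a"]
        kinds[row["id_b"]] = row["kind_b"]
    graphs = []
    for sign_label, subset in (("+", sig[sig["r"] > 0]), ("-", sig[sig["r"] < 0])):
        g = nx.Graph(sign=sign_label)
        for _, row in subset.iterrows():
            g.add_edge(
                row["id_a"], row["id_b"], r=float(row["r"]), p=float(row["p"]),
                q=float(row["q"]), sign=sign_label, weight=abs(float(row["r"])),
            )
        for node in g.nodes:
            g.nodes[node]["kind"] = kinds.get(node, OTU_KIND)
        graphs.append(g)
    return tuple(graphs)


@dataclass
class ModulePartition:
    """Node -> 1-based module id (modules ordered by decreasing size)."""

    assignments: dict
    modularity_q: float

    def sizes(self) -> pd.Series:
        s = pd.Series(self.assignments).value_counts().sort_index()
        s.name = "size"
        return s


def modularity_q(g: nx.Graph, communities) -> float:
    """Weighted Newman modularity Q = sum_c [W_c/W - (S_c / 2W)^2]."""
    w_total = g.size(weight="weight")
    if w_total == 0:
        return 0.0
    degrees = dict(g.degree(weight="weight"))
    q = 0.0
    for comm in communities:
        comm = set(comm)
        sub = g.subgraph(comm)
        w_c = sub.size(weight="weight")
        s_c = sum(degrees[n] for n in comm)
        q += w_c / w_total - (s_c / (2 * w_total)) ** 2
    return float(q)


def detect_modules(g: nx.Graph, resolution: float = 1.0,
                   seed: int = 0) -> ModulePartition:
    """Louvain greedy modularity maximization with edge weights |r|.

    Module ids are relabeled by decreasing size (ties broken by the smallest
    member name) so the labeling is deterministic under a fixed seed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(map(str, c))))
    assignments = {node: i + 1 for i, comm in enumerate(comms) for node in comm}
    return ModulePartition(assignments, modularity_q(g, comms))


def betweenness(g: nx.Graph) -> pd.DataFrame:
    """Unnormalized shortest-path betweenness (unweighted edges) and degree."""
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    return pd.DataFrame(
        {"betweenness": pd.Series(bc), "degree": pd.Series(dict(g.degree()))}
    ).rename_axis("node")


def fr_layout(g: nx.Graph, iterations: int = 1000, seed: int = 0,
              k: float | None = None) -> dict:
    """Fruchterman-Reingold layout from a deterministic circular start.

    Nodes begin on a unit circle in sorted-name order and are refined by the
    classic attractive (d^2/k along edges) and repulsive (k^2/d between all
    pairs) forces with a linearly cooling displacement cap.  Coordinates are
    reproducible under a fixed seed (the rng only breaks exact coincidences).
    """
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot lay out an empty graph")
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}
    if k is None:
        k = 1.0 / np.sqrt(n)
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n) / n
    pos = np.column_stack([np.cos(theta), np.sin(theta)])
    index = {node: i for i, node in enumerate(nodes)}
    edges = np.array([[index[a], index[b]] for a, b in g.edges], dtype=int)
    t0 = 0.1 * 2.0  # initial temperature ~ 10% of layout width
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        coincident = dist == 0
        if coincident.any():
            jitter = rng.normal(scale=1e-6, size=delta.shape)
            delta = delta + jitter
            dist = np.linalg.norm(delta, axis=-1)
            np.fill_diagonal(dist, np.inf)
        # repulsion between every pair
        disp = (delta / dist[..., None]) * (k**2 / dist)[..., None]
        disp = disp.sum(axis=1)
        # attraction along edges
        if len(edges):
            a, b = edges[:, 0], edges[:, 1]
            dvec = pos[a] - pos[b]
            d = np.linalg.norm(dvec, axis=1)
            d = np.where(d == 0, 1e-12, d)
            force = (dvec / d[:, None]) * (d**2 / k)[:, None]
            np.add.at(disp, a, -force)
            np.add.at(disp, b, force)
        length = np.linalg.norm(disp, axis=1)
        length = np.where(length == 0, 1e-12, length)
        temp = t0 * (1.0 - it / iterations)
        pos = pos + (disp / length[:, None]) * np.minimum(length, temp)[:, None]
    return {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}


def _round_half_up(value: float, places: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -places,
                                               rounding=ROUND_HALF_UP))


def module_summary(partition: ModulePartition,
                   kinds: dict | None = None) -> pd.DataFrame:
    """Per-module size, percent of all nodes (half-up, 2 decimals) and members.

    ``kinds`` maps node -> "OTU"/"ENV" to split the member lists; nodes
    without an entry count as OTUs.
    """
    total = len(partition.assignments)
    members: dict = {}
    for node, module in partition.assignments.items():
        members.setdefault(module, []).append(node)
    rows = []
    for module in sorted(members, key=lambda mid: (-len(members[mid]), mid)):
        nodes = sorted(members[module], key=str)
        kind_of = kinds or {}
        otu_members = [x for x in nodes if kind_of.get(x, OTU_KIND) == OTU_KIND]
        env_members = [x for x in nodes if kind_of.get(x, OTU_KIND) == ENV_KIND]
        rows.append(
            {"module": module, "size": len(nodes),
             "pct": _round_half_up(100.0 * len(nodes) / total),
             "otu_members": ",".join(otu_members),
             "env_members": ",".join(env_members)}
        )
    return pd.DataFrame(rows).set_index("module")


def network_report(corr: pd.DataFrame, pos: nx.Graph, neg: nx.Graph) -> dict:
    """Bookkeeping mirrored from the published network descriptions.

    Counts of tested pairs, significant correlations (q-based and raw-p
    based), and the edge/node composition of the two signed graphs; the edge
    conservation identity n_significant == n_pos_edges + n_neg_edges holds by
    construction.
    """
    tested = int(corr["r"].notna().sum())
    n_pos = pos.number_of_edges()
    n_neg = neg.number_of_edges()
    return {
        "n_pairs": int(len(corr)),
        "n_tested": tested,
        "n_significant": n_pos + n_neg,
        "n_significant_raw_p": int((corr["r"].notna() & (corr["p"] < 0.05)).sum()),
        "n_positive_edges": n_pos,
        "n_positive_nodes": pos.number_of_nodes(),
        "n_negative_edges": n_neg,
        "n_negative_nodes": neg.number_of_nodes(),
    }
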