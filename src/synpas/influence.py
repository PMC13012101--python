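"""Network-influence scoring and target-prioritization quadrants.

Two complementary propagation measures are computed on the undirected
simple projection of the network:

* heat diffusion — unit heat is placed on a node and diffused under the
  combinatorial-Laplacian kernel H = exp(-t L); the influence of node i is
  the heat it has lost, 1 - H_ii. High values mark efficient local
  propagators.
* personalized PageRank (PPR) — random-walk-with-restart mass
  r = (1 - alpha) s + alpha W^T r seeded at the focal gene, measuring how
  well connected each node is to the seed.

Crossing the two axes at their medians yields the prioritization quadrants:
high/high master regulators, high-heat/low-PPR signal modulators,
low-heat/high-PPR hubs, low/low peripheral nodes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.linalg import expm

from .io import ProteostasisNetwork

CATEGORIES = ("master_regulator", "signal_modulator", "hub", "peripheral")


def influence_graph(network: ProteostasisNetwork) -> nx.Graph:
    """Undirected simple projection of the network edges, focal included."""
    g = nx.Graph()
    g.add_nodes_from([n.gene for n in network.nodes])
    g.add_node(network.focal)
    for e in network.edges:
        g.add_edge(e.source, e.target)
    return g


def _as_graph(network_or_graph) -> nx.Graph:
    if isinstance(network_or_graph, ProteostasisNetwork):
        return influence_graph(network_or_graph)
    return network_or_graph


def heat_diffusion_scores(network_or_graph, t: float = 0.1) -> pd.Series:
    """Per-node heat influence 1 - H_ii under H = exp(-t L), L = D - A.

    An isolated node retains all its heat (influence 0). Row sums of H are
    1 (heat conservation), so influence lies in [0, 1].
    """
    if t <= 0:
        raise ValueError("diffusion time t must be positive")
    g = _as_graph(network_or_graph)
    nodes = sorted(g.nodes)
    if len(nodes) < 2:
        raise ValueError("heat diffusion needs at least 2 nodes")
    lap = nx.laplacian_matrix(g, nodelist=nodes).toarray().astype(float)
    h = expm(-t * lap)
    return pd.Series(1.0 - np.diag(h), index=nodes)


def ppr_scores(
    network_or_graph,
    damping: float = 0.85,
    seed_node: str | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> pd.Series:
    """Personalized PageRank on the undirected graph.

    Solves r = (1 - alpha) s + alpha W^T r by power iteration (L1 change
    below tol), with s the indicator of the seed node (the focal gene by
    default). Dangling (isolated) nodes teleport their mass to the seed.
    Scores sum to 1.
    """
    if not (0.0 < damping < 1.0):
        raise ValueError("damping must lie in (0, 1)")
    g = _as_graph(network_or_graph)
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    if seed_node is None:
        if isinstance(network_or_graph, ProteostasisNetwork):
            seed_node = network_or_graph.focal
        else:
            raise ValueError("seed_node required for a bare graph")
    if seed_node not in idx:
        raise ValueError(f"seed node {seed_node!r} not in graph")
    adj = nx.to_numpy_array(g, nodelist=nodes)
    deg = adj.sum(axis=1)
    dangling = deg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(deg[:, None] > 0, adj / np.where(deg[:, None] == 0, 1, deg[:, None]), 0.0)
    s = np.zeros(n)
    s[idx[seed_node]] = 1.0
    r = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling_mass = r[dangling].sum()
        r_new = (1.0 - damping) * s + damping * (w.T @ r + dangling_mass * s)
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    return pd.Series(r, index=nodes)


def classify_quadrants(heat: pd.Series, ppr: pd.Series, split: str | float = "median") -> pd.Series:
    """Assign each gene a prioritization category from its two influence axes.

    split: "median" or a quantile in (0, 1). "High" means >= the per-axis
    threshold, so a gene sitting exactly on both thresholds is a master
    regulator.
    """
    if set(heat.index) != set(ppr.index):
        raise ValueError("heat and ppr must cover the same genes")
    ppr = ppr.loc[heat.index]
    q = 0.5 if split == "median" else float(split)
    if not (0.0 < q < 1.0):
        raise ValueError("quantile split must lie in (0, 1)")
    heat_cut = heat.quantile(q)
    ppr_cut = ppr.quantile(q)
    high_heat = heat >= heat_cut
    high_ppr = ppr >= ppr_cut
    cats = np.where(
        high_heat & high_ppr,
        "master_regulator",
        np.where(high_heat, "signal_modulator", np.where(high_ppr, "hub", "peripheral")),
    )
    return pd.Series(cats, index=heat.index)


def influence_table(
    network: ProteostasisNetwork,
    t: float = 0.1,
    damping: float = 0.85,
    seed_node: str | None = None,
    split: str | float = "median",
) -> pd.DataFrame:
    """Convenience wrapper: heat, PPR and quadrant per network gene."""
    heat = heat_diffusion_scores(network, t=t)
    ppr = ppr_scores(network, damping=damping, seed_node=seed_node)
    cats = classify_quadrants(heat, ppr, split=split)
    df = pd.DataFrame({"gene": heat.index, "heat": heat.values,
                       "ppr": ppr.loc[heat.index].values, "category": cats.values})
    return df.sort_values("gene").reset_index(drop=True)
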