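"""Network enrichment analysis of driver target sets against pathway sets.

The statistic is the number of network edges with one endpoint in the target
set and one in the pathway set (an edge inside the intersection counts
once).  The default null preserves every node's degree: the observed edge
list is rewired by double-edge swaps, advancing the chain by
``burnin_factor * n_edges`` attempted swaps between successive permutation
samples.  A closed-form binomial approximation under the configuration model
is available for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GeneNetwork",
    "EnrichmentResult",
    "count_links",
    "nea_test",
    "select_targets_for_nea",
]


@dataclass
class GeneNetwork:
    """An undirected gene network: no self-loops, no duplicate edges."""

    nodes: list
    edges: np.ndarray  # (m, 2) int indices into nodes
    index: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_edges(cls, pairs: Iterable) -> "GeneNetwork":
        seen = set()
        nodes: list = []
        index: dict = {}
        edge_set = set()
        for a, b in pairs:
            if a == b:
                continue
            for g in (a, b):
                if g not in index:
                    index[g] = len(nodes)
                    nodes.append(g)
            i, j = index[a], index[b]
            edge_set.add((min(i, j), max(i, j)))
        edges = np.array(sorted(edge_set), dtype=np.int64).reshape(-1, 2)
        return cls(nodes=nodes, edges=edges, index=index)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def member_mask(self, genes) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            i = self.index.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((self.nodes[i], self.nodes[j])
                         for i, j in self.edges)
        return g


def _count_cross(edges: np.ndarray, in_a: np.ndarray,
                 in_b: np.ndarray) -> int:
    e0, e1 = edges[:, 0], edges[:, 1]
    return int(np.sum((in_a[e0] & in_b[e1]) | (in_b[e0] & in_a[e1])))


def count_links(set_a, set_b, network: GeneNetwork) -> int:
    """Edges with one endpoint in ``set_a`` and the other in ``set_b``.

    Each edge counts once, including edges inside the intersection of the
    two sets.  Raises when both sets are empty on the network.
    """
    in_a = network.member_mask(set_a)
    in_b = network.member_mask(set_b)
    if not in_a.any() and not in_b.any():
        raise ConfigurationError("both sets are empty on the network")
    return _count_cross(network.edges, in_a, in_b)


def _swap_chain_py(edges, adj, n_attempts, seed):
    np.random.seed(seed)
    m = edges.shape[0]
    for _ in range(n_attempts):
        a = np.random.randint(0, m)
        b = np.random.randint(0, m)
        if a == b:
            continue
        u, v = edges[a, 0], edges[a, 1]
        x, y = edges[b, 0], edges[b, 1]
        if np.random.randint(0, 2) == 1:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, y] or adj[x, v]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, y] = adj[y, u] = True
        adj[x, v] = adj[v, x] = True
        edges[a, 0], edges[a, 1] = u, y
        edges[b, 0], edges[b, 1] = x, v


if _HAVE_NUMBA:

    @njit(cache=True)
    def _swap_chain_nb(edges, adj, n_attempts, seed):  # pragma: no cover
        np.random.seed(seed)
        m = edges.shape[0]
        for _ in range(n_attempts):
            a = np.random.randint(0, m)
            b = np.random.randint(0, m)
            if a == b:
                continue
            u = edges[a, 0]
            v = edges[a, 1]
            x = edges[b, 0]
            y = edges[b, 1]
            if np.random.randint(0, 2) == 1:
                t = x
                x = y
                y = t
            if u == x or u == y or v == x or v == y:
                continue
            if adj[u, y] or adj[x, v]:
                continue
            adj[u, v] = False
            adj[v, u] = False
            adj[x, y] = False
            adj[y, x] = False
            adj[u, y] = True
            adj[y, u] = True
            adj[x, v] = True
            adj[v, x] = True
            edges[a, 0] = u
            edges[a, 1] = y
            edges[b, 0] = x
            edges[b, 1] = v

    _swap_chain = _swap_chain_nb
else:  # pragma: no cover
    _swap_chain = _swap_chain_py


@dataclass
class EnrichmentResult:
    """Enrichment of one pathway against a target set on the network."""

    pathway: str
    observed_links: int
    expected_links: float
    z: float
    p: float
    fdr: float = float("nan")
    testable: bool = True


def nea_test(target_set, pathway_sets: Mapping[str, Iterable],
             network: GeneNetwork, n_perm: int = 1000, seed: int = 0,
             method: str = "permutation",
             burnin_factor: int = 10) -> list[EnrichmentResult]:
    """Over-representation of network links between targets and pathways.

    ``method="permutation"`` (default) rewires the network by degree
    preserving double-edge swaps, advancing ``burnin_factor * n_edges``
    attempted swaps between samples; z is the standardized observed count
    and p the one-sided upper permutation p-value with the add-one rule.
    ``method="binomial"`` uses a configuration-model closed form instead.
    BH adjustment runs across testable pathways; a pathway with no gene on
    the network is flagged untestable.
    """
    in_t = network.member_mask(target_set)
    if not in_t.any():
        raise ConfigurationError("target set is empty on the network")
    names = list(pathway_sets)
    masks = {nm: network.member_mask(pathway_sets[nm]) for nm in names}
    results: dict[str, EnrichmentResult] = {}
    testable = [nm for nm in names if masks[nm].any()]
    for nm in names:
        if nm not in testable:
            results[nm] = EnrichmentResult(
                pathway=nm, observed_links=0, expected_links=float("nan"),
                z=float("nan"), p=float("nan"), testable=False)
    obs = {nm: _count_cross(network.edges, in_t, masks[nm])
           for nm in testable}

    if method == "permutation":
        m = network.n_edges
        edges = network.edges.copy()
        adj = np.zeros((network.n_nodes, network.n_nodes), dtype=np.bool_)
        adj[edges[:, 0], edges[:, 1]] = True
        adj[edges[:, 1], edges[:, 0]] = True
        rng = np.random.default_rng(seed)
        null = {nm: np.empty(n_perm) for nm in testable}
        for r in range(n_perm):
            chain_seed = int(rng.integers(2**31 - 1))
            _swap_chain(edges, adj, burnin_factor * m, chain_seed)
            for nm in testable:
                null[nm][r] = _count_cross(edges, in_t, masks[nm])
        for nm in testable:
            mu = float(null[nm].mean())
            sd = float(null[nm].std())
            if sd == 0:
                z = 0.0 if obs[nm] == mu else float(np.sign(obs[nm] - mu)
                                                    * np.inf)
            else:
                z = (obs[nm] - mu) / sd
            p = (1 + int(np.sum(null[nm] >= obs[nm]))) / (n_perm + 1)
            results[nm] = EnrichmentResult(
                pathway=nm, observed_links=obs[nm], expected_links=mu,
                z=float(z), p=float(p))
    elif method == "binomial":
        deg = network.degrees()
        two_m = float(2 * network.n_edges)
        qa = deg[in_t].sum() / two_m
        for nm in testable:
            qb = deg[masks[nm]].sum() / two_m
            qab = deg[in_t & masks[nm]].sum() / two_m
            q = min(max(2 * qa * qb - qab**2, 0.0), 1.0)
            mu = network.n_edges * q
            p = float(stats.binom.sf(obs[nm] - 1, network.n_edges, q))
            sd = float(np.sqrt(network.n_edges * q * (1 - q)))
            z = (obs[nm] - mu) / sd if sd > 0 else 0.0
            results[nm] = EnrichmentResult(
                pathway=nm, observed_links=obs[nm], expected_links=mu,
                z=float(z), p=p)
    else:
        raise ConfigurationError(f"unknown method {method!r}")

    if testable:
        ps = [results[nm].p for nm in testable]
        fdrs = multipletests(ps, method="fdr_bh")[1]
        for nm, q in zip(testable, fdrs):
            results[nm].fdr = float(q)
    return [results[nm] for nm in names]


def select_targets_for_nea(module, desired_size: int = 100,
                           grid: Sequence[float] | None = None,
                           mirna_mode: bool = False):
    """Correlation cutoff giving a target set of about ``desired_size``.

    Walks the cutoff grid upward and returns the set at the smallest cutoff
    whose target count is at most ``desired_size`` (with the cutoff used);
    if no cutoff qualifies the highest one is used.  In miRNA mode the
    target set bypasses correlation filtering and returns unchanged.
    """
    if module.n_targets == 0:
        raise ConfigurationError("empty module")
    if mirna_mode:
        return set(module.targets), None
    if grid is None:
        grid = np.round(np.arange(0.30, 0.91, 0.05), 2)
    grid = sorted(grid)
    absr = {t: abs(module.target_corr.get(t, 0.0)) for t in module.targets}
    chosen = None
    for thr in grid:
        sel = {t for t, r in absr.items() if r >= thr}
        if len(sel) <= desired_size:
            chosen = (sel, float(thr))
            break
    if chosen is None:
        thr = grid[-1]
        chosen = ({t for t, r in absr.items() if r >= thr}, float(thr))
    return chosen
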