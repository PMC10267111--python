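"""Shared fixtures: toy networks, latent samplers, exhaustive path oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from symptomnet.ggm import WeightedNetwork
from symptomnet.synthetic_data import GroundTruthNetwork, make_ground_truth


def sample_latent(truth: GroundTruthNetwork, n: int, seed: int) -> pd.DataFrame:
    """Draw the latent Gaussian itself (no discretisation) as a DataFrame."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(truth.latent_correlation)
    z = rng.standard_normal((n, truth.p)) @ chol.T
    return pd.DataFrame(z, columns=list(truth.nodes))


def net_from_edges(nodes, edges, communities=None) -> WeightedNetwork:
    """Build a WeightedNetwork from an explicit (a, b, w) edge list."""
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, val in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = val
    return WeightedNetwork(weights=w, nodes=list(nodes), communities=communities or {})


def random_network(p: int, seed: int, density: float = 0.5) -> WeightedNetwork:
    """Random signed network used by the exhaustive-oracle comparisons."""
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.05, 0.9) * rng.choice([-1, 1])
    return WeightedNetwork(weights=w, nodes=[f"N{i}" for i in range(p)])


# ---------------------------------------------------------------------------
# Exhaustive shortest-path oracles (independent of the networkx-based code):
# enumerate every simple path, find the minimum total 1/|w| length, split
# credit equally across tied minima.

def _all_simple_paths(adj: dict[str, dict[str, float]], s: str, t: str):
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def _shortest_paths(net: WeightedNetwork, s: str, t: str):
    adj: dict[str, dict[str, float]] = {v: {} for v in net.nodes}
    for a, b, w in net.edge_list():
        adj[a][b] = adj[b][a] = 1.0 / abs(w)
    best, paths = np.inf, []
    for path in _all_simple_paths(adj, s, t):
        length = sum(adj[a][b] for a, b in zip(path, path[1:]))
        if length < best - 1e-12:
            best, paths = length, [path]
        elif abs(length - best) <= 1e-12:
            paths.append(path)
    return paths


def brute_force_betweenness(net: WeightedNetwork) -> dict[str, float]:
    counts = {v: 0.0 for v in net.nodes}
    for s, t in itertools.combinations(net.nodes, 2):
        paths = _shortest_paths(net, s, t)
        if not paths:
            continue
        credit = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                counts[v] += credit
    return counts


def brute_force_predictive(net: WeightedNetwork, focal: str) -> dict[str, float]:
    counts = {v: 0.0 for v in net.nodes if v != focal}
    for t in net.nodes:
        if t == focal:
            continue
        paths = _shortest_paths(net, focal, t)
        if not paths:
            continue
        credit = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                counts[v] += credit
    return counts


MINI_STUDY = dict(
    n_participants=250,
    B_boot=8,
    B_casedrop=4,
    casedrop_proportions=(0.2, 0.5, 0.75),
    n_perm=10,
    n_lambdas=15,
    min_ratio=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def mini_report():
    """One full (scaled-down) study run shared by pipeline/acceptance tests."""
    from symptomnet.pipeline import StudyConfig, run_study

    config = StudyConfig(**MINI_STUDY)
    return config, run_study(config)


@pytest.fixture(scope="session")
def chain_truth() -> GroundTruthNetwork:
    """10-node chain with all partial correlations 0.3."""
    comm = {f"V{i}": "c" for i in range(10)}
    edges = [(f"V{i}", f"V{i + 1}", 0.3) for i in range(9)]
    return make_ground_truth(10, comm, sparsity=0.0, seed=0, fixed_edges=edges)


@pytest.fixture(scope="session")
def small_truth() -> GroundTruthNetwork:
    """5-node truth with three designated edges, two communities."""
    comm = {"A": "g1", "B": "g1", "C": "g1", "D": "g2", "E": "g2"}
    edges = [("A", "B", 0.4), ("B", "C", 0.3), ("D", "E", 0.35)]
    return make_ground_truth(
        5, comm, sparsity=0.0, seed=0, fixed_edges=edges,
        bridge_spec=[("C", "D", 0.25)],
    )
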