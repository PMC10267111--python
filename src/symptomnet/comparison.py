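"""Permutation test of network invariance between two subgroups.

Two global statistics are compared against their permutation nulls, obtained
by shuffling group labels over the pooled rows (group sizes preserved) and
re-estimating both networks per permutation:

* M — network structure invariance: the maximum absolute edge-weight
  difference over all edges;
* S — global strength invariance: the absolute difference of the two
  networks' global strengths (sum of |w| over unique edges).

p-values use the add-one estimator ``(1 + #{null >= observed}) / (1 + P)``.
Per-edge differences are tested the same way, restricted to edges present in
at least one observed network, with Holm multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ggm import WeightedNetwork
from .synthetic_data import CohortTable

__all__ = ["NCTResult", "global_strength", "nct"]


def global_strength(net: WeightedNetwork) -> float:
    """Total absolute connectivity: sum of |w_ij| over unordered pairs."""
    return float(np.abs(np.triu(net.weights, k=1)).sum())


@dataclass
class NCTResult:
    """Observed invariance statistics, permutation p-values, per-edge tests."""

    observed_max_edge_diff: float  # M, structure invariance
    observed_strength_diff: float  # S, global strength invariance
    strengths: tuple[float, float]
    p_structure: float
    p_strength: float
    n_perm: int
    seed: int
    edge_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    adjust: str = "holm"

    def to_dict(self) -> dict:
        return {
            "M_max_edge_diff": self.observed_max_edge_diff,
            "S_strength_diff": self.observed_strength_diff,
            "strength_group1": self.strengths[0],
            "strength_group2": self.strengths[1],
            "p_structure": self.p_structure,
            "p_strength": self.p_strength,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_edges_tested": int(len(self.edge_tests)),
            "n_edges_significant": int(self.edge_tests["significant"].sum())
            if len(self.edge_tests) else 0,
        }


def _frame_of(table) -> pd.DataFrame:
    return table.values if isinstance(table, CohortTable) else table


def nct(
    table1: CohortTable | pd.DataFrame,
    table2: CohortTable | pd.DataFrame,
    estimator: Callable[[pd.DataFrame], WeightedNetwork],
    n_perm: int = 1000,
    seed: int = 0,
    adjust: str = "holm",
    alpha: float = 0.05,
) -> NCTResult:
    """Network comparison test between two groups sharing the same variables.

    ``estimator`` is the group-level network pipeline (see
    ``stability.network_estimator``). Deterministic given ``seed``.
    """
    f1, f2 = _frame_of(table1), _frame_of(table2)
    if list(f1.columns) != list(f2.columns):
        only1 = sorted(set(f1.columns) - set(f2.columns))
        only2 = sorted(set(f2.columns) - set(f1.columns))
        raise ValueError(
            f"variable mismatch between groups: only in group1 {only1}, "
            f"only in group2 {only2}, or ordering differs"
        )
    n1, n2 = len(f1), len(f2)
    net1, net2 = estimator(f1), estimator(f2)
    p = net1.p
    iu = np.triu_indices(p, k=1)

    diff = np.abs(net1.weights - net2.weights)[iu]
    observed_m = float(diff.max()) if diff.size else 0.0
    s1, s2 = global_strength(net1), global_strength(net2)
    observed_s = abs(s1 - s2)

    either = (net1.weights[iu] != 0.0) | (net2.weights[iu] != 0.0)
    tested = np.flatnonzero(either)

    pooled = pd.concat([f1, f2], ignore_index=True)
    n = n1 + n2
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_m = np.empty(n_perm)
    null_s = np.empty(n_perm)
    null_edge_ge = np.zeros(len(tested))
    for b in range(n_perm):
        order = rng.permutation(n)
        g1 = pooled.iloc[order[:n1]].reset_index(drop=True)
        g2 = pooled.iloc[order[n1:]].reset_index(drop=True)
        w1, w2 = estimator(g1).weights, estimator(g2).weights
        d = np.abs(w1 - w2)[iu]
        null_m[b] = d.max() if d.size else 0.0
        null_s[b] = abs(
            np.abs(np.triu(w1, k=1)).sum() - np.abs(np.triu(w2, k=1)).sum()
        )
        if tested.size:
            null_edge_ge += d[tested] >= diff[tested] - 1e-12

    p_structure = float((1 + np.sum(null_m >= observed_m - 1e-12)) / (1 + n_perm))
    p_strength = float((1 + np.sum(null_s >= observed_s - 1e-12)) / (1 + n_perm))

    edge_tests = pd.DataFrame()
    if tested.size:
        raw = (1.0 + null_edge_ge) / (1.0 + n_perm)
        reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method=adjust)
        names = [
            (net1.nodes[iu[0][t]], net1.nodes[iu[1][t]]) for t in tested
        ]
        edge_tests = pd.DataFrame({
            "node_i": [a for a, _ in names],
            "node_j": [b for _, b in names],
            "observed_diff": diff[tested],
            "p_raw": raw,
            "p_adjusted": adjusted,
            "significant": reject,
        })

    return NCTResult(
        observed_max_edge_diff=observed_m,
        observed_strength_diff=observed_s,
        strengths=(s1, s2),
        p_structure=p_structure,
        p_strength=p_strength,
        n_perm=n_perm,
        seed=seed,
        edge_tests=edge_tests,
        adjust=adjust,
    )
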