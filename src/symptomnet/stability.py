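"""Bootstrap machinery for network accuracy and centrality stability.

Three procedures, all deterministic given their seed (per-replicate child
seeds are spawned up front, so a parallel execution order could not change
results):

* nonparametric bootstrap — rows resampled with replacement, the full
  estimation pipeline re-run per replicate; yields edge-weight quantile CIs
  and pairwise edge difference tests;
* case-dropping bootstrap — increasing fractions of participants dropped,
  correlation between subset and full-sample centrality recorded; summarised
  by the CS-coefficient (largest drop fraction at which the correlation stays
  above 0.7 with 95% probability);
* focal-node predictive-betweenness bootstrap — the distribution of
  focal-anchored betweenness counts across replicates.

Replicates whose estimation fails are excluded and counted, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .centrality import centrality_table, predictive_betweenness
from .correlations import mixed_matrix
from .ggm import WeightedNetwork, ebic_glasso
from .synthetic_data import CohortTable

__all__ = [
    "BootstrapResult",
    "CaseDropResult",
    "PredictiveBetweennessBootstrap",
    "network_estimator",
    "network_statistics",
    "nonparametric_bootstrap",
    "edge_difference_test",
    "case_dropping",
    "cs_coefficient",
    "bootstrap_predictive_betweenness",
]

DEFAULT_PROPORTIONS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))

CENTRALITY_INDICES = ("strength", "expected_influence", "bridge_expected_influence")


def _frame_of(table: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return table.values if isinstance(table, CohortTable) else table


def network_estimator(
    type_map: dict[str, str],
    communities: dict[str, str] | None = None,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> Callable[[pd.DataFrame], WeightedNetwork]:
    """Bind the standard pipeline (mixed correlations -> EBIC glasso) into a
    single DataFrame -> network callable for resampling procedures."""

    def estimate(frame: pd.DataFrame) -> WeightedNetwork:
        corr = mixed_matrix(frame, type_map=type_map)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ebic_glasso(
                corr, n=len(frame), gamma=gamma, n_lambdas=n_lambdas,
                min_ratio=min_ratio, tol=tol, max_iter=max_iter,
                communities=communities,
            )

    return estimate


def edge_label(a: str, b: str) -> str:
    return f"edge::{a}--{b}"


def network_statistics(net: WeightedNetwork, focal: str | None = None) -> pd.Series:
    """Flatten a network into a named statistic vector: every upper-triangle
    edge weight (zeros included, so replicates align) plus per-node strength,
    expected influence and, when labels exist, bridge expected influence."""
    stats: dict[str, float] = {}
    for i in range(net.p):
        for j in range(i + 1, net.p):
            stats[edge_label(net.nodes[i], net.nodes[j])] = float(net.weights[i, j])
    table = centrality_table(net, focal=focal)
    for index in CENTRALITY_INDICES:
        if index in table.columns:
            for node, value in table[index].items():
                stats[f"{index}::{node}"] = float(value)
    if focal is not None:
        for node, value in table["predictive_betweenness"].items():
            if node != focal:
                stats[f"predictive_betweenness::{node}"] = float(value)
    return pd.Series(stats)


@dataclass
class BootstrapResult:
    """Replicate-level statistics plus quantile summaries."""

    B: int
    seed: int
    point: pd.Series
    samples: pd.DataFrame  # one row per successful replicate
    n_failed: int = 0

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        alpha = (1.0 - level) / 2.0
        lower = self.samples.quantile(alpha)
        upper = self.samples.quantile(1.0 - alpha)
        median = self.samples.median()
        return pd.DataFrame({"lower": lower, "median": median, "upper": upper})

    def edge_ci(self, level: float = 0.95) -> pd.DataFrame:
        table = self.ci(level)
        return table.loc[[k for k in table.index if k.startswith("edge::")]]


def nonparametric_bootstrap(
    table: CohortTable | pd.DataFrame,
    estimator: Callable[[pd.DataFrame], pd.Series],
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Row-resampling bootstrap of an arbitrary named-statistic estimator.

    ``estimator`` maps a DataFrame to a pd.Series; for the full network
    pipeline compose :func:`network_estimator` with
    :func:`network_statistics`. Failed replicates are dropped and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    frame = _frame_of(table)
    n = len(frame)
    point = estimator(frame)
    children = np.random.SeedSequence(seed).spawn(B)
    rows, n_failed = [], 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        try:
            rows.append(estimator(frame.iloc[idx].reset_index(drop=True)))
        except Exception:
            n_failed += 1
    if not rows:
        raise RuntimeError(f"all {B} bootstrap replicates failed")
    samples = pd.DataFrame(rows).reset_index(drop=True)
    return BootstrapResult(B=B, seed=seed, point=point, samples=samples, n_failed=n_failed)


def _edge_key(edge) -> str:
    if isinstance(edge, str):
        return edge if edge.startswith("edge::") else f"edge::{edge}"
    a, b = edge
    return f"edge::{a}--{b}"


def edge_difference_test(boot: BootstrapResult, edge1, edge2, level: float = 0.95) -> bool:
    """True when the bootstrap quantile interval of ``w1 - w2`` excludes 0."""
    k1, k2 = _edge_key(edge1), _edge_key(edge2)
    for k in (k1, k2):
        if k not in boot.samples.columns:
            raise KeyError(f"{k} not tracked in bootstrap result")
    diff = boot.samples[k1] - boot.samples[k2]
    alpha = (1.0 - level) / 2.0
    lo, hi = diff.quantile(alpha), diff.quantile(1.0 - alpha)
    return bool(lo > 0.0 or hi < 0.0)


@dataclass
class CaseDropResult:
    """Subset-vs-full centrality correlations across drop proportions."""

    records: pd.DataFrame  # proportion, replicate, index, correlation
    proportions: tuple[float, ...]
    indices: tuple[str, ...]
    skipped: tuple[float, ...]
    n: int
    seed: int


def case_dropping(
    table: CohortTable | pd.DataFrame,
    estimator: Callable[[pd.DataFrame], WeightedNetwork],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    B: int = 100,
    indices: Sequence[str] = ("expected_influence",),
    seed: int = 0,
    communities: dict[str, str] | None = None,
) -> CaseDropResult:
    """Case-dropping bootstrap of centrality stability.

    For each drop proportion q, draws ``B`` subsamples retaining
    ``ceil((1-q) n)`` rows without replacement, re-estimates the network and
    records the Pearson correlation between subset and full-sample
    centrality for each requested index. Proportions leaving too few rows
    (n_sub <= number of nodes) are skipped with a warning.
    """
    if max(proportions) >= 1.0:
        raise ValueError("drop proportions must be < 1")
    frame = _frame_of(table)
    n = len(frame)
    full_net = estimator(frame)
    if communities:
        full_net.communities = dict(communities)
    full_tab = centrality_table(full_net)
    for index in indices:
        if index not in full_tab.columns:
            raise ValueError(f"unknown centrality index {index!r}")
    p = full_net.p

    records = []
    skipped = []
    children = np.random.SeedSequence(seed).spawn(len(proportions))
    for q, child in zip(proportions, children):
        n_sub = int(np.ceil((1.0 - q) * n))
        if n_sub <= p:
            warnings.warn(
                f"proportion {q:g} leaves n={n_sub} <= p={p}; skipped", stacklevel=2
            )
            skipped.append(float(q))
            continue
        for b, grandchild in enumerate(child.spawn(B)):
            rng = np.random.default_rng(grandchild)
            idx = rng.choice(n, size=n_sub, replace=False)
            try:
                net = estimator(frame.iloc[idx].reset_index(drop=True))
                if communities:
                    net.communities = dict(communities)
                tab = centrality_table(net)
            except Exception:
                for index in indices:
                    records.append((float(q), b, index, np.nan))
                continue
            for index in indices:
                x = full_tab[index].to_numpy()
                y = tab[index].reindex(full_tab.index).to_numpy()
                sx, sy = np.std(x), np.std(y)
                r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
                records.append((float(q), b, index, r))
    return CaseDropResult(
        records=pd.DataFrame(
            records, columns=["proportion", "replicate", "index", "correlation"]
        ),
        proportions=tuple(float(q) for q in proportions if q not in skipped),
        indices=tuple(indices),
        skipped=tuple(skipped),
        n=n,
        seed=seed,
    )


def cs_coefficient(
    result: CaseDropResult, cor_threshold: float = 0.7, prob: float = 0.95
) -> dict[str, float]:
    """Correlation-stability coefficient per centrality index.

    The largest tested drop proportion q at which the fraction of subsamples
    whose subset-vs-full correlation is at least ``cor_threshold`` reaches
    ``prob``; 0.0 when no proportion qualifies. Capped by construction at the
    largest tested proportion.
    """
    if result.records.empty:
        raise ValueError("case-dropping result is empty")
    out: dict[str, float] = {}
    for index in result.indices:
        sub = result.records[result.records["index"] == index]
        cs = 0.0
        for q in sorted(result.proportions):
            corr = sub.loc[sub["proportion"] == q, "correlation"]
            if len(corr) == 0:
                continue
            ok = np.mean(corr.fillna(-1.0).to_numpy() >= cor_threshold)
            if ok >= prob:
                cs = max(cs, float(q))
        out[index] = cs
    return out


@dataclass
class PredictiveBetweennessBootstrap:
    """Full-sample focal-anchored betweenness with replicate distributions
    (the point markers and variability whiskers of the usual figure)."""

    focal: str
    point: pd.Series
    samples: pd.DataFrame
    B: int
    seed: int
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "point": self.point,
            "median": self.samples.median(),
            "q025": self.samples.quantile(0.025),
            "q975": self.samples.quantile(0.975),
        })


def bootstrap_predictive_betweenness(
    table: CohortTable | pd.DataFrame,
    focal: str,
    estimator: Callable[[pd.DataFrame], WeightedNetwork],
    B: int = 1000,
    seed: int = 0,
) -> PredictiveBetweennessBootstrap:
    """Distribution of focal-anchored betweenness across bootstrap replicates."""
    frame = _frame_of(table)
    if focal not in frame.columns:
        raise KeyError(f"focal column {focal!r} not in table")

    def stat(df: pd.DataFrame) -> pd.Series:
        net = estimator(df)
        return predictive_betweenness(net, focal).drop(labels=[focal])

    boot = nonparametric_bootstrap(table, stat, B=B, seed=seed)
    return PredictiveBetweennessBootstrap(
        focal=focal, point=boot.point, samples=boot.samples,
        B=B, seed=seed, n_failed=boot.n_failed,
    )
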