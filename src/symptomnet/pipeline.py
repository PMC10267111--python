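"""End-to-end study orchestration.

Mirrors the analysis protocol of a symptom–biomarker network study: load and
validate a participant-by-variable table (24 ordinal depression items scored
0–4, three binary suicidality indicators, two positive biomarkers), apply
the severity inclusion rule (24-item total >= 8), drop the redundant
suicidal-ideation item (item 3) from the network node set, estimate the
mixed-type correlation matrix and the EBIC-glasso network, compute
centrality/bridge/flow summaries, run the bootstrap stability analyses, and
optionally compare networks between two subgroups.

Every stage receives a deterministic seed fanned out from the master seed,
so a full report is byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import synthetic_data as sdata
from .centrality import centrality_table, flow_edges, strongest_edges
from .comparison import nct
from .correlations import mixed_matrix
from .ggm import ebic_glasso
from .stability import (
    bootstrap_predictive_betweenness,
    case_dropping,
    cs_coefficient,
    edge_difference_test,
    network_estimator,
    network_statistics,
    nonparametric_bootstrap,
)
from .synthetic_data import CohortTable

logger = logging.getLogger("symptomnet")

__all__ = [
    "StudyConfig",
    "AnalysisReport",
    "load_cohort",
    "apply_inclusion",
    "prevalence_ci",
    "run_study",
]


@dataclass
class StudyConfig:
    """Variable roles, inclusion rules and estimator settings for one study."""

    hamd_items: tuple[str, ...] = sdata.HAMD_ALL_ITEMS
    suicidality_items: tuple[str, ...] = sdata.SUICIDALITY_ITEMS
    biomarkers: tuple[str, ...] = sdata.BIOMARKERS
    grouping: str | None = "gender"
    exclude: tuple[str, ...] = ("HAMD3",)
    inclusion_threshold: int = 8
    gamma: float = 0.5
    n_lambdas: int = 100
    min_ratio: float = 0.01
    glasso_tol: float = 1e-4
    glasso_max_iter: int = 200
    focal: str = "ACTH"
    B_boot: int = 1000
    B_casedrop: int = 100
    casedrop_proportions: tuple[float, ...] = tuple(
        np.round(np.arange(0.05, 0.751, 0.05), 2)
    )
    stability_indices: tuple[str, ...] = ("expected_influence", "bridge_expected_influence")
    n_perm: int = 1000
    run_nct: bool = True
    ci_method: str = "wald"
    n_participants: int = 898
    top_edges: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inclusion_threshold < 0:
            raise ValueError("inclusion threshold must be >= 0")
        bad = [v for v in self.exclude if v not in self.hamd_items]
        if bad:
            raise ValueError(f"excluded items not among the scale items: {bad}")

    @property
    def analysis_columns(self) -> tuple[str, ...]:
        return self.hamd_items + self.suicidality_items + self.biomarkers

    @property
    def network_nodes(self) -> tuple[str, ...]:
        return tuple(c for c in self.analysis_columns if c not in self.exclude)

    def stage_seeds(self) -> dict[str, int]:
        """Fan the master seed out to independent per-stage seeds (< 2^31)."""
        state = np.random.SeedSequence(self.seed).generate_state(5)
        names = ("simulate", "bootstrap", "case_dropping", "predictive_betweenness", "nct")
        return {k: int(v & 0x7FFFFFFF) for k, v in zip(names, state)}


def _type_map(config: StudyConfig) -> dict[str, str]:
    tm = {c: "ordinal" for c in config.hamd_items}
    tm.update({c: "binary" for c in config.suicidality_items})
    tm.update({c: "continuous" for c in config.biomarkers})
    return tm


def _communities(config: StudyConfig) -> dict[str, str]:
    comm = {c: "depression" for c in config.hamd_items}
    comm.update({c: "suicidality" for c in config.suicidality_items})
    comm.update({c: "biomarkers" for c in config.biomarkers})
    return comm


def load_cohort(path: str | Path, config: StudyConfig) -> CohortTable:
    """Read and validate a cohort CSV.

    Rows with a missing value on any analysis variable are dropped (with a
    logged count): the resampling-based network methods require complete
    cases. Out-of-range values fail loudly with row/column diagnostics.
    """
    frame = pd.read_csv(path)
    missing_cols = [c for c in config.analysis_columns if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"input is missing analysis columns: {missing_cols}")

    cols = list(config.analysis_columns)
    complete = frame[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing analysis values", n_dropped)
    frame = frame.loc[complete].reset_index(drop=True)

    for c in config.hamd_items:
        vals = frame[c].to_numpy()
        bad = (vals != np.floor(vals)) | (vals < 0) | (vals > 4)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"column {c!r}, row {row}: value {vals[row]!r} outside ordinal range 0..4"
            )
        frame[c] = vals.astype(int)
    for c in config.suicidality_items:
        vals = frame[c].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            row = int(np.flatnonzero(~np.isin(vals, (0, 1)))[0])
            raise ValueError(
                f"column {c!r}, row {row}: value {vals[row]!r} is not binary 0/1"
            )
        frame[c] = vals.astype(int)
    for c in config.biomarkers:
        frame[c] = frame[c].astype(float)

    subgroup = None
    if config.grouping is not None and config.grouping in frame.columns:
        subgroup = frame[config.grouping]
    return CohortTable(
        values=frame[cols],
        type_map=_type_map(config),
        communities=_communities(config),
        subgroup=subgroup,
    )


def apply_inclusion(table: CohortTable, config: StudyConfig) -> CohortTable:
    """Retain rows whose full-scale depression total meets the threshold.

    The total runs over all 24 items — the network-level exclusion of item 3
    does not apply to the severity total.
    """
    missing = [c for c in config.hamd_items if c not in table.values.columns]
    if missing:
        raise ValueError(f"cannot total the scale, items missing: {missing}")
    total = table.values[list(config.hamd_items)].sum(axis=1)
    keep = total >= config.inclusion_threshold
    subgroup = None
    if table.subgroup is not None:
        subgroup = table.subgroup.loc[keep.to_numpy()].reset_index(drop=True)
    return CohortTable(
        values=table.values.loc[keep].reset_index(drop=True),
        type_map=dict(table.type_map),
        communities=dict(table.communities),
        subgroup=subgroup,
    )


def prevalence_ci(
    count: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Prevalence with a binomial confidence interval, in percent (2 dp).

    Default is the Wald (normal-approximation) interval
    ``p +- z sqrt(p(1-p)/n)`` truncated to [0, 1]; Wilson is available via
    ``method="wilson"``.
    """
    if not 0 <= count <= n or n < 1:
        raise ValueError("need 0 <= count <= n and n >= 1")
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    lower, upper = proportion_confint(count, n, alpha=1.0 - level, method=sm_method)
    lower, upper = float(np.clip(lower, 0, 1)), float(np.clip(upper, 0, 1))
    est = count / n
    return (round(est * 100, 2), round(lower * 100, 2), round(upper * 100, 2))


@dataclass
class AnalysisReport:
    """Full study output; every block records the seed that produced it."""

    content: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.content, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _round(x: float, nd: int = 10) -> float:
    return float(np.round(float(x), nd))


def run_study(config: StudyConfig, table: CohortTable | None = None) -> AnalysisReport:
    """Execute the whole protocol and return a deterministic report.

    When no table is supplied, a synthetic cohort with the study's default
    structure is generated from the master seed.
    """
    seeds = config.stage_seeds()
    if table is None:
        table, _truth = sdata.default_study_cohort(
            n=config.n_participants, seed=seeds["simulate"]
        )
    n_total = table.n
    table = apply_inclusion(table, config)
    n_included = table.n
    logger.info("inclusion rule retained %d of %d rows", n_included, n_total)

    prevalence = {}
    for c in config.suicidality_items:
        count = int(table.values[c].sum())
        est, lo, hi = prevalence_ci(count, n_included, method=config.ci_method)
        prevalence[c] = {"count": count, "percent": est, "ci_lower": lo, "ci_upper": hi}
    hamd_total = table.values[list(config.hamd_items)].sum(axis=1)
    descriptives = {
        "hamd_total_mean": _round(hamd_total.mean(), 4),
        "hamd_total_sd": _round(hamd_total.std(ddof=1), 4),
        **{
            f"{c}_mean": _round(table.values[c].mean(), 4)
            for c in config.biomarkers
        },
        **{
            f"{c}_sd": _round(table.values[c].std(ddof=1), 4)
            for c in config.biomarkers
        },
    }

    # --- network estimation on the node subset (item 3 excluded by default)
    nodes = list(config.network_nodes)
    frame = table.values[nodes]
    type_map = {k: v for k, v in table.type_map.items() if k in nodes}
    communities = {k: v for k, v in table.communities.items() if k in nodes}
    corr = mixed_matrix(frame, type_map=type_map)
    net = ebic_glasso(
        corr, n=n_included, gamma=config.gamma, n_lambdas=config.n_lambdas,
        min_ratio=config.min_ratio, tol=config.glasso_tol,
        max_iter=config.glasso_max_iter, communities=communities,
    )
    cent = centrality_table(net, focal=config.focal)
    top = strongest_edges(net, k=config.top_edges)
    flow = flow_edges(net, config.focal)

    estimator = network_estimator(
        type_map, communities=communities, gamma=config.gamma,
        n_lambdas=config.n_lambdas, min_ratio=config.min_ratio,
        tol=config.glasso_tol, max_iter=config.glasso_max_iter,
    )

    # --- bootstrap accuracy of edge weights + difference tests
    boot = nonparametric_bootstrap(
        frame,
        lambda df: network_statistics(estimator(df)),
        B=config.B_boot,
        seed=seeds["bootstrap"],
    )
    edge_keys = [f"edge::{a}--{b}" for a, b, _ in net.edge_list()]
    sig = total_pairs = 0
    for i in range(len(edge_keys)):
        for j in range(i + 1, len(edge_keys)):
            total_pairs += 1
            sig += edge_difference_test(boot, edge_keys[i], edge_keys[j])
    edge_ci = boot.edge_ci()

    # --- case-dropping stability
    drop = case_dropping(
        frame, estimator, proportions=config.casedrop_proportions,
        B=config.B_casedrop, indices=config.stability_indices,
        seed=seeds["case_dropping"], communities=communities,
    )
    cs = cs_coefficient(drop)

    # --- focal-node predictive betweenness bootstrap
    pb = bootstrap_predictive_betweenness(
        frame, config.focal, estimator, B=config.B_boot,
        seed=seeds["predictive_betweenness"],
    )

    # --- subgroup comparison
    nct_block = None
    if config.run_nct and table.subgroup is not None:
        groups = table.subgroup.to_numpy()
        levels = np.unique(groups)
        if len(levels) == 2:
            f1 = frame.loc[groups == levels[0]].reset_index(drop=True)
            f2 = frame.loc[groups == levels[1]].reset_index(drop=True)
            result = nct(f1, f2, estimator, n_perm=config.n_perm, seed=seeds["nct"])
            nct_block = result.to_dict()
            nct_block["group_levels"] = [str(levels[0]), str(levels[1])]
            nct_block["group_sizes"] = [int(len(f1)), int(len(f2))]
        else:
            logger.warning("grouping column is not binary; comparison skipped")

    content = {
        "seeds": seeds,
        "cohort": {
            "n_total": n_total,
            "n_included": n_included,
            "prevalence": prevalence,
            "descriptives": descriptives,
        },
        "network": {
            "nodes": nodes,
            "n_nodes": net.p,
            "n_edges": len(net.edge_list()),
            "lambda": _round(net.lam),
            "gamma": config.gamma,
            "global_strength": _round(np.abs(np.triu(net.weights, 1)).sum()),
            "strongest_edges": [[a, b, _round(w)] for a, b, w in top],
            "edges": [[a, b, _round(w)] for a, b, w in net.edge_list()],
        },
        "centrality": {
            node: {k: (None if pd.isna(v) else _round(v)) if k != "community" else v
                   for k, v in row.items()}
            for node, row in cent.to_dict(orient="index").items()
        },
        "flow": {
            "focal": flow.focal,
            "direct": [[v, _round(w)] for v, w in flow.direct],
            "indirect": flow.indirect,
            "unreachable": flow.unreachable,
        },
        "stability": {
            "B": config.B_boot,
            "n_failed": boot.n_failed,
            "edge_ci": {
                k: [_round(edge_ci.loc[k, "lower"]), _round(edge_ci.loc[k, "median"]),
                    _round(edge_ci.loc[k, "upper"])]
                for k in edge_keys
            },
            "edge_difference_significant_fraction": _round(
                sig / total_pairs if total_pairs else 0.0, 4
            ),
            "cs_coefficient": {k: _round(v, 4) for k, v in cs.items()},
            "casedrop_skipped": list(drop.skipped),
        },
        "predictive_betweenness": {
            "focal": pb.focal,
            "B": pb.B,
            "n_failed": pb.n_failed,
            "summary": {
                node: [_round(row["point"]), _round(row["median"]),
                       _round(row["q025"]), _round(row["q975"])]
                for node, row in pb.summary().to_dict(orient="index").items()
            },
        },
        "comparison": nct_block,
    }
    return AnalysisReport(content=content)
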