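"""Synthetic cohorts with known network ground truth.

Observed variables are generated through a latent-Gaussian (copula) mechanism:
a sparse precision matrix defines a Gaussian graphical model, latent vectors
are drawn from the implied correlation structure, and each variable is then
mapped to its observed scale — ordinal items by thresholding at fixed cut
points, binary items by a single cut point set from a target prevalence, and
positive right-skewed biomarkers by exponentiation (lognormal margins). This
is exactly the data-generating model the polychoric/polyserial estimators
downstream assume, so parameter recovery is a well-posed end-to-end test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroundTruthNetwork",
    "NodeSpec",
    "GeneratorConfig",
    "CohortTable",
    "make_ground_truth",
    "generate_cohort",
    "default_study_truth",
    "default_study_config",
    "default_study_cohort",
]


def precision_to_partials(precision: np.ndarray) -> np.ndarray:
    """Standardise a precision matrix to partial correlations.

    ``partial_ij = -theta_ij / sqrt(theta_ii * theta_jj)``, zero diagonal.
    """
    d = np.sqrt(np.diag(precision))
    partials = -precision / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return partials


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A positive-definite precision matrix with community labels.

    The implied partial-correlation matrix (``partials``) is the edge-weight
    ground truth against which estimated networks are compared.
    """

    precision: np.ndarray
    nodes: tuple[str, ...]
    communities: dict[str, str]
    bridge_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        theta = np.asarray(self.precision, dtype=float)
        if not np.allclose(theta, theta.T, atol=1e-12):
            raise ValueError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(theta).min() <= 0:
            raise ValueError("precision matrix must be positive-definite")

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def partials(self) -> np.ndarray:
        return precision_to_partials(self.precision)

    @property
    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent Gaussian implied by the precision."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def edge_list(self) -> list[tuple[str, str, float]]:
        part = self.partials
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if part[i, j] != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(part[i, j])))
        return out


@dataclass(frozen=True)
class NodeSpec:
    """Observation model for one variable.

    kind:
        ``ordinal``     — 5-level item, discretised at ``thresholds`` (4 cuts);
        ``binary``      — thresholded at ``threshold`` (latent cut point);
        ``continuous``  — lognormal, ``exp(meanlog + sdlog * z)``.
    """

    kind: Literal["ordinal", "binary", "continuous"]
    community: str
    thresholds: tuple[float, ...] | None = None
    threshold: float | None = None
    meanlog: float = 0.0
    sdlog: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "ordinal":
            if self.thresholds is None or len(self.thresholds) != 4:
                raise ValueError("ordinal nodes need exactly 4 thresholds")
            if not np.all(np.diff(self.thresholds) > 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.kind == "binary" and self.threshold is None:
            raise ValueError("binary nodes need a threshold")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    node_spec: dict[str, NodeSpec]
    seed: int = 0
    subgroup_name: str | None = None
    subgroup_prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class CohortTable:
    """Participant-by-variable table plus per-variable metadata.

    ``values`` holds only analysis variables; an optional binary ``subgroup``
    series (e.g. gender) is carried alongside for subgroup comparisons.
    """

    values: pd.DataFrame
    type_map: dict[str, str]
    communities: dict[str, str]
    subgroup: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.type_map]
        if missing:
            raise ValueError(f"columns without a type: {missing}")

    @property
    def n(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        """Write values (+ subgroup) as CSV with a sidecar metadata JSON."""
        path = Path(path)
        frame = self.values.copy()
        if self.subgroup is not None:
            frame[self.subgroup.name] = self.subgroup.to_numpy()
        frame.to_csv(path, index=False)
        meta = {
            "type_map": self.type_map,
            "communities": self.communities,
            "subgroup": None if self.subgroup is None else str(self.subgroup.name),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def make_ground_truth(
    p: int,
    communities: Mapping[str, str],
    sparsity: float,
    bridge_spec: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
    *,
    weight_range: tuple[float, float] = (0.15, 0.35),
    fixed_edges: Sequence[tuple[str, str, float]] = (),
    cross_community: Literal["random", "bridge-only"] = "random",
) -> GroundTruthNetwork:
    """Draw a sparse positive-definite precision matrix with known support.

    Off-diagonal support is sampled with probability ``sparsity`` per pair
    (over all pairs, or within communities only when ``cross_community`` is
    ``"bridge-only"``); random edge weights are uniform in ``weight_range``
    with random sign. ``fixed_edges`` then pins designated within- or
    cross-community partial correlations and ``bridge_spec`` pins designated
    cross-community bridges. Positive-definiteness is enforced by adding a
    diagonal shift ``delta`` (doubling from 1e-3) until the smallest
    eigenvalue exceeds 1e-6; the shift shrinks magnitudes but preserves
    support and signs.
    """
    if p < 3 and sparsity > 0 and p != 2:
        raise ValueError("need p >= 3 for a random support (or p == 2 with a fixed edge)")
    nodes = tuple(communities)
    if len(nodes) != p:
        raise ValueError(f"communities map has {len(nodes)} nodes, expected {p}")
    index = {name: i for i, name in enumerate(nodes)}
    for a, b, _ in bridge_spec:
        if communities[a] == communities[b]:
            raise ValueError(f"bridge edge {a}--{b} does not cross communities")

    rng = np.random.default_rng(seed)
    target = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            same = communities[nodes[i]] == communities[nodes[j]]
            if cross_community == "bridge-only" and not same:
                continue
            if rng.random() < sparsity:
                w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
                target[i, j] = target[j, i] = w
    for a, b, w in list(fixed_edges) + list(bridge_spec):
        i, j = index[a], index[b]
        target[i, j] = target[j, i] = w

    theta = np.eye(p) - target  # theta_ij = -partial_ij when diagonal is constant
    delta = 1e-3
    for _ in range(64):
        if np.linalg.eigvalsh(theta).min() > 1e-6:
            break
        theta = theta + delta * np.eye(p)
        delta *= 2.0
    else:
        raise RuntimeError(
            "could not reach positive-definiteness; requested weights too strong "
            f"(min eigenvalue {np.linalg.eigvalsh(theta).min():.3g})"
        )

    bridge_nodes = tuple(dict.fromkeys(n for a, b, _ in bridge_spec for n in (a, b)))
    return GroundTruthNetwork(
        precision=theta,
        nodes=nodes,
        communities=dict(communities),
        bridge_nodes=bridge_nodes,
    )


def generate_cohort(truth: GroundTruthNetwork, config: GeneratorConfig) -> CohortTable:
    """Sample an observed cohort from a ground-truth network.

    Latent vectors are drawn from the Gaussian with the truth's implied
    correlation matrix (standard-normal margins, so threshold parameters are
    on the z scale), then mapped per node kind. Deterministic given
    ``config.seed``.
    """
    names = list(config.node_spec)
    if tuple(names) != truth.nodes:
        raise ValueError(
            f"config nodes {names[:3]}...({len(names)}) do not match truth nodes "
            f"({truth.p})"
        )
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(truth.latent_correlation)
    z = rng.standard_normal((config.n, truth.p)) @ chol.T

    columns: dict[str, np.ndarray] = {}
    type_map: dict[str, str] = {}
    for k, name in enumerate(names):
        spec = config.node_spec[name]
        if spec.kind == "ordinal":
            columns[name] = np.searchsorted(np.asarray(spec.thresholds), z[:, k]).astype(int)
        elif spec.kind == "binary":
            columns[name] = (z[:, k] > spec.threshold).astype(int)
        else:
            columns[name] = np.exp(spec.meanlog + spec.sdlog * z[:, k])
        type_map[name] = spec.kind

    subgroup = None
    if config.subgroup_name is not None:
        labels = (rng.random(config.n) < config.subgroup_prevalence).astype(int)
        subgroup = pd.Series(labels, name=config.subgroup_name)

    return CohortTable(
        values=pd.DataFrame(columns),
        type_map=type_map,
        communities=dict(truth.communities),
        subgroup=subgroup,
    )


# --------------------------------------------------------------------------
# Default study layout: the 24 ordinal depression items (item 3, suicidal
# ideation, is generated but later excluded from the network as redundant
# with the SI indicator), three binary suicidality indicators, two positive
# biomarkers of the hypothalamic-pituitary-adrenal axis.

HAMD_ALL_ITEMS: tuple[str, ...] = tuple(f"HAMD{i}" for i in range(1, 25))
HAMD_NETWORK_ITEMS: tuple[str, ...] = tuple(
    f"HAMD{i}" for i in range(1, 25) if i != 3
)
SUICIDALITY_ITEMS: tuple[str, ...] = ("SI", "SP", "SA")
BIOMARKERS: tuple[str, ...] = ("ACTH", "Cort")

#: Latent cut points shared by the ordinal items; chosen so category mass
#: decays (about .55/.28/.12/.04/.01), giving a plausibly right-skewed
#: depression-severity profile at the item level.
DEFAULT_ORDINAL_THRESHOLDS: tuple[float, ...] = tuple(
    float(stats.norm.ppf(q)) for q in (0.55, 0.83, 0.95, 0.99)
)

#: Target prevalences for current suicidal ideation / plan / attempt.
DEFAULT_BINARY_PREVALENCE: dict[str, float] = {"SI": 0.312, "SP": 0.304, "SA": 0.3062}

#: Lognormal margins approximating plasma ACTH (pg/ml) and cortisol (nmol/L)
#: distributions with standard deviations near their means (strong right skew).
DEFAULT_BIOMARKER_PARAMS: dict[str, tuple[float, float]] = {
    "ACTH": (3.2, 0.80),
    "Cort": (2.6, 0.65),
}


def default_communities(include_item3: bool = True) -> dict[str, str]:
    items = HAMD_ALL_ITEMS if include_item3 else HAMD_NETWORK_ITEMS
    comm = {name: "depression" for name in items}
    comm.update({name: "suicidality" for name in SUICIDALITY_ITEMS})
    comm.update({name: "biomarkers" for name in BIOMARKERS})
    return comm


def default_study_truth(seed: int = 0) -> GroundTruthNetwork:
    """The 29-variable ground truth emulating the study's community structure
    (the network analysed downstream has 28 nodes once item 3 is dropped).

    Within-community support is random at 15% density; designated edges pin
    the qualitative findings being emulated: initial/middle insomnia and the
    two anxiety items as strong depression edges, a fully connected
    suicidality triad, a strong ACTH--Cort link, and bridge edges that make
    cortisol (to suicide attempt and retardation), ACTH (to somatic
    symptoms) and suicidal ideation (to hopelessness) the bridge nodes.
    Item 3 of the depression scale is tied to the SI indicator (partial 0.45)
    to reproduce the redundancy that motivates its exclusion.
    """
    comm = default_communities()
    fixed = [
        ("HAMD3", "SI", 0.45),
        ("HAMD4", "HAMD5", 0.35),
        ("HAMD10", "HAMD11", 0.30),
        ("HAMD18", "HAMD19", 0.25),
        ("SA", "SP", 0.35),
        ("SA", "SI", 0.30),
        ("SP", "SI", 0.25),
        ("ACTH", "Cort", 0.30),
    ]
    bridges = [
        ("Cort", "SA", 0.20),
        ("Cort", "HAMD8", 0.18),
        ("ACTH", "HAMD13", 0.15),
        ("SI", "HAMD23", 0.18),
    ]
    return make_ground_truth(
        p=len(comm),
        communities=comm,
        sparsity=0.15,
        bridge_spec=bridges,
        seed=seed,
        fixed_edges=fixed,
        cross_community="bridge-only",
    )


def default_study_config(n: int = 898, seed: int = 0) -> GeneratorConfig:
    """Generator settings matching the emulated cohort: n = 898 participants,
    binary prevalences near 31%, right-skewed biomarkers, and an independent
    binary gender label (59% one group) for null subgroup comparisons."""
    spec: dict[str, NodeSpec] = {}
    comm = default_communities()
    for name in HAMD_ALL_ITEMS:
        spec[name] = NodeSpec(
            kind="ordinal", community=comm[name], thresholds=DEFAULT_ORDINAL_THRESHOLDS
        )
    for name in SUICIDALITY_ITEMS:
        prev = DEFAULT_BINARY_PREVALENCE[name]
        spec[name] = NodeSpec(
            kind="binary", community=comm[name], threshold=float(stats.norm.ppf(1 - prev))
        )
    for name in BIOMARKERS:
        meanlog, sdlog = DEFAULT_BIOMARKER_PARAMS[name]
        spec[name] = NodeSpec(
            kind="continuous", community=comm[name], meanlog=meanlog, sdlog=sdlog
        )
    return GeneratorConfig(
        n=n, node_spec=spec, seed=seed, subgroup_name="gender", subgroup_prevalence=0.59
    )


def default_study_cohort(n: int = 898, seed: int = 0) -> tuple[CohortTable, GroundTruthNetwork]:
    truth = default_study_truth(seed=seed)
    table = generate_cohort(truth, default_study_config(n=n, seed=seed + 1))
    return table, truth
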