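"""Mixed-type correlation estimation for ordinal, binary and continuous data.

All ordinal (and binary, as 2-category ordinal) variables are modelled as
discretised latent standard normals. Pairwise latent correlations are then
estimated by the classical two-step procedure: thresholds fixed at inverse
normal CDF values of the cumulative marginal proportions, followed by a
bounded one-dimensional maximisation of the bivariate-normal likelihood over
the correlation. Ordinal x ordinal gives the polychoric estimator (the 2x2
special case is the tetrachoric), ordinal x continuous the polyserial, and
continuous x continuous plain Pearson.

Pairwise estimates need not form a jointly positive-semidefinite matrix;
``nearest_psd`` repairs the assembled matrix by eigenvalue clipping before it
is handed to the graphical-model stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, owens_t

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import CohortTable

__all__ = [
    "PolychoricFit",
    "CorrelationMatrix",
    "bvn_cdf",
    "polychoric",
    "polyserial",
    "mixed_matrix",
    "nearest_psd",
]

_RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12
_CLIP = 37.0  # |z| beyond which the normal CDF is 0/1 to double precision


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` via Owen's T.

    Vectorised in ``h`` and ``k`` (broadcast), scalar ``rho``; absolute
    accuracy near machine precision (well inside the 1e-8 tolerance used by
    the likelihood code). Arguments at +-inf are handled by clipping.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))
    # nudge exact zeros so the a-coefficients below are well-defined
    h = np.where(h == 0.0, 1e-15, h)
    k = np.where(k == 0.0, 1e-15, k)
    s = math.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    beta = np.where(h * k > 0.0, 0.0, 0.5)
    p = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(p, 0.0, 1.0)


def _cell_probabilities(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the bivariate normal over a threshold grid.

    ``tx``/``ty`` are interior thresholds; returns an
    ``(len(tx)+1) x (len(ty)+1)`` table summing to 1.
    """
    gx = np.concatenate(([-_CLIP], tx, [_CLIP]))
    gy = np.concatenate(([-_CLIP], ty, [_CLIP]))
    grid = bvn_cdf(gx[:, None], gy[None, :], rho)
    return np.diff(np.diff(grid, axis=0), axis=1)


def _thresholds(counts: np.ndarray, name: str) -> np.ndarray:
    """Two-step thresholds: inverse normal CDF of cumulative proportions."""
    if (counts > 0).sum() < 2:
        raise ValueError(f"column {name!r} has fewer than 2 observed categories")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


@dataclass(frozen=True)
class PolychoricFit:
    """Two-step polychoric estimate: latent correlation plus thresholds."""

    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float
    at_bound: bool = False


def _codes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer category codes (0..K-1) and per-category counts."""
    vals, codes = np.unique(np.asarray(x), return_inverse=True)
    counts = np.bincount(codes, minlength=len(vals))
    return codes, counts


def polychoric(x, y, name_x: str = "x", name_y: str = "y") -> PolychoricFit:
    """Polychoric correlation between two ordinal columns (two-step ML).

    The tetrachoric correlation is the special case of two binary columns.
    Estimates that land at the optimiser bound (|rho| ~ 0.999, typical of
    contingency tables dominated by empty cells) are flagged ``at_bound``.
    """
    cx, counts_x = _codes(x)
    cy, counts_y = _codes(y)
    if len(cx) != len(cy):
        raise ValueError("columns differ in length")
    if len(cx) < 10:
        raise ValueError("need at least 10 observations")
    tx = _thresholds(counts_x, name_x)
    ty = _thresholds(counts_y, name_y)
    table = np.zeros((len(counts_x), len(counts_y)))
    np.add.at(table, (cx, cy), 1.0)

    def neg_loglik(rho: float) -> float:
        probs = np.clip(_cell_probabilities(tx, ty, rho), _PROB_FLOOR, None)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    return PolychoricFit(
        rho=rho,
        thresholds_x=tx,
        thresholds_y=ty,
        loglik=-float(res.fun),
        at_bound=abs(rho) >= _RHO_BOUND - 1e-3,
    )


def polyserial(ordinal, continuous, name_ord: str = "x", name_cont: str = "y") -> float:
    """Two-step polyserial correlation between an ordinal and a continuous column.

    The continuous variable is standardised and treated as marginally normal;
    thresholds come from the ordinal margins; rho maximises the conditional
    likelihood of the observed categories given the continuous values.
    """
    z = np.asarray(continuous, dtype=float)
    sd = z.std()
    if sd == 0:
        raise ValueError(f"continuous column {name_cont!r} has zero variance")
    z = (z - z.mean()) / sd
    codes, counts = _codes(ordinal)
    tau = np.concatenate(([-_CLIP], _thresholds(counts, name_ord), [_CLIP]))
    lo, hi = tau[codes], tau[codes + 1]

    def neg_loglik(rho: float) -> float:
        s = math.sqrt(1.0 - rho * rho)
        p = ndtr((hi - rho * z) / s) - ndtr((lo - rho * z) / s)
        return -float(np.sum(np.log(np.clip(p, _PROB_FLOOR, None))))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class CorrelationMatrix:
    """Symmetric mixed-type correlation matrix with pair-level provenance."""

    values: np.ndarray
    names: list[str]
    method_map: dict[tuple[str, str], str] = field(default_factory=dict)
    n: int = 0

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


_DISPATCH = {
    ("ordinal", "ordinal"): "polychoric",
    ("binary", "binary"): "tetrachoric",
    ("ordinal", "binary"): "polychoric",
    ("binary", "ordinal"): "polychoric",
    ("ordinal", "continuous"): "polyserial",
    ("binary", "continuous"): "polyserial",
    ("continuous", "ordinal"): "polyserial",
    ("continuous", "binary"): "polyserial",
    ("continuous", "continuous"): "pearson",
}


def mixed_matrix(table: "CohortTable | pd.DataFrame", type_map: dict[str, str] | None = None,
                 psd_floor: float = 1e-6,
                 continuous_transform: str = "none") -> CorrelationMatrix:
    """Assemble the pairwise mixed-type correlation matrix of a cohort.

    Dispatch per pair of column types: ordinal/ordinal -> polychoric (binary
    treated as 2-category ordinal, so binary/binary -> tetrachoric),
    ordinal/continuous -> polyserial, continuous/continuous -> Pearson. Any
    per-pair failures are collected and reported together. The result is
    passed through :func:`nearest_psd`.

    ``continuous_transform="rank"`` replaces each continuous column by its
    normal scores before estimation (a nonparanormal/Gaussian-copula step
    that undoes skewed margins such as lognormal biomarkers); the default
    leaves continuous columns untransformed.
    """
    if type_map is None:
        if isinstance(table, pd.DataFrame):
            raise ValueError("a bare DataFrame needs an explicit type_map")
        frame, type_map = table.values, table.type_map
    else:
        frame = table if isinstance(table, pd.DataFrame) else table.values
    if continuous_transform not in ("none", "rank"):
        raise ValueError("continuous_transform must be 'none' or 'rank'")
    names = list(frame.columns)
    missing = [c for c in names if c not in type_map]
    if missing:
        raise ValueError(f"no type declared for columns: {missing}")

    p = len(names)
    data = {c: frame[c].to_numpy() for c in names}
    if continuous_transform == "rank":
        for c in names:
            if type_map[c] == "continuous":
                ranks = stats.rankdata(data[c])
                data[c] = stats.norm.ppf(ranks / (len(ranks) + 1.0))
    out = np.eye(p)
    methods: dict[tuple[str, str], str] = {}
    failures: list[str] = []
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            method = _DISPATCH[(type_map[a], type_map[b])]
            try:
                if method == "pearson":
                    r = float(np.corrcoef(data[a], data[b])[0, 1])
                elif method == "polyserial":
                    if type_map[a] == "continuous":
                        r = polyserial(data[b], data[a], name_ord=b, name_cont=a)
                    else:
                        r = polyserial(data[a], data[b], name_ord=a, name_cont=b)
                else:
                    r = polychoric(data[a], data[b], name_x=a, name_y=b).rho
            except ValueError as exc:
                failures.append(f"{a}--{b}: {exc}")
                continue
            out[i, j] = out[j, i] = r
            methods[(a, b)] = method
    if failures:
        raise ValueError("correlation estimation failed for pairs: " + "; ".join(failures))

    result = CorrelationMatrix(values=out, names=names, method_map=methods, n=len(frame))
    return nearest_psd(result, floor=psd_floor)


def nearest_psd(M: CorrelationMatrix | np.ndarray, floor: float = 1e-6) -> CorrelationMatrix:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it, the matrix is reassembled
    and rescaled back to unit diagonal. Inputs that are already
    positive-semidefinite are returned unchanged (idempotent).
    """
    if isinstance(M, CorrelationMatrix):
        values, names, methods, n = M.values, M.names, M.method_map, M.n
    else:
        values = np.asarray(M, dtype=float)
        names = [f"V{i}" for i in range(values.shape[0])]
        methods, n = {}, 0
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    values = (values + values.T) / 2.0
    eigval, eigvec = np.linalg.eigh(values)
    if eigval.min() >= floor:
        repaired = values
    else:
        repaired = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
        repaired = (repaired + repaired.T) / 2.0
    return CorrelationMatrix(values=repaired, names=names, method_map=methods, n=n)
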