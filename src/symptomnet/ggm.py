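"""Sparse Gaussian graphical model estimation with EBIC model selection.

The network is the partial-correlation matrix implied by an L1-penalised
precision-matrix estimate (graphical lasso; penalty on off-diagonals only).
The penalty is chosen by minimising the Extended Bayesian Information
Criterion over a logarithmically spaced path from ``lambda_max`` (the
smallest penalty giving an empty graph) downward:

    EBIC(lambda) = -n * (log det Theta - tr(S Theta)) + E log n + 4 E gamma log p

where E is the number of selected edges and gamma (default 0.5) trades
sparsity against fit. By default each candidate support is scored (and the
returned network's weights computed) at its support-constrained maximum
likelihood — the criterion's original formulation, free of lasso shrinkage —
with the penalised-likelihood shortcut available via ``score="penalized"``.
Ties are broken toward the sparser (larger-lambda) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn import config_context
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

try:  # core solver: skips re-validation and accepts a warm start
    from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_core
except ImportError:  # pragma: no cover
    _sk_core = None

from ._ipf import constrained_mle, constrained_mle_loglik
from .correlations import CorrelationMatrix

__all__ = [
    "GlassoFit",
    "WeightedNetwork",
    "glasso",
    "lambda_path",
    "ebic",
    "constrained_mle_loglik",
    "ebic_glasso",
]

_EDGE_EPS = 1e-8  # |theta| below this counts as a structural zero


def _as_array(S) -> tuple[np.ndarray, list[str] | None, int | None]:
    if isinstance(S, CorrelationMatrix):
        return np.asarray(S.values, dtype=float), list(S.names), S.n or None
    return np.asarray(S, dtype=float), None, None


@dataclass(frozen=True)
class GlassoFit:
    """One penalised fit: precision matrix, penalty, and diagnostics."""

    precision: np.ndarray
    lam: float
    loglik: float  # per-observation: log det Theta - tr(S Theta)
    converged: bool
    n_iter: int
    covariance: np.ndarray | None = None  # solver working covariance (warm starts)

    @property
    def edge_count(self) -> int:
        off = np.abs(np.triu(self.precision, k=1))
        return int((off > _EDGE_EPS).sum())

    @property
    def partials(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.precision))
        w = -self.precision / np.outer(d, d)
        np.fill_diagonal(w, 0.0)
        w[np.abs(w) <= _EDGE_EPS] = 0.0
        return w


@dataclass
class WeightedNetwork:
    """Estimated partial-correlation network with community labels."""

    weights: np.ndarray
    nodes: list[str]
    communities: dict[str, str] = field(default_factory=dict)
    lam: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        self.weights = w

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} not in network") from None

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out

    def to_graph(self) -> nx.Graph:
        """networkx view with ``weight`` and ``distance = 1/|weight|`` edges."""
        g = nx.Graph()
        for i, name in enumerate(self.nodes):
            g.add_node(name, community=self.communities.get(name))
        for a, b, w in self.edge_list():
            g.add_edge(a, b, weight=w, distance=1.0 / abs(w))
        return g

    def to_edge_tsv(self, path: str | Path) -> None:
        lines = ["node_i\tnode_j\tweight"]
        lines += [f"{a}\t{b}\t{w:.10g}" for a, b, w in self.edge_list()]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    def summary(self) -> dict:
        return {
            "p": self.p,
            "edges": len(self.edge_list()),
            "lambda": self.lam,
            "gamma": self.gamma,
        }


def glasso(S, lam: float, tol: float = 1e-4, max_iter: int = 200,
           mode: str = "auto", cov_init: np.ndarray | None = None) -> GlassoFit:
    """Graphical lasso at a single penalty.

    Maximises ``log det Theta - tr(S Theta) - lam * sum_{i!=j} |Theta_ij|``
    (penalty on off-diagonals only; at ``lam = 0`` the solution is the
    inverse of S). Penalties at or above the largest absolute off-diagonal
    of S give the exact closed-form diagonal solution. ``mode="auto"``
    dispatches to the lars inner solver in the sparse regime and coordinate
    descent in the dense regime, both solving the same problem to ``tol``.
    Non-convergence returns a fit flagged ``converged=False`` with a warning.
    """
    S_arr, _, _ = _as_array(S)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    lam_max = float(np.max(np.abs(S_arr - np.diag(np.diag(S_arr))))) if S_arr.shape[0] > 1 else 0.0
    if lam >= lam_max and lam > 0:
        precision = np.diag(1.0 / np.diag(S_arr))
        sign, logdet = np.linalg.slogdet(precision)
        return GlassoFit(precision=precision, lam=float(lam),
                         loglik=float(logdet - np.trace(S_arr @ precision)),
                         converged=True, n_iter=0,
                         covariance=np.diag(np.diag(S_arr)))
    if mode == "auto":
        mode = "lars" if lam >= 0.35 * lam_max else "cd"
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if _sk_core is not None:
            with config_context(skip_parameter_validation=True, assume_finite=True):
                try:
                    covariance, precision, _, n_iter = _sk_core(
                        S_arr, lam, cov_init=cov_init, mode=mode, tol=tol,
                        enet_tol=tol, max_iter=max_iter,
                    )
                except (OverflowError, ValueError, FloatingPointError,
                        np.linalg.LinAlgError):
                    # lars can destabilise on near-degenerate subproblems
                    # (NaN directions, runaway Cholesky jitter); coordinate
                    # descent solves the same convex problem
                    if mode == "cd":
                        raise
                    covariance, precision, _, n_iter = _sk_core(
                        S_arr, lam, cov_init=cov_init, mode="cd", tol=tol,
                        enet_tol=tol, max_iter=max_iter,
                    )
        else:  # pragma: no cover - public fallback, no warm start
            covariance, precision, n_iter = _sk_graphical_lasso(
                S_arr, alpha=lam, mode=mode, tol=tol, max_iter=max_iter,
                return_n_iter=True,
            )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                f"graphical lasso did not converge at lambda={lam:.4g} "
                f"within {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
    precision = (precision + precision.T) / 2.0
    sign, logdet = np.linalg.slogdet(precision)
    loglik = float(logdet - np.trace(S_arr @ precision)) if sign > 0 else -np.inf
    return GlassoFit(precision=precision, lam=float(lam), loglik=loglik,
                     converged=converged, n_iter=int(n_iter), covariance=covariance)


def lambda_path(S, n_lambdas: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Logarithmically spaced penalty path from ``lambda_max`` downward.

    ``lambda_max`` is the largest absolute off-diagonal of S (the smallest
    penalty at which the selected graph is empty). An S with all-zero
    off-diagonals yields the single value 0.
    """
    if n_lambdas < 2:
        raise ValueError("n_lambdas must be >= 2")
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must be in (0, 1)")
    S_arr, _, _ = _as_array(S)
    lam_max = float(np.max(np.abs(S_arr - np.diag(np.diag(S_arr)))))
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def ebic(fit: GlassoFit, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fit: ``-2 loglik + E log n + 4 E gamma log p`` with
    the log-likelihood on the full-sample scale ``(n/2)(log det - tr)``."""
    if not np.isfinite(fit.loglik):
        return np.inf
    p = fit.precision.shape[0]
    E = fit.edge_count
    return float(-n * fit.loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p))




def ebic_glasso(
    S,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambdas: int = 100,
    min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 200,
    nodes: list[str] | None = None,
    communities: dict[str, str] | None = None,
    score: str = "refit",
    return_path: bool = False,
):
    """Fit the full penalty path and return the EBIC-minimising network.

    With the default ``score="refit"`` each candidate support is scored by
    the EBIC of its support-constrained maximum likelihood (the criterion's
    original definition, which does not charge the lasso shrinkage to the
    model), and the returned network is that constrained MLE — a relaxed
    estimate whose edge weights are not biased toward zero. With
    ``score="penalized"`` the penalised log-likelihood is scored directly
    and the penalised fit's partial correlations are returned (the common
    shortcut in psychometric-network software). Fits that fail
    (non-positive-definite at small penalties) are skipped; if every path
    point fails, an error is raised. Ties in EBIC are broken toward the
    larger penalty, i.e. the sparser model.
    """
    S_arr, names, n_from_S = _as_array(S)
    if n is None:
        n = n_from_S
    if n is None or n < 2:
        raise ValueError("sample size n is required (and must be >= 2)")
    if score not in ("refit", "penalized"):
        raise ValueError("score must be 'refit' or 'penalized'")
    p = S_arr.shape[0]
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: EBIC selection may be unstable", stacklevel=2)
    if nodes is None:
        nodes = names if names is not None else [f"V{i}" for i in range(p)]

    path = lambda_path(S_arr, n_lambdas=n_lambdas, min_ratio=min_ratio)
    best: GlassoFit | None = None
    best_score = np.inf
    scores = []
    n_failed = 0
    cache: dict[bytes, tuple[float, np.ndarray, float]] = {}
    prev_cov: np.ndarray | None = None
    for lam in path:  # decreasing lambda: ties resolve to the sparser fit
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = glasso(S_arr, lam=float(lam), tol=tol, max_iter=max_iter,
                             cov_init=prev_cov)
        except (FloatingPointError, OverflowError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if fit.covariance is not None:
            prev_cov = fit.covariance
        if score == "refit":
            support = np.abs(fit.precision) > _EDGE_EPS
            np.fill_diagonal(support, True)
            key = support.tobytes()
            if key not in cache:
                K0 = np.where(support, fit.precision, 0.0)
                K, ll = constrained_mle(S_arr, support, K0=K0)
                E = fit.edge_count
                value = (
                    float(-n * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))
                    if np.isfinite(ll) else np.inf
                )
                cache[key] = (value, K, ll)
            value, K_refit, ll_refit = cache[key]
            candidate = GlassoFit(precision=K_refit, lam=float(lam),
                                  loglik=ll_refit, converged=fit.converged,
                                  n_iter=fit.n_iter)
        else:
            value = ebic(fit, n=n, gamma=gamma)
            candidate = fit
        scores.append((float(lam), value, fit.edge_count))
        if value < best_score:
            best, best_score = candidate, value
    if best is None:
        raise RuntimeError(
            f"no positive-definite graphical-lasso fit on the path "
            f"({n_failed} of {len(path)} penalties failed)"
        )
    net = WeightedNetwork(
        weights=best.partials, nodes=list(nodes),
        communities=dict(communities or {}), lam=best.lam, gamma=gamma,
    )
    if return_path:
        return net, scores
    return net
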