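"""Ordinal partial-correlation network estimation.

The pipeline treats symptom ratings as ordinal manifestations of latent
Gaussian variables: pairwise polychoric correlations are estimated by
two-step maximum likelihood, the polychoric matrix feeds a graphical
lasso over a penalty path, and the extended Bayesian information
criterion (EBIC, hyperparameter gamma) selects the returned network.
Multiply imputed datasets are handled by stacking: all completed copies
are concatenated, one network is estimated, and the likelihood uses the
original number of participants as the effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import NODE_COMMUNITIES, NODE_ITEMS, NODE_LABELS

__all__ = [
    "EBICConfig",
    "CorrelationMatrix",
    "SymptomNetwork",
    "NetworkDescriptives",
    "build_node_table",
    "bvn_cdf",
    "polychoric_corr",
    "polychoric_matrix",
    "graphical_lasso",
    "ebic_select",
    "estimate_network_stacked",
    "network_descriptives",
    "precision_to_partial",
]

_CLIP = 8.0  # latent thresholds beyond +-8 SD are numerically at the boundary


def build_node_table(items: pd.DataFrame) -> pd.DataFrame:
    """Collapse instrument items into the 13 symptom-node columns.

    Seven PGD nodes are single TGI-SR+ items; four cPTSD clusters
    (re-experiencing, avoidance, sense of current threat, disturbances in
    relationships) are the sum of their two items; affective
    dysregulation and negative self-concept are single items.
    """
    out = {}
    for lab, cols in NODE_ITEMS.items():
        for c in cols:
            if c not in items.columns:
                raise KeyError(f"node {lab!r} needs item column {c!r}")
            if items[c].isna().any():
                raise ValueError(f"item {c!r} for node {lab!r} has missing values")
        out[lab] = items[list(cols)].sum(axis=1).to_numpy(dtype=float)
    return pd.DataFrame(out, index=items.index)


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X<=h, Y<=k), vectorized via Owen's T."""
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -0.9999, 0.9999))
    # avoid exact zeros so the Owen's T arguments stay finite
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    val = 0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k)) - special.owens_t(h, ah) - special.owens_t(k, ak)
    beta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    return np.clip(val - beta, 0.0, 1.0)


def _marginal_thresholds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed categories and their standard-normal cut points."""
    cats, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)[:-1] / len(x)
    return cats, stats.norm.ppf(cum)


def _cell_probabilities(ti: np.ndarray, tj: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the ordinal cross-table under rho."""
    a = np.concatenate([[-_CLIP], ti, [_CLIP]])
    b = np.concatenate([[-_CLIP], tj, [_CLIP]])
    F = bvn_cdf(a[:, None], b[None, :], rho)
    return F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]


def polychoric_corr(x: np.ndarray, y: np.ndarray, bound: float = 0.999) -> float:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Thresholds come from the marginal cumulative proportions; the latent
    correlation maximizes the bivariate-normal cell-probability
    likelihood over (-bound, bound).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, ti = _marginal_thresholds(x)
    cy, tj = _marginal_thresholds(y)
    if len(cx) < 2 or len(cy) < 2:
        raise ValueError("polychoric correlation needs >= 2 observed categories per variable")
    counts = np.zeros((len(cx), len(cy)))
    ix = np.searchsorted(cx, x)
    iy = np.searchsorted(cy, y)
    np.add.at(counts, (ix, iy), 1.0)
    counts /= counts.sum()  # invariant to duplicating rows (stacked estimation)

    def nll(rho: float) -> float:
        p = _cell_probabilities(ti, tj, rho)
        return -np.sum(counts * np.log(np.maximum(p, 1e-300)))

    res = optimize.minimize_scalar(nll, bounds=(-bound, bound), method="bounded",
                                   options={"xatol": 1e-6})
    return float(np.clip(res.x, -bound, bound))


def _repair_pd(S: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal."""
    w, V = np.linalg.eigh(S)
    if w.min() >= floor:
        return S
    S2 = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(S2))
    S2 = S2 / np.outer(d, d)
    S2 = (S2 + S2.T) / 2
    np.fill_diagonal(S2, 1.0)
    return S2


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with its effective n."""

    S: np.ndarray
    kind: str  # "polychoric" | "pearson"
    n: int
    labels: tuple[str, ...] = ()

    def validate(self) -> None:
        if not np.allclose(self.S, self.S.T):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")


def polychoric_matrix(nodes: pd.DataFrame, n_effective: int | None = None) -> CorrelationMatrix:
    """Pairwise polychoric correlation matrix of an ordinal node table.

    The assembled matrix is repaired to positive definiteness (eigenvalue
    clipping at 1e-6, rescaled to unit diagonal) when needed, since
    pairwise two-step estimates need not be jointly consistent.
    """
    cols = list(nodes.columns)
    for c in cols:
        if nodes[c].nunique(dropna=True) < 2:
            raise ValueError(f"node {c!r} is constant; polychoric correlation undefined")
    p = len(cols)
    S = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            S[i, j] = S[j, i] = polychoric_corr(nodes[cols[i]].to_numpy(), nodes[cols[j]].to_numpy())
    S = _repair_pd(S)
    return CorrelationMatrix(S, "polychoric", n_effective if n_effective is not None else len(nodes),
                             tuple(cols))


# ---------------------------------------------------------------------------
# graphical lasso


from numba import njit


@njit(cache=True)
def _lasso_cd(V: np.ndarray, s: np.ndarray, lam: float, beta: np.ndarray,
              tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Coordinate descent for 0.5 b'Vb - s'b + lam |b|_1 (V PSD)."""
    p = len(s)
    Vb = V @ beta
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            r = s[j] - (Vb[j] - V[j, j] * beta[j])
            a = abs(r) - lam
            new = (a if a > 0.0 else 0.0) * (1.0 if r > 0 else -1.0) / V[j, j]
            d = new - beta[j]
            if d != 0.0:
                for i in range(p):
                    Vb[i] += V[i, j] * d
                beta[j] = new
                if abs(d) > delta:
                    delta = abs(d)
        if delta < tol:
            break
    return beta


def _dual_gap(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    gap = np.sum(S * theta) - S.shape[0]
    gap += lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
    return float(gap)


def graphical_lasso(S: np.ndarray, lam: float, tol: float = 1e-9,
                    max_iter: int = 500, warm_W: np.ndarray | None = None,
                    warm_theta: np.ndarray | None = None) -> np.ndarray:
    """L1-penalized precision estimate (penalty on off-diagonals only).

    Maximizes ``log det T - tr(S T) - lam * sum_{i != j} |T_ij|`` by block
    coordinate descent over the covariance estimate (Friedman-style
    column sweeps). Convergence is declared when a full sweep changes no
    covariance entry by more than ``tol``; the duality gap of the
    returned precision is verified as a final check. ``lam = 0`` returns
    the unpenalized MLE ``inv(S)``.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        return np.linalg.inv(S)
    W = S.copy() if warm_W is None else warm_W.copy()
    np.fill_diagonal(W, np.diag(S))
    B = np.zeros((p - 1, p))
    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    if warm_theta is not None:  # beta_j = -theta_1j / theta_jj at the optimum
        for j in range(p):
            B[:, j] = -warm_theta[idx_cache[j], j] / warm_theta[j, j]
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            idx = idx_cache[j]
            V = np.ascontiguousarray(W[np.ix_(idx, idx)])
            B[:, j] = _lasso_cd(V, np.ascontiguousarray(S[idx, j]), lam,
                                np.ascontiguousarray(B[:, j]))
            w_new = V @ B[:, j]
            delta = max(delta, np.max(np.abs(w_new - W[idx, j])))
            W[idx, j] = W[j, idx] = w_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(last sweep moved covariance entries by {delta:.3g})"
        )
    theta = np.eye(p)
    for j in range(p):
        idx = idx_cache[j]
        t_jj = 1.0 / (W[j, j] - W[idx, j] @ B[:, j])
        theta[j, j] = t_jj
        theta[idx, j] = -B[:, j] * t_jj
    theta = (theta + theta.T) / 2
    gap = abs(_dual_gap(S, theta, lam))
    if gap > 1e-6:
        raise RuntimeError(f"graphical lasso converged with duality gap {gap:.3g} > 1e-6")
    theta[np.abs(theta) < 1e-12] = 0.0
    return theta


def precision_to_partial(theta: np.ndarray) -> np.ndarray:
    """Partial correlations -T_ij / sqrt(T_ii T_jj), zero diagonal."""
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


@dataclass
class EBICConfig:
    """EBIC graphical-lasso selection settings (gamma defaults to 0.5)."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


@dataclass
class SymptomNetwork:
    """Selected regularized partial-correlation network."""

    nodes: tuple[str, ...]
    weights: np.ndarray            # partial correlations, zero diagonal
    precision: np.ndarray
    selected_lambda: float
    n: int
    communities: dict[str, str] = field(default_factory=dict)
    path: pd.DataFrame | None = None  # lambda, n_edges, ebic diagnostics

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_set(self, tol: float = 0.0) -> set[tuple[int, int]]:
        return {(i, j) for i in range(self.p) for j in range(i + 1, self.p)
                if abs(self.weights[i, j]) > tol}

    def edge_list(self) -> pd.DataFrame:
        rows = [(self.nodes[i], self.nodes[j], self.weights[i, j])
                for (i, j) in sorted(self.edge_set())]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_graph(self):
        """networkx Graph with community attributes and edge weights."""
        import networkx as nx

        G = nx.Graph()
        for lab in self.nodes:
            G.add_node(lab, community=self.communities.get(lab, ""))
        for (i, j) in sorted(self.edge_set()):
            G.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        return G


def ebic(S: np.ndarray, theta: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a precision estimate given the correlation matrix."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    ll = logdet - np.sum(S * theta)
    E = int(np.count_nonzero(np.triu(theta, 1)))
    return float(-n * ll + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def ebic_select(S: CorrelationMatrix, config: EBICConfig | None = None) -> SymptomNetwork:
    """Graphical lasso over a log-spaced penalty path, EBIC-selected.

    The path runs from ``lambda_max`` (the largest off-diagonal |S|,
    where the solution is fully sparse) down to
    ``lambda_max * lambda_min_ratio``. Ties in EBIC go to the smallest
    penalty (densest candidate). A degenerate path (``lambda_max = 0``)
    returns the empty network with a warning.
    """
    cfg = config or EBICConfig()
    cfg.validate()
    S.validate()
    mat, n, p = S.S, S.n, S.S.shape[0]
    labels = S.labels or tuple(f"V{i+1}" for i in range(p))
    communities = {lab: NODE_COMMUNITIES[lab] for lab in labels if lab in NODE_COMMUNITIES}

    lam_max = float(np.max(np.abs(mat - np.diag(np.diag(mat)))))
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; returning the empty network")
        theta = np.diag(1.0 / np.diag(mat))
        return SymptomNetwork(labels, np.zeros((p, p)), theta, 0.0, n, communities)

    lambdas = np.exp(np.linspace(np.log(lam_max), np.log(lam_max * cfg.lambda_min_ratio),
                                 cfg.n_lambda))
    rows = []
    best = None
    warm = warm_theta = None
    for lam in lambdas:
        theta = graphical_lasso(mat, lam, warm_W=warm, warm_theta=warm_theta)
        warm_theta = theta
        warm = np.linalg.inv(theta)
        score = ebic(mat, theta, n, cfg.gamma)
        E = int(np.count_nonzero(np.triu(theta, 1)))
        rows.append((lam, E, score))
        if best is None or score <= best[0]:  # <= : smallest lambda wins ties
            best = (score, lam, theta)
    path = pd.DataFrame(rows, columns=["lambda", "n_edges", "ebic"])
    _, lam_sel, theta_sel = best
    return SymptomNetwork(labels, precision_to_partial(theta_sel), theta_sel,
                          float(lam_sel), n, communities, path)


def estimate_network_stacked(stack, config: EBICConfig | None = None,
                             n_effective: int | None = None,
                             node_builder=None) -> SymptomNetwork:
    """Estimate one network from all imputed datasets stacked row-wise.

    Rows of the m completed datasets are concatenated, the polychoric
    matrix is computed on the stack, and EBIC selection runs with the
    effective sample size equal to the original number of participants
    (not N*m) — stacking reuses each participant m times and carries no
    extra information.
    """
    datasets = stack.datasets if hasattr(stack, "datasets") else list(stack)
    shapes = {d.values.shape if hasattr(d, "values") else d.shape for d in datasets}
    if len(shapes) != 1:
        raise ValueError(f"imputed datasets have inconsistent shapes: {shapes}")
    frames = [d.values if hasattr(d, "values") and isinstance(d.values, pd.DataFrame) else d
              for d in datasets]
    stacked = pd.concat(frames, axis=0, ignore_index=True)
    nodes = (node_builder or build_node_table)(stacked)
    N = n_effective if n_effective is not None else len(frames[0])
    S = polychoric_matrix(nodes, n_effective=N)
    return ebic_select(S, config)


@dataclass
class NetworkDescriptives:
    density: float
    mean_weight_all: float
    mean_weight_nonzero: float
    min_weight: float
    max_weight: float
    n_edges: int


def network_descriptives(net: SymptomNetwork) -> NetworkDescriptives:
    """Density and edge-weight summaries of a selected network.

    ``mean_weight_all`` averages over every node pair (zeros included);
    ``mean_weight_nonzero`` averages over selected edges only. Min/max
    are over nonzero edges (0 for an empty network).
    """
    p = net.p
    iu = np.triu_indices(p, 1)
    w = net.weights[iu]
    nz = w[w != 0]
    possible = p * (p - 1) // 2
    return NetworkDescriptives(
        density=len(nz) / possible if possible else 0.0,
        mean_weight_all=float(w.mean()) if possible else 0.0,
        mean_weight_nonzero=float(nz.mean()) if len(nz) else 0.0,
        min_weight=float(nz.min()) if len(nz) else 0.0,
        max_weight=float(nz.max()) if len(nz) else 0.0,
        n_edges=int(len(nz)),
    )
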