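"""Synthetic cohort generator.

Emulates the study's data structure so that every downstream stage —
imputation, diagnostic scoring, network estimation, stability — is
testable without the confidential clinical data. The generative model is
a latent Gaussian graphical model over the 13 symptom nodes: a sparse
precision matrix defines the true partial-correlation network, latent
multivariate-normal draws are discretized at per-node thresholds into
ordinal codes, and the instrument items are reconstructed from the node
values (two-item clusters are split back into their constituent items).
Items outside the network follow a single shared severity factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .data import (
    CAPS_ITEMS,
    COPISAC_ITEMS,
    DICHOTOMOUS,
    ITEM_COLUMNS,
    ITEM_RANGES,
    NODE_ITEMS,
    NODE_LABELS,
    TGI_ITEMS,
    ItemResponseMatrix,
    scale_of,
)

__all__ = [
    "TrueNetwork",
    "CohortConfig",
    "MARSpec",
    "SyntheticCohort",
    "generate_true_network",
    "sample_ordinal",
    "generate_instrument_cohort",
    "inject_missingness",
    "equiprobable_thresholds",
    "node_category_counts",
]


def equiprobable_thresholds(n_categories: int) -> np.ndarray:
    """Standard-normal cut points giving equal mass to each category."""
    return stats.norm.ppf(np.arange(1, n_categories) / n_categories)


def node_category_counts() -> dict[str, int]:
    """Number of ordinal categories per network node.

    Single TGI items have 5 categories (1-5), single CAPS/COPISAC items 5
    (0-4), and two-item cluster sums 9 (0-8).
    """
    return {lab: 9 if len(items) == 2 else 5 for lab, items in NODE_ITEMS.items()}


@dataclass
class TrueNetwork:
    """Ground-truth Gaussian graphical model over the 13 symptom nodes."""

    node_labels: tuple[str, ...]
    precision: np.ndarray
    thresholds: dict[str, np.ndarray]
    seed: int | None = None

    @property
    def p(self) -> int:
        return len(self.node_labels)

    @property
    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.precision))
        pc = -self.precision / np.outer(d, d)
        np.fill_diagonal(pc, 0.0)
        return pc

    @property
    def covariance(self) -> np.ndarray:
        """Latent covariance: inverse precision standardized to unit diagonal."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def edge_set(self, tol: float = 1e-12) -> set[tuple[int, int]]:
        pc = self.partial_correlations
        p = self.p
        return {(i, j) for i in range(p) for j in range(i + 1, p) if abs(pc[i, j]) > tol}

    def validate(self) -> None:
        K = self.precision
        if not np.allclose(K, K.T):
            raise ValueError("precision matrix is not symmetric")
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("precision matrix is not positive definite")
        for lab, t in self.thresholds.items():
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds for node {lab!r} are not strictly increasing")

    def to_json(self) -> str:
        return json.dumps({
            "node_labels": list(self.node_labels),
            "precision": self.precision.tolist(),
            "thresholds": {k: v.tolist() for k, v in self.thresholds.items()},
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, text: str) -> "TrueNetwork":
        d = json.loads(text)
        return cls(
            tuple(d["node_labels"]),
            np.asarray(d["precision"], dtype=float),
            {k: np.asarray(v, dtype=float) for k, v in d["thresholds"].items()},
            d.get("seed"),
        )


def generate_true_network(
    p: int = 13,
    density: float = 0.5,
    weight_low: float = -0.04,
    weight_high: float = 0.49,
    seed: int = 0,
    node_labels: tuple[str, ...] | None = None,
    thresholds: dict[str, np.ndarray] | None = None,
    max_shrink_steps: int = 60,
) -> TrueNetwork:
    """Draw a sparse ground-truth partial-correlation network.

    Exactly ``round(density * p(p-1)/2)`` node pairs receive a nonzero
    partial correlation drawn uniformly in ``[weight_low, weight_high]``.
    The implied precision matrix (unit diagonal, off-diagonal −weight) is
    repaired to positive definiteness by diagonal inflation — delta added
    to the diagonal, doubling from 0.01 until the smallest eigenvalue is
    at least 1e−6 — then rescaled to unit diagonal. The repair preserves
    the edge support but shrinks weight magnitudes.

    Defaults target the density-0.5 regime with weights spanning roughly
    −0.04 to 0.49 that the estimation pipeline is designed for.
    """
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if not (-1 < weight_low <= weight_high < 1):
        raise ValueError("weights must satisfy -1 < weight_low <= weight_high < 1")
    if node_labels is None:
        node_labels = NODE_LABELS if p == 13 else tuple(f"V{i+1}" for i in range(p))
    rng = substream(seed, "true-network")

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(density * len(pairs)))
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n_edges, replace=False)] if n_edges else []

    K = np.eye(p)
    for (i, j) in chosen:
        w = rng.uniform(weight_low, weight_high)
        if w == 0.0:  # keep the edge count exact
            w = (weight_high or weight_low) * 1e-6
        K[i, j] = K[j, i] = -w

    delta, step = 0.0, 0.01
    for _ in range(max_shrink_steps):
        if np.linalg.eigvalsh(K + delta * np.eye(p)).min() >= 1e-6:
            break
        delta = step
        step *= 2.0
    else:
        raise ValueError(
            f"could not repair precision to positive definite; last diagonal inflation {delta:g}"
        )
    K = K + delta * np.eye(p)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)

    if thresholds is None:
        counts = node_category_counts() if tuple(node_labels) == NODE_LABELS else {
            lab: 5 for lab in node_labels
        }
        thresholds = {lab: equiprobable_thresholds(counts[lab]) for lab in node_labels}
    net = TrueNetwork(tuple(node_labels), K, thresholds, seed=seed)
    net.validate()
    return net


def sample_ordinal(n: int, net: TrueNetwork, seed: int = 0, shifts: dict[str, float] | None = None) -> pd.DataFrame:
    """Sample n participants' ordinal node codes from the latent model.

    Latent vectors are multivariate normal with the standardized inverse
    precision as covariance; each latent value falls into the ordinal
    category whose threshold interval contains it (categories coded
    0..len(thresholds)). ``shifts`` adds per-node latent mean shifts
    (severity offsets) before discretization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    net.validate()
    rng = substream(seed, "sample-ordinal")
    cov = net.covariance
    z = rng.multivariate_normal(np.zeros(net.p), cov, size=n, method="cholesky")
    out = {}
    for k, lab in enumerate(net.node_labels):
        t = np.asarray(net.thresholds[lab])
        x = z[:, k] + (shifts or {}).get(lab, 0.0)
        out[lab] = np.searchsorted(t, x, side="left")
    return pd.DataFrame(out)


@dataclass
class MARSpec:
    """Missing-at-random mechanism: masking probability is a logistic
    function of one fully observed covariate (standardized), with the
    intercept calibrated so the average probability matches each scale's
    target rate."""

    covariate: str
    slope: float = 1.0


@dataclass
class CohortConfig:
    """Generator settings for a full instrument-level cohort.

    ``item_shifts`` are latent mean shifts (standard-normal units) applied
    to individual items before thresholding; positive shifts raise item
    severity and hence diagnostic prevalence. ``factor_loading`` is the
    loading of non-network items on one shared severity factor (0 makes
    all non-network items independent). ``months_mu``/``months_sigma``
    parameterize a log-normal months-since-loss distribution whose
    defaults match a mean of roughly 8 years with wide spread.
    """

    item_shifts: dict[str, float] = field(default_factory=dict)
    default_shift: float = 0.0
    factor_loading: float = 0.7
    months_mu: float = 4.30    # log-months; exp(mu + s^2/2) ~ 96 months
    months_sigma: float = 0.73
    bereaved_prob: float = 1.0
    trauma_prob: float = 1.0
    duration_prob: float = 1.0  # CAPS 22 duration gate satisfied


@dataclass
class SyntheticCohort:
    items: ItemResponseMatrix
    loss_metadata: pd.DataFrame
    true_network: TrueNetwork
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Single cohort table: items plus loss metadata columns."""
        return pd.concat([self.items.values, self.loss_metadata], axis=1)


def _shift_for_node(cfg: CohortConfig, items: tuple[str, ...]) -> float:
    return float(np.mean([cfg.item_shifts.get(it, cfg.default_shift) for it in items]))


def _split_sum(s: np.ndarray, rng: np.random.Generator, item_max: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Split a 0..2*item_max cluster sum into two in-range items uniformly."""
    lo = np.maximum(0, s - item_max)
    hi = np.minimum(item_max, s)
    a = lo + rng.integers(0, hi - lo + 1)
    return a, s - a


def generate_instrument_cohort(
    n: int,
    config: CohortConfig | None = None,
    seed: int = 0,
    net: TrueNetwork | None = None,
) -> SyntheticCohort:
    """Generate a complete cohort: all instrument items plus loss metadata.

    The 13 network-node variables rebuilt from the emitted items (single
    items, or the two-item cluster sums) reproduce exactly the ordinal
    codes drawn from ``net``, so the node table downstream follows the
    supplied ground-truth network. Items that are not network nodes load
    on one shared severity factor with loading ``config.factor_loading``.
    """
    cfg = config or CohortConfig()
    if net is None:
        net = generate_true_network(13, 0.5, -0.04, 0.49, seed=seed)
    if tuple(net.node_labels) != NODE_LABELS:
        raise ValueError("instrument cohorts require the 13 standard symptom nodes")
    rng = substream(seed, "cohort-items")

    shifts = {lab: _shift_for_node(cfg, items) for lab, items in NODE_ITEMS.items()}
    nodes = sample_ordinal(n, net, seed=seed, shifts=shifts)

    cols: dict[str, np.ndarray] = {}
    # network nodes -> items; cluster sums are split uniformly into two items
    for lab, items in NODE_ITEMS.items():
        v = nodes[lab].to_numpy()
        if len(items) == 1:
            lo = ITEM_RANGES[items[0]][0]
            cols[items[0]] = v + lo  # 0-based codes onto the item scale
        else:
            a, b = _split_sum(v, rng)
            cols[items[0]], cols[items[1]] = a, b

    # remaining items: shared severity factor + unique noise, equiprobable cuts
    g = rng.standard_normal(n)
    lam = cfg.factor_loading
    for col in ITEM_COLUMNS:
        if col in cols:
            continue
        if col == "CAPS_22":
            cols[col] = (rng.uniform(size=n) < cfg.duration_prob).astype(float)
            continue
        lo, hi = ITEM_RANGES[col]
        ncat = int(hi - lo) + 1
        shift = cfg.item_shifts.get(col, cfg.default_shift)
        z = shift + lam * g + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        cols[col] = np.searchsorted(equiprobable_thresholds(ncat), z) + lo

    values = pd.DataFrame({c: np.asarray(cols[c], dtype=float) for c in ITEM_COLUMNS})
    meta = pd.DataFrame({
        "MONTHS_SINCE_LOSS": np.round(rng.lognormal(cfg.months_mu, cfg.months_sigma, size=n), 1),
        "BEREAVED": (rng.uniform(size=n) < cfg.bereaved_prob).astype(float),
        "TRAUMA_A": (rng.uniform(size=n) < cfg.trauma_prob).astype(float),
    })
    items = ItemResponseMatrix(values)
    items.validate()
    return SyntheticCohort(items, meta, net, seed)


def inject_missingness(
    data: ItemResponseMatrix,
    per_scale_rates: dict[str, float],
    mechanism: str | MARSpec = "MCAR",
    seed: int = 0,
) -> ItemResponseMatrix:
    """Mask item responses scale by scale; never alters unmasked cells.

    Under MCAR every cell of a scale is masked independently with the
    scale's rate. Under MAR (a :class:`MARSpec`) the per-row masking
    probability follows a logistic curve in the named covariate, with the
    intercept calibrated so the expected rate matches the target.
    """
    for s, r in per_scale_rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"rate for scale {s!r} must lie in [0, 1]")
    out = data.copy()
    out.truth = data.values.copy()
    rng = substream(seed, "missingness")

    if isinstance(mechanism, MARSpec):
        cov = data.values[mechanism.covariate] if mechanism.covariate in data.values else None
        if cov is None:
            raise KeyError(f"MAR covariate {mechanism.covariate!r} not in data")
        if cov.isna().any():
            raise ValueError(f"MAR covariate {mechanism.covariate!r} has missing values")
        x = (cov.to_numpy() - cov.mean()) / (cov.std() or 1.0)

        def row_probs(rate: float) -> np.ndarray:
            if rate in (0.0, 1.0):
                return np.full(len(x), rate)
            from scipy.optimize import brentq
            a = brentq(lambda a0: np.mean(1 / (1 + np.exp(-(a0 + mechanism.slope * x)))) - rate, -30, 30)
            return 1 / (1 + np.exp(-(a + mechanism.slope * x)))
    else:
        if mechanism != "MCAR":
            raise ValueError("mechanism must be 'MCAR' or a MARSpec")
        row_probs = None

    for col in out.values.columns:
        rate = per_scale_rates.get(scale_of(col), 0.0)
        if rate == 0.0:
            continue
        if isinstance(mechanism, MARSpec) and col == mechanism.covariate:
            continue  # the MAR covariate must stay fully observed
        p = row_probs(rate) if row_probs is not None else rate
        mask = rng.uniform(size=out.n) < p
        out.values.loc[mask, col] = np.nan
    return out
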