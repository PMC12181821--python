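"""Network stability: bootstrapped edges, case-dropping, CS-coefficients.

Stability follows a bootstrap-then-impute scheme: participants are
resampled from the original incomplete data first, each bootstrap sample
is multiply imputed, and the full impute -> stacked-estimate pipeline is
re-run per replicate. Edge-weight uncertainty is summarized by
percentile confidence intervals. Centrality robustness uses the
case-dropping subset bootstrap: random fractions of participants are
dropped, the pipeline re-runs on the subset, and the correlation between
subset and full-sample centralities is recorded. The correlation
stability (CS) coefficient is the largest drop fraction at which at
least 95% of replicates still correlate >= 0.7 with the full sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ._rng import subseed, substream
from .data import ItemResponseMatrix
from .imputation import ImputationConfig, ImputationStack, fcs_impute
from .network import EBICConfig, SymptomNetwork, build_node_table, estimate_network_stacked

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "NetworkPipeline",
    "EdgeStabilityResult",
    "CaseDropResult",
    "bootstrap_edges",
    "case_dropping",
    "cs_coefficient",
]


@dataclass
class StabilityConfig:
    """Bootstrap settings.

    Defaults mirror a full-scale run (1000 bootstraps, 20 imputations per
    bootstrap); both knobs scale down for cheaper profiles without
    changing the algorithm.
    """

    n_boot: int = 1000
    m_per_boot: int = 20
    ci_level: float = 0.95
    cs_correlation: float = 0.7
    cs_probability: float = 0.95
    drop_min: float = 0.05
    drop_max: float = 0.75
    seed: int = 0
    max_redraws: int = 100

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0 < self.cs_correlation < 1:
            raise ValueError("cs_correlation must lie in (0, 1)")
        if not 0 <= self.drop_min <= self.drop_max < 1:
            raise ValueError("need 0 <= drop_min <= drop_max < 1")


@dataclass
class NetworkPipeline:
    """Deterministic impute -> stacked-network pipeline handle.

    ``m`` imputations are generated when the input has missing cells
    (skipped otherwise), stacked, and one EBIC-glasso network is
    estimated with effective n equal to the number of participants.
    ``node_builder`` maps an item table to the ordinal node table; the
    default collapses instrument items into the 13 symptom nodes, and an
    identity builder supports data that already is a node table.
    """

    m: int = 20
    max_iterations: int = 10
    donor_pool: int = 5
    max_predictors: int = 15
    ebic: EBICConfig = field(default_factory=EBICConfig)
    node_builder: Callable[[pd.DataFrame], pd.DataFrame] = staticmethod(build_node_table)
    communities: dict[str, str] | None = None  # override for non-standard node sets

    def impute(self, data: ItemResponseMatrix, seed: int) -> ImputationStack:
        if data.values.isna().any().any():
            cfg = ImputationConfig(m=self.m, max_iterations=self.max_iterations,
                                   donor_pool=self.donor_pool,
                                   max_predictors=self.max_predictors, seed=seed)
            return fcs_impute(data, cfg)
        cfg = ImputationConfig(m=1, seed=seed)
        return ImputationStack([data], cfg)

    def estimate(self, data: ItemResponseMatrix, seed: int) -> SymptomNetwork:
        stack = self.impute(data, seed)
        return estimate_network_stacked(stack, self.ebic, n_effective=data.n,
                                        node_builder=self.node_builder)

    def centralities(self, data: ItemResponseMatrix, seed: int) -> pd.DataFrame:
        from .centrality import centrality_table

        net = self.estimate(data, seed)
        c = centrality_table(net, communities=self.communities)
        return pd.DataFrame({"strength": c.strength, "bridge_strength": c.bridge_strength})


def _edge_series(net: SymptomNetwork) -> pd.Series:
    p = net.p
    iu = np.triu_indices(p, 1)
    labels = [f"{net.nodes[i]}--{net.nodes[j]}" for i, j in zip(*iu)]
    return pd.Series(net.weights[iu], index=labels)


@dataclass
class EdgeStabilityResult:
    replicates: pd.DataFrame      # n_boot x edges
    point: pd.Series              # full-sample edge weights
    ci_lower: pd.Series
    ci_upper: pd.Series
    n_redrawn: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"point": self.point, "ci_lower": self.ci_lower,
                             "ci_upper": self.ci_upper})


def bootstrap_edges(data: ItemResponseMatrix,
                    pipeline: "NetworkPipeline | Callable[[ItemResponseMatrix, int], pd.Series]",
                    config: StabilityConfig | None = None) -> EdgeStabilityResult:
    """Nonparametric bootstrap of edge weights with per-bootstrap imputation.

    Each replicate resamples N participants with replacement from the
    ORIGINAL incomplete data, re-runs the impute -> estimate pipeline,
    and records every edge weight. A replicate whose sample makes a node
    constant (polychoric undefined) is redrawn and counted. The CI is
    the percentile interval of the replicates.

    ``pipeline`` may also be any callable ``(data, seed) -> Series`` of
    statistics, enabling generic percentile-bootstrap use.
    """
    cfg = config or StabilityConfig()
    cfg.validate()
    if isinstance(pipeline, NetworkPipeline):
        stat = lambda d, s: _edge_series(pipeline.estimate(d, s))
    else:
        stat = pipeline
    n = data.n
    point = stat(data, subseed(cfg.seed, "boot-full"))
    rng = substream(cfg.seed, "boot-edges")
    rows, n_redrawn = [], 0
    for b in range(cfg.n_boot):
        for attempt in range(cfg.max_redraws):
            idx = rng.integers(0, n, size=n)
            sample = ItemResponseMatrix(data.values.iloc[idx].reset_index(drop=True),
                                        dict(data.ranges), data.dichotomous)
            rep_seed = subseed(cfg.seed, f"boot-{b}-{attempt}")
            try:
                rows.append(stat(sample, rep_seed))
                break
            except ValueError as e:
                n_redrawn += 1
                logger.info("bootstrap replicate %d redrawn (%s)", b, e)
        else:
            raise RuntimeError(f"bootstrap replicate {b} failed after {cfg.max_redraws} redraws")
    reps = pd.DataFrame(rows).reset_index(drop=True)
    alpha = 1.0 - cfg.ci_level
    lo = reps.quantile(alpha / 2)
    hi = reps.quantile(1 - alpha / 2)
    return EdgeStabilityResult(reps, point, lo, hi, n_redrawn)


@dataclass
class CaseDropResult:
    """Case-dropping replicate records plus the full-sample reference."""

    records: pd.DataFrame   # columns: k, boot, corr_strength, corr_bridge
    full: pd.DataFrame      # full-sample centralities
    n: int
    n_skipped: int = 0


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance centrality vector; correlation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def case_dropping(data: ItemResponseMatrix, pipeline: NetworkPipeline,
                  config: StabilityConfig | None = None) -> CaseDropResult:
    """Case-dropping subset bootstrap of strength and bridge strength.

    Each replicate drops a uniformly drawn number of participants k
    (between drop_min*N and drop_max*N), subsamples N-k without
    replacement, re-runs the impute -> estimate -> centrality pipeline,
    and records the Pearson correlations between subset and full-sample
    centrality vectors. Subsets too small to estimate (N-k < p+2) are
    skipped and logged.
    """
    cfg = config or StabilityConfig()
    cfg.validate()
    n = data.n
    full = pipeline.centralities(data, subseed(cfg.seed, "drop-full"))
    p = len(full)
    k_lo = int(np.ceil(cfg.drop_min * n))
    k_hi = int(np.floor(cfg.drop_max * n))
    if k_lo > k_hi:
        raise ValueError("drop range contains no integer drop count")
    rng = substream(cfg.seed, "case-dropping")
    rows, n_skipped = [], 0
    for b in range(cfg.n_boot):
        k = int(rng.integers(k_lo, k_hi + 1))
        if n - k < p + 2:
            n_skipped += 1
            logger.info("case-dropping replicate %d skipped: subset of %d too small", b, n - k)
            continue
        idx = rng.choice(n, size=n - k, replace=False)
        sample = ItemResponseMatrix(data.values.iloc[idx].reset_index(drop=True),
                                    dict(data.ranges), data.dichotomous)
        try:
            sub = pipeline.centralities(sample, subseed(cfg.seed, f"drop-{b}"))
        except ValueError as e:
            n_skipped += 1
            logger.info("case-dropping replicate %d skipped (%s)", b, e)
            continue
        rows.append({
            "k": k, "boot": b,
            "corr_strength": _safe_corr(sub["strength"].to_numpy(), full["strength"].to_numpy()),
            "corr_bridge": _safe_corr(sub["bridge_strength"].to_numpy(),
                                      full["bridge_strength"].to_numpy()),
        })
    return CaseDropResult(pd.DataFrame(rows), full, n, n_skipped)


def cs_coefficient(result: CaseDropResult, config: StabilityConfig | None = None,
                   metric: str = "corr_strength") -> float:
    """Correlation stability coefficient for one centrality metric.

    CS is the largest drop fraction k/N such that at EVERY evaluated
    drop level k' <= k, at least ``cs_probability`` of the replicates
    correlate >= ``cs_correlation`` with the full-sample centralities;
    0 if no level qualifies. Replicates with undefined correlations are
    excluded with a warning.
    """
    cfg = config or StabilityConfig()
    rec = result.records
    if rec.empty:
        raise ValueError("no case-dropping replicates to evaluate")
    if rec[metric].isna().any():
        warnings.warn(f"{int(rec[metric].isna().sum())} replicates with undefined "
                      f"{metric} excluded from CS")
        rec = rec.dropna(subset=[metric])
        if rec.empty:
            raise ValueError("no valid replicates after excluding undefined correlations")
    cs = 0.0
    for k in sorted(rec["k"].unique()):
        sub = rec.loc[rec["k"] == k, metric]
        if (sub >= cfg.cs_correlation).mean() >= cfg.cs_probability:
            cs = k / result.n
        else:
            break
    return float(cs)
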