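"""End-to-end pipeline orchestration and file dialects.

Ties the stages together the way the study's analysis ran: impute ->
diagnose/prevalence -> build nodes -> stacked network -> centralities ->
stability. Each stage draws from a named substream of one global seed,
every artifact lands in the output directory, and a manifest JSON
records artifacts with the seed and a configuration hash so reruns are
bitwise reproducible.

Cohort CSV dialect: one row per participant, item columns TGI_01..TGI_22,
CAPS_*, COPISAC_CO1..CO5, then MONTHS_SINCE_LOSS, BEREAVED, TRAUMA_A;
empty cells are missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import subseed
from .centrality import centrality_table
from .data import ITEM_COLUMNS, META_COLUMNS, ItemResponseMatrix
from .imputation import ImputationConfig, fcs_impute
from .network import EBICConfig, SymptomNetwork, estimate_network_stacked, network_descriptives
from .scoring import InstrumentSpec, prevalence_and_comorbidity
from .stability import NetworkPipeline, StabilityConfig, bootstrap_edges, case_dropping, cs_coefficient

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort", "write_cohort", "write_network"]

ALL_STAGES = ("impute", "diagnose", "network", "centrality", "stability")


@dataclass
class PipelineConfig:
    input_csv: str | Path = ""
    output_dir: str | Path = "results"
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    ebic: EBICConfig = field(default_factory=EBICConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            input_csv=raw.get("input_csv", ""),
            output_dir=raw.get("output_dir", "results"),
            imputation=ImputationConfig(**raw.get("imputation", {})),
            ebic=EBICConfig(**raw.get("ebic", {})),
            stability=StabilityConfig(**raw.get("stability", {})),
            instrument=InstrumentSpec(**raw.get("instrument", {})),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            seed=int(raw.get("seed", 0)),
        )


def read_cohort(path: str | Path) -> tuple[ItemResponseMatrix, pd.DataFrame]:
    """Read a cohort CSV; returns (items, metadata).

    Unknown columns are ignored with a warning; duplicate participant
    IDs (index values) and out-of-range item values raise.
    """
    df = pd.read_csv(path)
    if "participant_id" in df.columns:
        if df["participant_id"].duplicated().any():
            dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise ValueError(f"duplicate participant ID {dup!r}")
        df = df.set_index("participant_id")
    known = set(ITEM_COLUMNS) | set(META_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}")
        df = df.drop(columns=unknown)
    missing_cols = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort is missing required item columns: {missing_cols}")
    items = ItemResponseMatrix(df[list(ITEM_COLUMNS)].astype(float).reset_index(drop=True))
    items.validate()
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].astype(float).reset_index(drop=True)
    return items, meta


def write_cohort(items: ItemResponseMatrix, metadata: pd.DataFrame, path: str | Path) -> None:
    df = pd.concat([items.values, metadata], axis=1)
    df.insert(0, "participant_id", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)


def write_network(net: SymptomNetwork, stem: Path) -> list[Path]:
    """Edge list CSV, full weight-matrix CSV and GraphML for one network."""
    import networkx as nx

    paths = []
    p_edges = stem.with_suffix(".edges.csv")
    net.edge_list().to_csv(p_edges, index=False)
    paths.append(p_edges)
    p_mat = stem.with_suffix(".weights.csv")
    pd.DataFrame(net.weights, index=list(net.nodes), columns=list(net.nodes)).to_csv(p_mat)
    paths.append(p_mat)
    p_gml = stem.with_suffix(".graphml")
    nx.write_graphml(net.to_graph(), p_gml)
    paths.append(p_gml)
    if net.path is not None:
        p_path = stem.with_suffix(".ebic_path.csv")
        net.path.to_csv(p_path, index=False)
        paths.append(p_path)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages over a cohort CSV; returns the manifest.

    Stage order: impute -> diagnose -> network -> centrality ->
    stability (each toggleable via ``config.stages``). Every artifact is
    listed in ``manifest.json`` together with the global seed and the
    configuration hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "stages": list(config.stages), "artifacts": {}}

    def register(stage: str, *paths: Path) -> None:
        manifest["artifacts"].setdefault(stage, []).extend(str(p) for p in paths)

    items, meta = read_cohort(config.input_csv)

    stack = None
    stage = "impute"
    try:
        if "impute" in config.stages:
            imp_cfg = dataclasses.replace(config.imputation, seed=subseed(config.seed, "impute"))
            if items.values.isna().any().any():
                stack = fcs_impute(items, imp_cfg)
            else:
                from .imputation import ImputationStack
                stack = ImputationStack([items], imp_cfg)
            p = out / "imputations_long.csv"
            stack.to_long(items).to_csv(p, index=False)
            register("impute", p)

        if "diagnose" in config.stages:
            stage = "diagnose"
            if stack is None:
                raise RuntimeError("diagnose stage requires the impute stage")
            summary = prevalence_and_comorbidity(stack, meta, config.instrument)
            p = out / "prevalence.json"
            p.write_text(json.dumps(summary, indent=2))
            register("diagnose", p)

        net = None
        if "network" in config.stages:
            stage = "network"
            if stack is None:
                raise RuntimeError("network stage requires the impute stage")
            net = estimate_network_stacked(stack, config.ebic, n_effective=items.n)
            register("network", *write_network(net, out / "network"))
            desc = network_descriptives(net)
            p = out / "network_descriptives.json"
            p.write_text(json.dumps(dataclasses.asdict(desc), indent=2))
            register("network", p)

        if "centrality" in config.stages:
            stage = "centrality"
            if net is None:
                raise RuntimeError("centrality stage requires the network stage")
            cent = centrality_table(net)
            p = out / "centrality.csv"
            cent.to_frame().to_csv(p, index_label="node")
            register("centrality", p)

        if "stability" in config.stages:
            stage = "stability"
            stab_cfg = dataclasses.replace(config.stability, seed=subseed(config.seed, "stability"))
            pipe = NetworkPipeline(m=stab_cfg.m_per_boot,
                                   max_iterations=config.imputation.max_iterations,
                                   donor_pool=config.imputation.donor_pool,
                                   max_predictors=config.imputation.max_predictors,
                                   ebic=config.ebic)
            edges = bootstrap_edges(items, pipe, stab_cfg)
            p1 = out / "edge_bootstrap.csv"
            edges.replicates.to_csv(p1, index_label="boot")
            p2 = out / "edge_ci.csv"
            edges.summary().to_csv(p2, index_label="edge")
            drops = case_dropping(items, pipe, stab_cfg)
            p3 = out / "case_dropping.csv"
            drops.records.to_csv(p3, index=False)
            cs = {"strength": cs_coefficient(drops, stab_cfg, "corr_strength"),
                  "bridge_strength": cs_coefficient(drops, stab_cfg, "corr_bridge")}
            p4 = out / "cs_coefficients.json"
            p4.write_text(json.dumps(cs, indent=2))
            register("stability", p1, p2, p3, p4)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
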