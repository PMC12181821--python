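"""Strength and bridge-strength centrality.

Strength is the sum of the absolute weights of a node's incident edges;
bridge strength sums only the edges crossing between the two theoretical
symptom communities (PGD vs cPTSD). Absolute values are the default
convention; a signed variant is available. Z-standardized versions
(mean 0, SD 1 across nodes) are computed alongside the raw sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SymptomNetwork

__all__ = ["CentralityResult", "strength", "bridge_strength", "centrality_table"]


def _weights(net: SymptomNetwork, signed: bool) -> np.ndarray:
    return net.weights if signed else np.abs(net.weights)


def strength(net: SymptomNetwork, signed: bool = False) -> pd.Series:
    """Per-node sum of (absolute) incident edge weights."""
    w = _weights(net, signed)
    return pd.Series(w.sum(axis=1), index=list(net.nodes), name="strength")


def bridge_strength(net: SymptomNetwork, communities: dict[str, str] | None = None,
                    signed: bool = False) -> pd.Series:
    """Per-node sum of (absolute) edge weights crossing communities."""
    comm = communities if communities is not None else net.communities
    missing = [lab for lab in net.nodes if lab not in comm]
    if missing:
        raise ValueError(f"nodes without a community assignment: {missing}")
    labels = np.array([comm[lab] for lab in net.nodes])
    if len(set(labels)) > 2:
        raise ValueError("bridge strength is defined for exactly two communities")
    cross = labels[:, None] != labels[None, :]
    w = _weights(net, signed) * cross
    return pd.Series(w.sum(axis=1), index=list(net.nodes), name="bridge_strength")


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0


@dataclass
class CentralityResult:
    strength: pd.Series
    bridge_strength: pd.Series
    z_strength: pd.Series
    z_bridge: pd.Series
    communities: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "community": pd.Series(self.communities),
            "strength": self.strength,
            "bridge_strength": self.bridge_strength,
            "z_strength": self.z_strength,
            "z_bridge": self.z_bridge,
        }).loc[self.strength.index]


def centrality_table(net: SymptomNetwork, communities: dict[str, str] | None = None,
                     signed: bool = False) -> CentralityResult:
    """Raw and z-standardized strength and bridge strength for a network."""
    s = strength(net, signed)
    b = bridge_strength(net, communities, signed)
    comm = communities if communities is not None else net.communities
    return CentralityResult(s, b, _zscore(s), _zscore(b), dict(comm))
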