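"""Strength and bridge-strength centrality of the estimated network.

Reads the network weight matrix written by the previous step and
reports, for the PGD vs cPTSD community split, each node's strength
(sum of absolute incident edge weights) and bridge strength (sum over
cross-community edges), raw and z-standardized. Writes centrality.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from griefnet.centrality import centrality_table
from griefnet.data import NODE_COMMUNITIES
from griefnet.network import SymptomNetwork


def main(seed: int = 0, out: str = "results") -> None:
    out_dir = Path(out)
    w = pd.read_csv(out_dir / "network.weights.csv", index_col=0)
    nodes = tuple(w.columns)
    net = SymptomNetwork(nodes, w.to_numpy(), np.eye(len(nodes)), 0.0, 0,
                         communities={n: NODE_COMMUNITIES[n] for n in nodes})
    cent = centrality_table(net)
    frame = cent.to_frame()
    frame.to_csv(out_dir / "centrality.csv", index_label="node")

    if frame["strength"].max() > 0:
        top = frame["strength"].idxmax()
        top_bridge = frame["bridge_strength"].idxmax()
        print(f"most central symptom: {top} (strength {frame.loc[top,'strength']:.2f}); "
              f"strongest bridge: {top_bridge} "
              f"(bridge strength {frame.loc[top_bridge,'bridge_strength']:.2f})")
    else:
        print("selected network is empty; all centralities are zero")
    print(f"wrote {out_dir/'centrality.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    a = ap.parse_args()
    main(a.seed, a.out)
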