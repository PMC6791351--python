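"""Plain-text I/O for traits, sampling status and regime paintings.

Traits and liabilities: 2-column TSV (tip_label, value).
Sampling status: 2-column TSV (tip_label, status) with status in {0, 1}.
Regimes: 3-column TSV (node, node_type, state); tips are identified by label,
internal nodes by their deterministic integer id (see ``phylo.Tree``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import RegimePainting

__all__ = [
    "read_trait_tsv", "write_trait_tsv",
    "read_status_tsv", "write_status_tsv",
    "read_regimes_tsv", "write_regimes_tsv",
]


def read_trait_tsv(path):
    df = pd.read_csv(path, sep="\t", header=None, names=["tip_label", "value"],
                     dtype={"tip_label": str})
    return pd.Series(df["value"].to_numpy(float), index=df["tip_label"], name="trait")


def write_trait_tsv(trait, path):
    pd.DataFrame({"tip_label": trait.index, "value": trait.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False)


def read_status_tsv(path):
    df = pd.read_csv(path, sep="\t", header=None, names=["tip_label", "status"],
                     dtype={"tip_label": str})
    s = pd.Series(df["status"].to_numpy(np.int8), index=df["tip_label"], name="status")
    if not s.isin([0, 1]).all():
        raise ValueError("status values must be 0 or 1")
    return s


def write_status_tsv(status, path):
    pd.DataFrame({"tip_label": status.index, "status": status.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False)


def write_regimes_tsv(tree, painting, path):
    rows = []
    for node in range(tree.n_nodes):
        if tree.is_tip(node):
            rows.append((tree.tip_labels[node], "tip", int(painting.state[node])))
        else:
            rows.append((str(node), "internal", int(painting.state[node])))
    pd.DataFrame(rows, columns=["node", "node_type", "state"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_regimes_tsv(tree, path):
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["node", "node_type", "state"], dtype={"node": str})
    state = np.full(tree.n_nodes, -1, dtype=np.int8)
    for _, row in df.iterrows():
        if row["node_type"] == "tip":
            state[tree.tip_id(row["node"])] = row["state"]
        else:
            state[int(row["node"])] = row["state"]
    if (state < 0).any():
        missing = int((state < 0).sum())
        raise ValueError(f"regime file does not cover {missing} node(s)")
    return RegimePainting(state)
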