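"""Fritz-Purvis D: phylogenetic signal of a binary tip character.

The observed sum of sister-clade differences d_obs is rescaled between two
null expectations estimated by simulation: d_r, the mean under random
permutation of tip states (D = 1), and d_b, the mean under a Brownian
liability thresholded to the observed prevalence (D = 0):

    D = (d_obs - d_b) / (d_r - d_b)

Nodal values are estimated rootward as the unweighted mean of the two child
values (branch lengths play no role in the sum); d is the sum of
|parent - child| over all edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import _simulate_bm_tip_matrix

__all__ = ["DResult", "sister_clade_difference_sum", "d_statistic"]


@dataclass(frozen=True)
class DResult:
    D: float
    d_obs: float
    d_rand: float   # mean permutation-null sum
    d_brownian: float  # mean Brownian-threshold-null sum
    n_null: int


def _d_sums(tree, tip_values):
    """Sister-clade difference sums for each column of (n_tips, B) values."""
    vals = np.empty((tree.n_nodes, tip_values.shape[1]))
    vals[: tree.n_tips] = tip_values
    for v in tree.postorder:
        ch = tree.children[v]
        if len(ch) == 2:
            np.add(vals[ch[0]], vals[ch[1]], out=vals[v])
            vals[v] *= 0.5
        elif len(ch) == 1:  # unary root from pruning
            vals[v] = vals[ch[0]]
    nonroot = np.delete(np.arange(tree.n_nodes), tree.root)
    return np.abs(vals[tree.parent[nonroot]] - vals[nonroot]).sum(axis=0)


def _tip_state_array(tree, states):
    if isinstance(states, pd.Series):
        arr = states.reindex(tree.tip_labels).to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("states do not cover every tip")
    else:
        arr = np.asarray(states, dtype=float)
        if arr.shape != (tree.n_tips,):
            raise ValueError("states must cover exactly the tree's tips")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("states must be binary 0/1")
    if arr.min() == arr.max():
        raise ValueError("monomorphic states: D is undefined")
    return arr


def sister_clade_difference_sum(tree, states):
    """The raw d value for one binary character (both states required)."""
    arr = _tip_state_array(tree, states)
    return float(_d_sums(tree, arr[:, None])[0])


def d_statistic(tree, status, n_null=1000, seed=None):
    """D of a binary sampling status, with simulated nulls.

    Permutation null: tip states shuffled across tips.  Brownian null: a
    unit-rate Brownian liability simulated on the tree and thresholded at its
    own order statistic so each null replicate matches the observed number of
    0s exactly.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = np.random.default_rng(seed)
    arr = _tip_state_array(tree, status)
    n = tree.n_tips
    d_obs = float(_d_sums(tree, arr[:, None])[0])

    # permutation null
    perm = np.repeat(arr[None, :], n_null, axis=0)
    perm = rng.permuted(perm, axis=1)
    d_rand = float(_d_sums(tree, perm.T).mean())

    # Brownian-threshold null at matched prevalence: each simulated liability
    # is cut at its own k-th order statistic, so every null replicate has
    # exactly the observed number of 0s
    k_missing = int(np.sum(arr == 0))
    liab = _simulate_bm_tip_matrix(tree, sigma2=1.0, root_value=0.0,
                                   size=n_null, rng=rng).T.copy()  # (B, n)
    kth = np.partition(liab, k_missing - 1, axis=1)[:, k_missing - 1]
    thresh = (liab > kth[:, None]).astype(float)
    d_brown = float(_d_sums(tree, thresh.T).mean())

    denom = d_rand - d_brown
    if abs(denom) < 1e-12:
        raise ValueError("degenerate nulls: d_rand == d_brownian")
    return DResult(D=(d_obs - d_brown) / denom, d_obs=d_obs, d_rand=d_rand,
                   d_brownian=d_brown, n_null=n_null)
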