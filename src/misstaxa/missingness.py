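"""Sampling-status trait ``S`` under the three missing-taxa schemes.

``S`` is a 0/1 value per tip (0 = missing, 1 = sampled), represented as a
pandas Series indexed by tip label.

* **random** (rMT): each tip is missing independently with probability p, so
  the realized missing count is Binomial(n, p) and fluctuates around p*n.
* **clumped** (cluMT): a Brownian liability is thresholded; exactly
  round(p*n) tips — those with the lowest liabilities — are missing, which
  makes missingness phylogenetically clumped.
* **correlated** (corMT): exactly round(p*n) tips are drawn without
  replacement with probability proportional to the weight
  w_i = t_i/sum(T) - min(T)/sum(T), so higher-trait tips are more likely to
  be missing and the minimum-trait tip (weight 0) is always sampled.

``round`` is Python's round-half-to-even throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylo import prune_tips

__all__ = [
    "sample_missing_random",
    "sample_missing_clumped",
    "correlated_weights",
    "sample_missing_correlated",
    "apply_missingness",
]


def _rng(seed):
    return np.random.default_rng(seed)


def _status_series(labels, missing_mask):
    return pd.Series(np.where(missing_mask, 0, 1).astype(np.int8),
                     index=list(labels), name="status")


def sample_missing_random(tips, p, seed=None):
    """Each tip independently missing with probability p (Bernoulli)."""
    if not 0 <= p < 1:
        raise ValueError("p must be in [0, 1)")
    tips = list(tips)
    rng = _rng(seed)
    return _status_series(tips, rng.random(len(tips)) < p)


def sample_missing_clumped(liability, p):
    """Exactly round(p*n) tips missing: those with the lowest liabilities.

    Deterministic given the liability; ties broken by tip-label order.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    labels = np.asarray(liability.index)
    values = liability.to_numpy(dtype=float)
    n = len(labels)
    k = round(p * n)
    if n - k < 2:
        raise ValueError("clumped missingness would leave fewer than 2 tips")
    order = np.lexsort((labels, values))  # by liability, then label
    missing = np.zeros(n, dtype=bool)
    missing[order[:k]] = True
    return _status_series(labels, missing)


def correlated_weights(trait):
    """Sampling-for-removal weights w = t/sum(T) - min(T)/sum(T).

    The minimum-trait tip gets weight exactly 0 (it is never removed);
    weights are non-negative whenever trait values are, and increase
    linearly with the trait.
    """
    values = trait.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 tips")
    total = values.sum()
    if total == 0:
        raise ValueError("trait values sum to 0; weights undefined")
    w = values / total - values.min() / total
    if np.all(w == 0):
        raise ValueError("all trait values equal; removal weights are all 0")
    return pd.Series(w, index=trait.index, name="weight")


def sample_missing_correlated(trait, p, seed=None):
    """Exactly round(p*n) tips missing, drawn proportionally to the weights.

    Sequential weighted sampling without replacement (weights renormalized
    after each draw), realized through the exponential-keys equivalence:
    draws Exp(1)/w_i per tip and removes the k smallest keys, which has the
    same distribution as the sequential procedure.  Zero-weight tips are
    never missing.
    """
    if not 0 <= p < 1:
        raise ValueError("p must be in [0, 1)")
    n = len(trait)
    k = round(p * n)
    if k == 0:
        return _status_series(trait.index, np.zeros(n, dtype=bool))
    w = correlated_weights(trait).to_numpy()
    if k > int((w > 0).sum()):
        raise ValueError(
            f"cannot remove {k} tips: only {int((w > 0).sum())} have positive weight"
        )
    rng = _rng(seed)
    with np.errstate(divide="ignore"):
        keys = np.where(w > 0, rng.exponential(size=n) / w, np.inf)
    missing = np.zeros(n, dtype=bool)
    missing[np.argpartition(keys, k - 1)[:k]] = True
    return _status_series(trait.index, missing)


def apply_missingness(tree, trait, status, return_map=False):
    """Prune status-0 tips from the tree and restrict the trait to the rest."""
    if set(status.index) != set(tree.tip_labels):
        raise ValueError("status labels do not match the tree's tips")
    drop = set(status.index[status == 0])
    if not drop:
        return (tree, trait, None) if return_map else (tree, trait)
    if return_map:
        pruned, node_map = prune_tips(tree, drop, return_map=True)
    else:
        pruned = prune_tips(tree, drop)
    kept_trait = trait.loc[pruned.tip_labels] if trait is not None else None
    if return_map:
        return pruned, kept_trait, node_map
    return pruned, kept_trait
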