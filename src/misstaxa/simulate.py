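"""Generative machinery of the study.

Everything the sensitivity analysis consumes is simulated here:

* pure-birth (Yule) trees conditioned on a tip count, rescaled to unit height;
* a binary selective-regime character ``R`` under an equal-rates Mk model;
* the continuous trait of interest ``T`` under BM, BMS, OU or OUM, using the
  exact Gaussian transition along each edge;
* a Brownian liability ``L`` that underlies the threshold model for
  phylogenetically clumped missingness.

Edges carry the regime of their rootward (parent) node, constant along the
whole edge; within-edge character changes are not simulated.  The same
convention is used by the fitting module, so simulator and fitter are mutually
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Tree, _Node, rescale_to_unit_height

__all__ = [
    "ModelSpec",
    "RegimePainting",
    "MODELS",
    "STUDY_DEFAULTS",
    "initial_tree_size",
    "simulate_yule_tree",
    "simulate_mk_regimes",
    "regime_balance_ok",
    "simulate_trait",
    "simulate_liability",
]

MODELS = ("BM", "BMS", "OU", "OUM")

#: study-condition parameter values (trait units / per unit tree height)
STUDY_DEFAULTS = {
    "sigma2_root": 0.5,
    "sigma2_derived": 1.0,
    "theta_root": 10.0,
    "theta_derived": 11.0,
    "alpha": 1.5,
    "mk_rate": 0.5,
    "liability_sigma2": 1.0,
    "n_target": 300,
    "balance_window": (0.25, 0.45),
}


def _rng(seed):
    """int, SeedSequence, Generator or None -> Generator."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one trait-evolution model.

    ``sigma2_*`` are variances per unit time, ``theta_*`` trait units,
    ``alpha`` per unit time.  ``root_value`` is the trait value at the root;
    if ``None`` it resolves to ``theta_root`` for OU/OUM and 10 for BM/BMS
    (any constant shift leaves BM/BMS inference invariant).
    """

    model: str
    sigma2_root: float = 0.5
    sigma2_derived: float | None = None
    theta_root: float = 10.0
    theta_derived: float | None = None
    alpha: float | None = None
    root_value: float | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.sigma2_root <= 0:
            raise ValueError("sigma2_root must be > 0")
        if self.model == "BMS" and (self.sigma2_derived is None or self.sigma2_derived <= 0):
            raise ValueError("BMS requires sigma2_derived > 0")
        if self.model in ("OU", "OUM") and (self.alpha is None or self.alpha <= 0):
            raise ValueError(f"{self.model} requires alpha > 0")
        if self.model in ("BM", "BMS") and self.alpha is not None:
            raise ValueError("alpha is not a BM/BMS parameter")
        if self.model == "OUM" and self.theta_derived is None:
            raise ValueError("OUM requires theta_derived")

    @classmethod
    def study_default(cls, model):
        """The study conditions for one generating model."""
        d = STUDY_DEFAULTS
        if model == "BM":
            return cls("BM", sigma2_root=d["sigma2_root"])
        if model == "BMS":
            return cls("BMS", sigma2_root=d["sigma2_root"], sigma2_derived=d["sigma2_derived"])
        if model == "OU":
            return cls("OU", sigma2_root=d["sigma2_root"], theta_root=d["theta_root"],
                       alpha=d["alpha"])
        if model == "OUM":
            return cls("OUM", sigma2_root=d["sigma2_root"], theta_root=d["theta_root"],
                       theta_derived=d["theta_derived"], alpha=d["alpha"])
        raise ValueError(f"unknown model {model!r}")

    @property
    def resolved_root_value(self):
        if self.root_value is not None:
            return self.root_value
        return self.theta_root if self.model in ("OU", "OUM") else 10.0

    def true_params(self):
        """Generating values keyed like fitted-parameter names."""
        p = {"sigma2_0": self.sigma2_root}
        if self.model == "BMS":
            p["sigma2_1"] = self.sigma2_derived
        if self.model in ("OU", "OUM"):
            p["theta_0"] = self.theta_root
            p["alpha"] = self.alpha
        if self.model == "OUM":
            p["theta_1"] = self.theta_derived
        return p


@dataclass(frozen=True)
class RegimePainting:
    """Binary regime state per node; an edge carries its parent node's state."""

    state: np.ndarray  # (n_nodes,) int8 in {0, 1}

    def __post_init__(self):
        s = np.asarray(self.state, dtype=np.int8)
        if s.ndim != 1 or not np.isin(s, (0, 1)).all():
            raise ValueError("regime states must be a 1-D 0/1 array")
        object.__setattr__(self, "state", s)

    def edge_regimes(self, tree):
        """Regime of the edge above each node (root entry is its own state)."""
        reg = self.state[tree.parent]
        reg[tree.root] = self.state[tree.root]
        return reg

    def tip_states(self, tree):
        return pd.Series(self.state[: tree.n_tips], index=tree.tip_labels, name="regime")

    def restrict(self, node_map):
        """Painting for a pruned tree via its new-id -> old-id map."""
        return RegimePainting(self.state[node_map])


# ----------------------------------------------------------------- tree sizes


def initial_tree_size(p_missing, n_target=300):
    """Tips to simulate so that ``n_target`` remain after dropping a fraction.

    round(n_target / (1 - p)); e.g. 333 at 10%, 600 at 50%, 3000 at 90%.
    """
    if not 0 <= p_missing < 1:
        raise ValueError("p_missing must be in [0, 1)")
    return round(n_target / (1.0 - p_missing))


# ----------------------------------------------------------------- Yule trees


def simulate_yule_tree(n_tips, seed=None, birth_rate=1.0):
    """Pure-birth tree with exactly ``n_tips`` tips, rescaled to unit height.

    Lineages split at exponential waiting times (total rate k*lambda, the
    splitting lineage uniform); after the n-th speciation one further
    exponential epoch is drawn so that pendant edges have positive length.
    The height artifact of the stopping rule is irrelevant: the tree is
    rescaled to unit height before return.
    """
    if n_tips < 2:
        raise ValueError("a pure-birth tree needs at least 2 tips")
    rng = _rng(seed)
    width = len(str(n_tips))

    root = _Node()
    start = {id(root): 0.0}
    active = [root]
    t = 0.0
    k = 1
    # the root itself splits immediately at time 0 (rooted at first speciation)
    while k < n_tips:
        node = active.pop(rng.integers(len(active)))
        node.length = t - start[id(node)]
        for _ in range(2):
            child = _Node()
            start[id(child)] = t
            node.children.append(child)
            active.append(child)
        k += 1
        t += rng.exponential(1.0 / (k * birth_rate))
    for i, node in enumerate(active):
        node.length = t - start[id(node)]
        node.label = f"t{i + 1:0{width}d}"

    return rescale_to_unit_height(Tree._from_node(root))


# ----------------------------------------------------------------- Mk regimes


def simulate_mk_regimes(tree, q=0.5, seed=None):
    """Binary regime character under the equal-rates Mk model.

    Root state uniform on {0, 1} (the stationary distribution); along a
    branch of length t the child differs from the parent with probability
    (1 - exp(-2 q t)) / 2.
    """
    if q < 0:
        raise ValueError("transition rate q must be >= 0")
    rng = _rng(seed)
    state = np.zeros(tree.n_nodes, dtype=np.int8)
    order = tree.postorder[::-1]
    state[order[0]] = rng.integers(2)
    for v in order[1:]:
        p_change = 0.5 * (1.0 - math.exp(-2.0 * q * tree.blen[v]))
        s = state[tree.parent[v]]
        state[v] = s ^ 1 if rng.random() < p_change else s
    return RegimePainting(state)


def regime_balance_ok(tree, painting, retained_tips=None,
                      window=STUDY_DEFAULTS["balance_window"]):
    """True iff the minority regime holds a share of retained tips in window.

    The study keeps only simulations where the minority regime covers 25-45%
    of the tips remaining *after* dropping missing taxa.
    """
    if retained_tips is None:
        ids = np.arange(tree.n_tips)
    else:
        ids = np.array([tree.tip_id(t) for t in retained_tips], dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("retained tip set must be non-empty")
    share1 = painting.state[ids].mean()
    minority = min(share1, 1.0 - share1)
    lo, hi = window
    return bool(lo <= minority <= hi)


# ------------------------------------------------------------------- traits


def _simulate_trait_matrix(tree, painting, spec, size, rng):
    """(n_tips, size) draws of tip traits; exact Gaussian edge transitions."""
    state = painting.state if painting is not None else np.zeros(tree.n_nodes, np.int8)
    vals = np.empty((tree.n_nodes, size))
    order = tree.postorder[::-1]
    vals[order[0]] = spec.resolved_root_value
    is_ou = spec.model in ("OU", "OUM")
    for v in order[1:]:
        t = tree.blen[v]
        r = state[tree.parent[v]]
        parent_vals = vals[tree.parent[v]]
        if is_ou:
            a = spec.alpha
            theta = (spec.theta_derived
                     if (spec.model == "OUM" and r == 1) else spec.theta_root)
            e = math.exp(-a * t)
            var = spec.sigma2_root / (2.0 * a) * (1.0 - math.exp(-2.0 * a * t))
            mean = theta + (parent_vals - theta) * e
        else:
            s2 = (spec.sigma2_derived
                  if (spec.model == "BMS" and r == 1) else spec.sigma2_root)
            var = s2 * t
            mean = parent_vals
        if var > 0:
            vals[v] = mean + rng.standard_normal(size) * math.sqrt(var)
        else:
            vals[v] = mean
    return vals[: tree.n_tips]


def simulate_trait(tree, painting, spec, seed=None):
    """One draw of the continuous trait ``T`` at the tips.

    Pre-order recursion from ``spec.resolved_root_value``; along an edge of
    length t in regime r the child is Normal(parent, sigma2_r * t) under
    BM/BMS and Normal(theta_r + (parent - theta_r) e^{-alpha t},
    sigma2/(2 alpha) (1 - e^{-2 alpha t})) under OU/OUM.
    """
    if spec.model in ("BMS", "OUM") and painting is None:
        raise ValueError(f"{spec.model} simulation requires a regime painting")
    rng = _rng(seed)
    vals = _simulate_trait_matrix(tree, painting, spec, 1, rng)[:, 0]
    return pd.Series(vals, index=tree.tip_labels, name="trait")


def simulate_liability(tree, sigma2=STUDY_DEFAULTS["liability_sigma2"], seed=None):
    """Brownian liability ``L`` (root 0) underlying the threshold model."""
    spec = ModelSpec("BM", sigma2_root=sigma2, root_value=0.0)
    rng = _rng(seed)
    vals = _simulate_trait_matrix(tree, None, spec, 1, rng)[:, 0]
    return pd.Series(vals, index=tree.tip_labels, name="liability")


def _simulate_bm_tip_matrix(tree, sigma2, root_value, size, rng):
    """Vectorized BM tip draws, used by the D-statistic Brownian null."""
    spec = ModelSpec("BM", sigma2_root=sigma2, root_value=root_value)
    return _simulate_trait_matrix(tree, None, spec, size, rng)
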