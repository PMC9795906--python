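"""Equal-rates k-state Markov model over areas: pruning likelihood with
polymorphic/missing tips, 1-D maximum-likelihood rate fit, and marginal
ancestral-state reconstruction.

The rate matrix has all off-diagonals equal to ``q`` and diagonal
``-(k-1) q``; its transition probabilities have the closed form

    P_ii(t) = 1/k + ((k-1)/k) exp(-k q t)
    P_ij(t) = 1/k - (1/k)  exp(-k q t),   i != j.

Tip observations are area sets: a set enters the pruning algorithm as an
indicator vector (all ones when the set is empty, i.e. missing), so
polymorphic tips are integrated over, not treated as an extra state.
Likelihoods are computed with per-node scaling factors, safe for
thousands of tips.  The root is weighted uniformly (1/k), which equals the
stationary distribution of the equal-rates chain; a likelihood-proportional
(FitzJohn) weighting is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from areaevo.io_core import TimeTree

__all__ = [
    "AreaModel",
    "FitReport",
    "transition_prob",
    "prune_loglik",
    "fit_rate",
    "marginal_ancestral",
]


@dataclass(frozen=True)
class AreaModel:
    """The one-parameter equal-rates model over ``k`` areas."""

    k: int
    q: float

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.q <= 0:
            raise ValueError("q must be > 0")

    def rate_matrix(self) -> np.ndarray:
        Q = np.full((self.k, self.k), self.q)
        np.fill_diagonal(Q, -(self.k - 1) * self.q)
        return Q


def transition_prob(q: float, k: int, t: float) -> np.ndarray:
    """Closed-form k x k transition probability matrix of the equal-rates chain."""
    if t < 0:
        raise ValueError("t must be >= 0")
    e = math.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


class _TreeIndex:
    """Flat postorder arrays for fast repeated pruning passes."""

    def __init__(self, tree: TimeTree):
        nodes = list(tree.postorder())
        self.names = [nd.name for nd in nodes]
        self.index = {nd.name: i for i, nd in enumerate(nodes)}
        self.parent = np.array(
            [self.index[nd.parent.name] if nd.parent else -1 for nd in nodes]
        )
        self.length = np.array([nd.length for nd in nodes])
        self.is_tip = np.array([nd.is_tip for nd in nodes])
        self.children: list[list[int]] = [
            [self.index[c.name] for c in nd.children] for nd in nodes
        ]
        self.root = self.index[tree.root.name]
        self.n = len(nodes)


def _tip_vector(area_set, k: int) -> np.ndarray:
    if not area_set:
        return np.ones(k)
    v = np.zeros(k)
    for s in area_set:
        if not 0 <= s < k:
            raise ValueError(f"area state {s} outside 0..{k - 1}")
        v[s] = 1.0
    return v


def _message(partial: np.ndarray, q: float, k: int, t: float) -> np.ndarray:
    """P(t) @ partial via the closed form, O(k)."""
    s = partial.sum()
    e = math.exp(-k * q * t)
    return s / k + e * (partial - s / k)


def _up_pass(
    idx: _TreeIndex, tips: Mapping[str, frozenset], q: float, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled up partials per node and per-node cumulative log scaling factors."""
    partial = np.empty((idx.n, k))
    logscale = np.zeros(idx.n)
    for i in range(idx.n):
        if idx.is_tip[i]:
            name = idx.names[i]
            if name not in tips:
                raise KeyError(f"tip {name!r} absent from the area assignment table")
            partial[i] = _tip_vector(tips[name], k)
            continue
        v = np.ones(k)
        ls = 0.0
        for c in idx.children[i]:
            v = v * _message(partial[c], q, k, idx.length[c])
            ls += logscale[c]
        mx = v.max()
        if mx <= 0:
            raise FloatingPointError("zero partial likelihood (impossible data?)")
        partial[i] = v / mx
        logscale[i] = ls + math.log(mx)
    return partial, logscale


def prune_loglik(
    tree: TimeTree,
    tips: Mapping[str, frozenset],
    model: AreaModel,
    root_prior: str = "uniform",
    _index: Optional[_TreeIndex] = None,
) -> float:
    """Felsenstein-pruning log-likelihood with ambiguous/missing tips.

    ``tips`` maps every tip label to a set of observed area indices (empty =
    missing).  ``root_prior`` is ``'uniform'`` (default; equals the model's
    stationary distribution) or ``'fitzjohn'`` (likelihood-proportional).
    """
    idx = _index if _index is not None else _TreeIndex(tree)
    partial, logscale = _up_pass(idx, tips, model.q, model.k)
    root_partial = partial[idx.root]
    if root_prior == "uniform":
        lik = root_partial.sum() / model.k
    elif root_prior == "fitzjohn":
        s = root_partial.sum()
        lik = (root_partial * (root_partial / s)).sum()
    else:
        raise ValueError(f"unknown root_prior {root_prior!r}")
    return math.log(lik) + logscale[idx.root]


@dataclass
class FitReport:
    q_hat: float
    loglik: float
    converged: bool
    at_bound: bool
    n_evaluations: int
    message: str


def fit_rate(
    tree: TimeTree,
    tips: Mapping[str, frozenset],
    k: Optional[int] = None,
    bounds: tuple[float, float] = (1e-8, 1e3),
    root_prior: str = "uniform",
    xatol: float = 1e-8,
) -> FitReport:
    """Maximize the pruning likelihood over the single rate ``q``.

    Bounded 1-D optimization on log10(q); tolerance 1e-8 on q itself.
    An optimum at a bound is flagged, not an error.
    """
    observed = [s for s in (tips.get(t, frozenset()) for t in tree.tip_labels) if s]
    if not observed:
        raise ValueError("all tips missing: rate is not identifiable")
    distinct = {frozenset(s) for s in observed}
    if len(distinct) < 2 and all(len(s) == 1 for s in distinct):
        import logging

        logging.getLogger(__name__).warning(
            "all observed tips share one state; q_hat will sit at the lower bound"
        )
    idx = _TreeIndex(tree)
    if k is None:
        k = max(max((max(s) for s in observed if s), default=0) + 1, 2)

    def neg(log10_q: float) -> float:
        model = AreaModel(k=k, q=10.0**log10_q)
        return -prune_loglik(tree, tips, model, root_prior=root_prior, _index=idx)

    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    q_hat = float(10.0**res.x)
    # polish on the natural scale to meet the absolute tolerance on q
    res2 = minimize_scalar(
        lambda q: -prune_loglik(tree, tips, AreaModel(k=k, q=q), root_prior=root_prior, _index=idx),
        bounds=(max(bounds[0], q_hat / 4), min(bounds[1], q_hat * 4)),
        method="bounded",
        options={"xatol": xatol},
    )
    if -res2.fun >= -res.fun:
        q_hat, fun = float(res2.x), res2.fun
    else:
        fun = res.fun
    at_bound = q_hat <= bounds[0] * 1.5 or q_hat >= bounds[1] / 1.5
    return FitReport(
        q_hat=q_hat,
        loglik=-float(fun),
        converged=bool(res.success and res2.success),
        at_bound=at_bound,
        n_evaluations=int(res.nfev + res2.nfev),
        message=("optimum at a bound" if at_bound else "ok"),
    )


def marginal_ancestral(
    tree: TimeTree,
    tips: Mapping[str, frozenset],
    model: AreaModel,
    root_prior: str = "uniform",
) -> dict[str, np.ndarray]:
    """Marginal posterior state probabilities for every node (tips included).

    Up-down algorithm with the chosen root weighting; each returned vector is
    normalized to sum to 1.
    """
    idx = _TreeIndex(tree)
    q, k = model.q, model.k
    partial, _ = _up_pass(idx, tips, q, k)
    down = np.empty((idx.n, k))
    if root_prior == "uniform":
        down[idx.root] = np.full(k, 1.0 / k)
    elif root_prior == "fitzjohn":
        rp = partial[idx.root]
        down[idx.root] = rp / rp.sum()
    else:
        raise ValueError(f"unknown root_prior {root_prior!r}")

    # preorder = reversed postorder
    for i in range(idx.n - 1, -1, -1):
        children = idx.children[i]
        if not children:
            continue
        msgs = [_message(partial[c], q, k, idx.length[c]) for c in children]
        # leave-one-out products via prefix/suffix
        nc = len(children)
        prefix = [None] * (nc + 1)
        prefix[0] = np.ones(k)
        for j in range(nc):
            prefix[j + 1] = prefix[j] * msgs[j]
        suffix = [None] * (nc + 1)
        suffix[nc] = np.ones(k)
        for j in range(nc - 1, -1, -1):
            suffix[j] = suffix[j + 1] * msgs[j]
        for j, c in enumerate(children):
            above = down[i] * prefix[j] * suffix[j + 1]
            # equal-rates P is symmetric, so the down message reuses _message
            d = _message(above, q, k, idx.length[c])
            mx = d.max()
            down[c] = d / mx if mx > 0 else d
    marginals: dict[str, np.ndarray] = {}
    for i in range(idx.n):
        v = partial[i] * down[i]
        marginals[idx.names[i]] = v / v.sum()
    return marginals
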