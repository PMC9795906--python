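"""Stochastic character mapping of area histories and dispersal summaries.

A map is sampled in two stages: joint node states root-to-tips from the
conditional distribution given tip data (reusing the pruning partials), then
each branch's internal history from the equal-rates chain conditioned on its
endpoint states, by uniformization with dominating rate ``k q``.  For the
equal-rates chain the uniformized jump matrix is uniform (every entry 1/k),
which makes conditioned path sampling exact and cheap.

Summaries: pairwise dispersal counts (mean, median, 2.5/97.5% quantiles with
linear interpolation between order statistics), time-windowed immigration and
emigration per area, and network filtering by quantile range excluding zero.
Events are dated by the age at which the new state begins; events exactly on
a window boundary go to the older window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from areaevo.io_core import TimeTree
from areaevo.mk_model import AreaModel, _message, _TreeIndex, _up_pass

__all__ = [
    "StochasticMap",
    "DispersalSummary",
    "sample_maps",
    "count_dispersals",
    "filter_network",
    "dispersal_time_windows",
    "window_edges",
    "window_index",
    "maps_to_table",
    "table_to_maps",
]


@dataclass
class StochasticMap:
    """One sampled piecewise-constant area history over every branch.

    ``pieces[branch_id]`` lists ``(state, older_age, younger_age)`` ordered
    older to younger; adjacent pieces differ in state, and the first state of
    a child branch equals the last state of its parent branch.
    """

    pieces: dict[str, list[tuple[int, float, float]]]
    node_states: dict[str, int]
    map_id: int = 0
    rng_seed: Optional[int] = None

    def n_events(self) -> int:
        return sum(len(ps) - 1 for ps in self.pieces.values())

    def validate(self, tree: TimeTree, tol: float = 1e-9) -> None:
        ages = tree.ages()
        scale = max(tree.root_age, 1.0)
        for nd in tree.preorder():
            if nd is tree.root:
                continue
            ps = self.pieces[nd.name]
            older, younger = ages[nd.parent.name], ages[nd.name]
            if abs(ps[0][1] - older) > tol * scale or abs(ps[-1][2] - younger) > tol * scale:
                raise ValueError(f"pieces do not tile branch {nd.name!r}")
            for (s0, a0, a1), nxt in zip(ps, ps[1:] + [None]):
                if nxt is not None:
                    if abs(nxt[1] - a1) > tol * scale:
                        raise ValueError(f"gap in pieces on branch {nd.name!r}")
                    if nxt[0] == s0:
                        raise ValueError(f"adjacent equal states on branch {nd.name!r}")
            if ps[0][0] != self.node_states[nd.parent.name]:
                raise ValueError(f"state discontinuity above branch {nd.name!r}")
            if ps[-1][0] != self.node_states[nd.name]:
                raise ValueError(f"state discontinuity at node {nd.name!r}")


def _sample_conditioned_path(
    a: int, b: int, t: float, q: float, k: int, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Jump times/states on (0, t) for the chain conditioned on X(0)=a, X(t)=b.

    Uniformization with dominating rate kq: the jump matrix R = I + Q/(kq)
    is uniform 1/k, so given n >= 1 total (possibly virtual) jumps the
    intermediate states are iid uniform and the last jump lands on b.
    Returns the real state-change points as (new_state, time) forward in time.
    """
    if t <= 0 or q <= 0:
        if a != b:
            raise AssertionError("impossible endpoint pair on zero-length branch")
        return []
    lam = k * q * t
    e = math.exp(-k * q * t)
    p_ab = (1.0 / k) + ((k - 1) / k) * e if a == b else (1.0 / k) * (1.0 - e)
    u = rng.random() * p_ab
    # P(N=n, end=b): n=0 -> e * [a==b]; n>=1 -> pois(n)/k
    n = 0
    acc = e if a == b else 0.0
    pois = e  # Poisson(lam) pmf at n=0
    while acc < u:
        n += 1
        pois *= lam / n
        acc += pois / k
        if n > 100000:  # pragma: no cover - numerically unreachable
            raise AssertionError("uniformization failed to converge")
    if n == 0:
        return []
    times = np.sort(rng.random(n)) * t
    states = np.empty(n, dtype=int)
    if n > 1:
        states[: n - 1] = rng.integers(k, size=n - 1)
    states[n - 1] = b
    # collapse virtual jumps
    path = []
    cur = a
    for i in range(n):
        s = int(states[i])
        if s != cur:
            path.append((s, float(times[i])))
            cur = s
    return path


def sample_maps(
    tree: TimeTree,
    tips: Mapping[str, frozenset],
    model: AreaModel,
    n_maps: int = 100,
    seed: int = 0,
    root_prior: str = "uniform",
) -> list[StochasticMap]:
    """Draw ``n_maps`` stochastic area histories conditioned on the tip data."""
    idx = _TreeIndex(tree)
    q, k = model.q, model.k
    partial, _ = _up_pass(idx, tips, q, k)
    ages = tree.ages()
    parent_age = {
        nd.name: ages[nd.parent.name] for nd in tree.preorder() if nd.parent is not None
    }
    rng = np.random.default_rng(seed)
    if root_prior == "uniform":
        prior = np.full(k, 1.0 / k)
    elif root_prior == "fitzjohn":
        rp = partial[idx.root]
        prior = rp / rp.sum()
    else:
        raise ValueError(f"unknown root_prior {root_prior!r}")

    # preorder over flat indices (reverse of postorder)
    preorder = list(range(idx.n - 1, -1, -1))
    maps = []
    for m in range(n_maps):
        node_state = np.empty(idx.n, dtype=int)
        w = prior * partial[idx.root]
        node_state[idx.root] = rng.choice(k, p=w / w.sum())
        pieces: dict[str, list[tuple[int, float, float]]] = {}
        for i in preorder:
            for c in idx.children[i]:
                s = node_state[i]
                t = idx.length[c]
                e = math.exp(-k * q * t)
                pvec = (1.0 - e) / k + np.where(np.arange(k) == s, e, 0.0)
                w = pvec * partial[c]
                sc = int(rng.choice(k, p=w / w.sum()))
                node_state[c] = sc
                name = idx.names[c]
                older = parent_age[name]
                path = _sample_conditioned_path(s, sc, t, q, k, rng)
                ps = []
                cur, start = s, older
                for new_state, tau in path:
                    ps.append((cur, start, older - tau))
                    cur, start = new_state, older - tau
                ps.append((cur, start, older - t))
                pieces[name] = ps
        maps.append(
            StochasticMap(
                pieces=pieces,
                node_states={idx.names[i]: int(node_state[i]) for i in range(idx.n)},
                map_id=m,
                rng_seed=seed,
            )
        )
    return maps


@dataclass
class DispersalSummary:
    """Quantile summaries of dispersal counts across stochastic maps."""

    area_codes: list[str]
    counts: np.ndarray  # (n_maps, k, k) per-map ordered-pair event counts
    mean: np.ndarray
    median: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    windowed: Optional["WindowedDispersal"] = None


@dataclass
class WindowedDispersal:
    edges: np.ndarray  # (n_windows + 1,) ages, oldest first
    immigration: np.ndarray  # (n_maps, n_windows, k)
    emigration: np.ndarray  # (n_maps, n_windows, k)
    imm_median: np.ndarray
    imm_q025: np.ndarray
    imm_q975: np.ndarray
    emi_median: np.ndarray
    emi_q025: np.ndarray
    emi_q975: np.ndarray


def _events(smap: StochasticMap):
    """Yield (source, dest, age_of_new_state) over all branches of one map."""
    for ps in smap.pieces.values():
        for (s0, _, _), (s1, a1, _) in zip(ps, ps[1:]):
            yield s0, s1, a1


def count_dispersals(
    maps: Sequence[StochasticMap], area_codes: Sequence[str]
) -> DispersalSummary:
    """Per ordered area pair: mean, median and 95% quantile range of counts."""
    if not maps:
        raise ValueError("need at least one stochastic map")
    k = len(area_codes)
    counts = np.zeros((len(maps), k, k))
    for mi, smap in enumerate(maps):
        for s0, s1, _ in _events(smap):
            counts[mi, s0, s1] += 1
    return DispersalSummary(
        area_codes=list(area_codes),
        counts=counts,
        mean=counts.mean(axis=0),
        median=np.quantile(counts, 0.5, axis=0),
        q025=np.quantile(counts, 0.025, axis=0),
        q975=np.quantile(counts, 0.975, axis=0),
    )


def filter_network(summary: DispersalSummary) -> set[tuple[str, str]]:
    """Ordered pairs whose 2.5% quantile of counts exceeds zero."""
    keep = set()
    k = len(summary.area_codes)
    for i in range(k):
        for j in range(k):
            if i != j and summary.q025[i, j] > 0:
                keep.add((summary.area_codes[i], summary.area_codes[j]))
    return keep


def window_edges(root_age: float, n_windows: int) -> np.ndarray:
    """Ages of window boundaries, oldest first: root_age down to 0."""
    return np.linspace(root_age, 0.0, n_windows + 1)


def window_index(age: float, root_age: float, n_windows: int) -> int:
    """Index (0 = oldest) of the window containing an event at ``age``.

    Windows partition [root_age, 0]; an event exactly on a boundary belongs
    to the older window.
    """
    w = root_age / n_windows
    x = (root_age - age) / w
    j = int(math.floor(x))
    if j > 0 and x == j:
        j -= 1
    return min(max(j, 0), n_windows - 1)


def dispersal_time_windows(
    maps: Sequence[StochasticMap],
    area_codes: Sequence[str],
    root_age: float,
    n_windows: int = 10,
    focal_areas: Optional[Sequence[str]] = None,
) -> WindowedDispersal:
    """Median and 95% quantile range of immigration/emigration per window.

    Immigration into an area counts events whose destination is the area;
    emigration counts events whose source is the area.  ``focal_areas`` only
    restricts which columns are meaningful to report; all are computed.
    """
    if not maps:
        raise ValueError("need at least one stochastic map")
    k = len(area_codes)
    imm = np.zeros((len(maps), n_windows, k))
    emi = np.zeros((len(maps), n_windows, k))
    for mi, smap in enumerate(maps):
        for s0, s1, age in _events(smap):
            wi = window_index(age, root_age, n_windows)
            imm[mi, wi, s1] += 1
            emi[mi, wi, s0] += 1
    return WindowedDispersal(
        edges=window_edges(root_age, n_windows),
        immigration=imm,
        emigration=emi,
        imm_median=np.quantile(imm, 0.5, axis=0),
        imm_q025=np.quantile(imm, 0.025, axis=0),
        imm_q975=np.quantile(imm, 0.975, axis=0),
        emi_median=np.quantile(emi, 0.5, axis=0),
        emi_q025=np.quantile(emi, 0.025, axis=0),
        emi_q975=np.quantile(emi, 0.975, axis=0),
    )


def maps_to_table(maps: Sequence[StochasticMap], area_codes: Sequence[str]) -> pd.DataFrame:
    rows = []
    for smap in maps:
        for branch, ps in smap.pieces.items():
            for state, a0, a1 in ps:
                rows.append(
                    {
                        "map_id": smap.map_id,
                        "branch_id": branch,
                        "state": area_codes[state],
                        "start_age": a0,
                        "end_age": a1,
                    }
                )
    return pd.DataFrame(rows, columns=["map_id", "branch_id", "state", "start_age", "end_age"])


def table_to_maps(
    df: pd.DataFrame, tree: TimeTree, area_codes: Sequence[str]
) -> list[StochasticMap]:
    idx = {c: i for i, c in enumerate(area_codes)}
    maps = []
    for map_id, grp in df.groupby("map_id", sort=True):
        pieces: dict[str, list[tuple[int, float, float]]] = {}
        for row in grp.itertuples(index=False):
            pieces.setdefault(str(row.branch_id), []).append(
                (idx[row.state], float(row.start_age), float(row.end_age))
            )
        for branch in pieces:
            pieces[branch].sort(key=lambda p: -p[1])
        node_states = {}
        for nd in tree.preorder():
            if nd.name in pieces:
                node_states[nd.name] = pieces[nd.name][-1][0]
        for nd in tree.preorder():
            if nd.children and nd.children[0].name in pieces:
                node_states[nd.name] = pieces[nd.children[0].name][0][0]
        maps.append(StochasticMap(pieces=pieces, node_states=node_states, map_id=int(map_id)))
    return maps
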