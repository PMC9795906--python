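"""Synthetic inputs with known ground truth for every pipeline stage.

Provides birth-death trees with rate shifts, tip areas evolved under the
equal-rates Markov process with controlled polymorphism and missingness,
sequence families with controlled pairwise identity, and metadata records
with known true areas.  All randomness flows through one seeded
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from areaevo.io_core import MetadataRecord, Node, RateMap, SequenceRecord, TimeTree

__all__ = [
    "SimConfig",
    "sim_bd_tree",
    "sim_mk_tips",
    "MkSimResult",
    "sim_sequence_family",
    "grid_scheme_geojson",
    "grid_country_table",
    "sim_metadata",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters for the full synthetic-data bundle.

    ``rate_shift_spec`` entries are ``(shift_time, new_birth, new_death)``:
    at ``shift_time`` (forward time from the root) one randomly chosen
    surviving lineage and all its descendants switch to the new rates.
    """

    n_tips: int = 50
    birth_rate: float = 0.3
    death_rate: float = 0.0
    rate_shift_spec: list[tuple[float, float, float]] = field(default_factory=list)
    mk_rate: float = 0.05
    n_areas: int = 9
    polymorphic_fraction: float = 0.0
    missing_fraction: float = 0.0
    seq_divergence_spec: list[tuple[int, float]] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.mk_rate < 0:
            raise ValueError("mk_rate must be >= 0")
        for f in (self.polymorphic_fraction, self.missing_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.polymorphic_fraction + self.missing_fraction > 1:
            raise ValueError("polymorphic_fraction + missing_fraction > 1")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")


class _SimLineage:
    __slots__ = ("parent", "children", "birth_time", "end_time", "alive", "regimes")

    def __init__(self, parent, birth_time, lam, mu):
        self.parent = parent
        self.children = []
        self.birth_time = birth_time
        self.end_time = None
        self.alive = True
        # (start_time, birth, death) regime pieces along this edge, forward time
        self.regimes = [(birth_time, lam, mu)]


def sim_bd_tree(config: SimConfig, max_tries: int = 100) -> tuple[TimeTree, RateMap]:
    """Simulate a birth-death tree forward in time, stopping at ``n_tips`` extant.

    Returns the pruned, ultrametric tree of extant tips plus the true
    per-branch net-rate map (birth - death, including shifts).  Simple
    stop-at-n sampling, not GSA; adequate for desk-scale testing.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    last_err = None
    for _ in range(max_tries):
        result = _try_sim_bd(config, rng)
        if result is not None:
            return result
        last_err = "all lineages went extinct"
    raise RuntimeError(
        f"birth-death simulation failed after {max_tries} tries: {last_err}"
    )


def _try_sim_bd(config: SimConfig, rng) -> Optional[tuple[TimeTree, RateMap]]:
    lam, mu = config.birth_rate, config.death_rate
    root = _SimLineage(None, 0.0, lam, mu)
    c1 = _SimLineage(root, 0.0, lam, mu)
    c2 = _SimLineage(root, 0.0, lam, mu)
    root.children = [c1, c2]
    root.end_time = 0.0
    root.alive = False
    active = [c1, c2]
    t = 0.0
    shifts = sorted(config.rate_shift_spec)
    shift_i = 0

    while True:
        if not active:
            return None
        if len(active) == config.n_tips:
            # stop just before the next event would occur
            rates = np.array([l.regimes[-1][1] + l.regimes[-1][2] for l in active])
            total = rates.sum()
            present = t + (rng.exponential(1.0 / total) if total > 0 else 1.0)
            return _build_pruned(active, present, config)
        rates = np.array([l.regimes[-1][1] + l.regimes[-1][2] for l in active])
        total = rates.sum()
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_next = t + wait
        # apply any rate shift scheduled before the next event
        if shift_i < len(shifts) and shifts[shift_i][0] <= t_next:
            st, nl, nm = shifts[shift_i]
            shift_i += 1
            victim = active[rng.integers(len(active))]
            victim.regimes.append((st, nl, nm))
            t = st
            continue
        t = t_next
        idx = rng.choice(len(active), p=rates / total)
        lineage = active[idx]
        _, cl, cm = lineage.regimes[-1]
        lineage.end_time = t
        if rng.random() < cl / (cl + cm) if cm > 0 else True:
            k1 = _SimLineage(lineage, t, cl, cm)
            k2 = _SimLineage(lineage, t, cl, cm)
            lineage.children = [k1, k2]
            lineage.alive = False
            active.pop(idx)
            active.extend([k1, k2])
        else:
            lineage.alive = False
            active.pop(idx)


def _build_pruned(extant, present, config) -> tuple[TimeTree, RateMap]:
    """Prune extinct lineages, merge unifurcations, build TimeTree + RateMap."""
    keep = set()
    for l in extant:
        l.end_time = present
        nd = l
        while nd is not None and nd not in keep:
            keep.add(nd)
            nd = nd.parent

    def surviving_children(l):
        return [c for c in l.children if c in keep]

    tip_counter = [0]
    node_counter = [0]

    def build(l, path_regimes, path_start):
        """Walk down merging single-survivor chains; returns (Node, regime pieces)."""
        regimes = path_regimes + [(max(s, path_start), b, d) for s, b, d in l.regimes]
        while True:
            kids = surviving_children(l)
            if len(kids) == 1:
                l = kids[0]
                regimes = regimes + list(l.regimes)
            else:
                break
        end = l.end_time
        if not surviving_children(l):
            tip_counter[0] += 1
            nd = Node(name=f"t{tip_counter[0]}")
        else:
            node_counter[0] += 1
            nd = Node(name=f"i{node_counter[0]}")
            for c in surviving_children(l):
                child, child_regimes = build(c, [], c.birth_time)
                nd.add_child(child)
                nd_pieces[child] = child_regimes
        start = path_start
        nd.length = end - start
        # clip regime pieces to (start, end) in forward time
        pieces = []
        for i, (s, b, d) in enumerate(regimes):
            s2 = max(s, start)
            e2 = regimes[i + 1][0] if i + 1 < len(regimes) else end
            e2 = min(e2, end)
            if e2 > s2:
                pieces.append((s2, e2, b - d))
        return nd, pieces

    nd_pieces: dict[Node, list] = {}
    # find the MRCA of extant tips (deepest node with >=2 surviving children)
    top = None
    for l in keep:
        if l.parent is None or l.parent not in keep:
            top = l
    while len(surviving_children(top)) == 1:
        top = surviving_children(top)[0]
    root_node = Node(name="root")
    crown_time = top.end_time
    for c in surviving_children(top):
        child, child_regimes = build(c, [], c.birth_time)
        root_node.add_child(child)
        nd_pieces[child] = child_regimes
    tree = TimeTree(root_node)
    root_age = present - crown_time
    # convert forward-time regime pieces to (older_age, younger_age) pieces
    pieces = {}
    for nd, ps in nd_pieces.items():
        merged = []
        for s, e, r in ps:
            a0, a1 = present - s, present - e
            if merged and abs(merged[-1][2] - r) < 1e-300:
                merged[-1] = (merged[-1][0], a1, r)
            else:
                merged.append((a0, a1, r))
        pieces[nd.name] = merged
    rate_map = RateMap(pieces)
    rate_map.validate(tree)
    tree.validate(expect_ultrametric=True)
    return tree, rate_map


# ---------------------------------------------------------------------------
# Equal-rates Markov tip simulation
# ---------------------------------------------------------------------------


@dataclass
class MkSimResult:
    tip_areas: dict[str, frozenset[int]]
    true_node_states: dict[str, int]
    n_events: int
    branch_events: dict[str, int]


def sim_mk_tips(
    tree: TimeTree,
    q: float,
    k: int,
    polymorphic_fraction: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> MkSimResult:
    """Evolve a k-state equal-rates character down the tree.

    Root state uniform; along each branch, change events occur at rate
    ``q * (k - 1)`` with the new state uniform among the other ``k - 1``.
    A random tip subset then becomes polymorphic (true state plus one random
    extra state), another subset missing (empty set).
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    if polymorphic_fraction + missing_fraction > 1:
        raise ValueError("polymorphic_fraction + missing_fraction > 1")
    rng = np.random.default_rng(seed)
    states: dict[str, int] = {tree.root.name: int(rng.integers(k))}
    branch_events: dict[str, int] = {}
    n_events = 0
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        s = states[nd.parent.name]
        t_left = nd.length
        events = 0
        if q > 0:
            while True:
                wait = rng.exponential(1.0 / (q * (k - 1)))
                if wait >= t_left:
                    break
                t_left -= wait
                step = int(rng.integers(k - 1))
                s = step if step < s else step + 1
                events += 1
        states[nd.name] = s
        branch_events[nd.name] = events
        n_events += events

    tips = tree.tip_labels
    n = len(tips)
    order = rng.permutation(n)
    n_missing = int(round(missing_fraction * n))
    n_poly = int(round(polymorphic_fraction * n))
    missing_set = {tips[i] for i in order[:n_missing]}
    poly_set = {tips[i] for i in order[n_missing : n_missing + n_poly]}
    tip_areas: dict[str, frozenset[int]] = {}
    for t in tips:
        if t in missing_set:
            tip_areas[t] = frozenset()
        elif t in poly_set:
            true = states[t]
            step = int(rng.integers(k - 1))
            extra = step if step < true else step + 1
            tip_areas[t] = frozenset({true, extra})
        else:
            tip_areas[t] = frozenset({states[t]})
    return MkSimResult(
        tip_areas=tip_areas,
        true_node_states=states,
        n_events=n_events,
        branch_events=branch_events,
    )


# ---------------------------------------------------------------------------
# Sequence families
# ---------------------------------------------------------------------------


def sim_sequence_family(
    centroid_length: int,
    family_spec: Sequence[tuple[int, float]],
    seed: int = 0,
    inter_divergence: float = 0.2,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Generate sequence families by mutating per-family centroids.

    ``family_spec`` is a list of ``(family_size, per_site_substitution_prob)``.
    The first centroid is random; subsequent centroids are copies of the first
    mutated at ``inter_divergence`` per site, controlling between-family
    identity.  Returns the records (centroid first per family, slightly
    longer than members so greedy clustering picks it) plus true labels.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    base_centroid = rng.integers(4, size=centroid_length)
    for fam, (size, p_sub) in enumerate(family_spec):
        if size < 1:
            raise ValueError("family size must be >= 1")
        if not 0 <= p_sub <= 1:
            raise ValueError("substitution probability must be in [0, 1]")
        if fam == 0:
            centroid = base_centroid.copy()
        else:
            centroid = _mutate(base_centroid, inter_divergence, rng)
        cid = f"f{fam}_c"
        records.append(SequenceRecord(cid, "".join(_BASES[centroid])))
        labels[cid] = fam
        for m in range(size - 1):
            seq = _mutate(centroid, p_sub, rng)
            # members are one base shorter so the centroid is the longest
            sid = f"f{fam}_m{m}"
            records.append(SequenceRecord(sid, "".join(_BASES[seq[:-1]])))
            labels[sid] = fam
    return records, labels


def _mutate(seq: np.ndarray, p: float, rng) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        out[hits] = (out[hits] + shift) % 4
    return out


# ---------------------------------------------------------------------------
# Synthetic geography
# ---------------------------------------------------------------------------


def grid_scheme_geojson(area_codes: Sequence[str]) -> dict:
    """Non-overlapping unit-square polygons, one per area, along the equator.

    Square i spans lon [2i, 2i+1], lat [0, 1]; squares are separated by a
    1-degree gap so no point falls in two polygons.
    """
    features = []
    for i, code in enumerate(area_codes):
        x0 = 2.0 * i
        ring = [[x0, 0.0], [x0 + 1.0, 0.0], [x0 + 1.0, 1.0], [x0, 1.0], [x0, 0.0]]
        features.append(
            {
                "type": "Feature",
                "properties": {"area": code},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def grid_country_table(area_codes: Sequence[str]) -> dict[str, list[str]]:
    """One unambiguous country per area plus one spanning the first two."""
    table = {f"Country_{c}": [c] for c in area_codes}
    if len(area_codes) >= 2:
        table["Ambiguo"] = [area_codes[0], area_codes[1]]
    return table


def sim_metadata(
    true_areas: dict[str, str],
    area_codes: Sequence[str],
    seed: int = 0,
    coordinate_fraction: float = 0.2,
    manual_fraction: float = 0.0,
) -> list[MetadataRecord]:
    """Metadata records whose cascade assignment recovers ``true_areas``.

    Each record gets either an unambiguous country, in-polygon coordinates
    (for the :func:`grid_scheme_geojson` layout), or a manual area code,
    chosen at the given fractions.
    """
    rng = np.random.default_rng(seed)
    idx = {c: i for i, c in enumerate(area_codes)}
    out = []
    for seq_id, area in true_areas.items():
        u = rng.random()
        if u < coordinate_fraction:
            lon = 2.0 * idx[area] + 0.1 + 0.8 * rng.random()
            lat = 0.1 + 0.8 * rng.random()
            out.append(MetadataRecord(seq_id, otu_id=seq_id, lat=lat, lon=lon))
        elif u < coordinate_fraction + manual_fraction:
            out.append(MetadataRecord(seq_id, otu_id=seq_id, manual_area=area))
        else:
            out.append(MetadataRecord(seq_id, otu_id=seq_id, country=f"Country_{area}"))
    return out
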