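"""Focal-area lineages: identification from marginal ancestral estimates,
stem/crown age extraction, calibration scaling, and geological-event overlap.

A lineage for a focal area is a maximal connected set of nodes (tips and
internals) whose probability for that area exceeds the threshold.  Tips enter
with indicator probabilities (split equally across a polymorphic tip's
areas), internal nodes with their marginal relative likelihoods.  The stem
age is the age of the parent of the set's shallowest node; the crown age is
the age of that node itself when the set holds two or more tips.

The threshold must be >= 0.5: probabilities sum to 1 across areas, so above
0.5 no node can belong to lineages of two areas and the sets are unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from areaevo.io_core import TimeTree
from areaevo.supertree import CalibrationSpec, format_age, round_age

__all__ = [
    "FocalLineage",
    "EventWindow",
    "find_focal_lineages",
    "tabulate_lineages",
    "event_overlap",
    "load_default_events",
]


@dataclass
class FocalLineage:
    lineage_id: str
    focal_area: str
    member_otus: list[str]
    is_clade: bool
    root_node: str
    stem_age_rel: Optional[float]  # None when the set contains the tree root
    crown_age_rel: Optional[float]  # None for single-OTU lineages


@dataclass(frozen=True)
class EventWindow:
    """A geological event: an age span in Myr (start >= end; point if equal)."""

    name: str
    start_age: float
    end_age: float

    def __post_init__(self):
        if not self.start_age >= self.end_age >= 0:
            raise ValueError(f"need start_age >= end_age >= 0 for {self.name!r}")


def load_default_events() -> list[EventWindow]:
    text = resources.files("areaevo").joinpath("data/events.yaml").read_text()
    raw = yaml.safe_load(text)
    return [EventWindow(e["name"], float(e["start_age"]), float(e["end_age"])) for e in raw]


def _node_prob(node, marginals, tips, area_index: int) -> float:
    if node.is_tip:
        observed = tips.get(node.name, frozenset())
        if not observed:
            return 0.0
        return (1.0 / len(observed)) if area_index in observed else 0.0
    return float(marginals[node.name][area_index])


def find_focal_lineages(
    tree: TimeTree,
    marginals: Mapping[str, np.ndarray],
    tips: Mapping[str, frozenset],
    focal_areas: Sequence[str],
    area_codes: Sequence[str],
    threshold: float = 0.5,
) -> list[FocalLineage]:
    """Maximal connected above-threshold node sets, one lineage each."""
    if threshold < 0.5:
        raise ValueError(
            "threshold must be >= 0.5 so that lineages of different areas are disjoint"
        )
    ages = tree.ages()
    out: list[FocalLineage] = []
    for area in focal_areas:
        ai = list(area_codes).index(area)
        passing = {
            nd.name
            for nd in tree.preorder()
            if _node_prob(nd, marginals, tips, ai) > threshold
        }
        # connected components under tree adjacency, rooted representation
        comp_root = {}
        for nd in tree.preorder():  # parents precede children
            if nd.name not in passing:
                continue
            if nd.parent is not None and nd.parent.name in passing:
                comp_root[nd.name] = comp_root[nd.parent.name]
            else:
                comp_root[nd.name] = nd.name
        components: dict[str, list[str]] = {}
        for name, root in comp_root.items():
            components.setdefault(root, []).append(name)
        for n, (root_name, members) in enumerate(sorted(components.items(), key=lambda kv: -ages[kv[0]])):
            root_node = tree.node(root_name)
            tips_in = [m for m in members if tree.node(m).is_tip]
            stem = ages[root_node.parent.name] if root_node.parent is not None else None
            crown = ages[root_name] if len(tips_in) >= 2 else None
            out.append(
                FocalLineage(
                    lineage_id=f"{area}_{n + 1}",
                    focal_area=area,
                    member_otus=sorted(tips_in),
                    is_clade=len(tips_in) >= 2,
                    root_node=root_name,
                    stem_age_rel=stem,
                    crown_age_rel=crown,
                )
            )
    return out


def _age_string(rel_age: float, calib: CalibrationSpec, decimals: int = 1) -> str:
    point = format_age(rel_age * calib.point_age, decimals)
    low = format_age(rel_age * calib.low_age, decimals)
    high = format_age(rel_age * calib.high_age, decimals)
    return f"{point} ({low}–{high})"


def tabulate_lineages(
    lineages: Sequence[FocalLineage],
    calib: CalibrationSpec,
    focal_areas: Optional[Sequence[str]] = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-area lineage counts and oldest crown/stem age strings.

    Ages are formatted ``point (low-high)`` after half-up rounding to 0.1 Myr;
    whole values print without decimals; missing crown ages print an em dash.
    """
    if focal_areas is None:
        focal_areas = sorted({l.focal_area for l in lineages})
    rows = []
    for area in focal_areas:
        ls = [l for l in lineages if l.focal_area == area]
        crowns = [l.crown_age_rel for l in ls if l.crown_age_rel is not None]
        stems = [l.stem_age_rel for l in ls if l.stem_age_rel is not None]
        rows.append(
            {
                "area": area,
                "n_lineages": len(ls),
                "n_clades": sum(1 for l in ls if l.is_clade),
                "oldest_crown": _age_string(max(crowns), calib, decimals) if crowns else "—",
                "oldest_stem": _age_string(max(stems), calib, decimals) if stems else "—",
            }
        )
    return pd.DataFrame(rows, columns=["area", "n_lineages", "n_clades", "oldest_crown", "oldest_stem"])


def event_overlap(
    lineages: Sequence[FocalLineage],
    events: Sequence[EventWindow],
    calib: CalibrationSpec,
) -> pd.DataFrame:
    """For every lineage and event: does the calibrated stem/crown age
    uncertainty interval [low, high] intersect the event window?"""
    rows = []
    for l in lineages:
        for which, rel in (("stem", l.stem_age_rel), ("crown", l.crown_age_rel)):
            if rel is None:
                continue
            low, high = rel * calib.low_age, rel * calib.high_age
            for ev in events:
                rows.append(
                    {
                        "lineage_id": l.lineage_id,
                        "area": l.focal_area,
                        "age_type": which,
                        "age_low": low,
                        "age_high": high,
                        "event": ev.name,
                        "overlaps": bool(low <= ev.start_age and high >= ev.end_age),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["lineage_id", "area", "age_type", "age_low", "age_high", "event", "overlaps"],
    )
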