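"""Supertree assembly: support-filtered constraints, rescale-grafting of
relatively calibrated subclade trees into a unit-root backbone, long-branch
flagging, and absolute-time scaling with calibration uncertainty.

Trees enter this module already time-calibrated (relative crown age 1);
rate smoothing itself is out of scope.  Shared tips between backbone and
subtree are given explicitly, never fuzzy-matched.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from areaevo.io_core import Node, TimeTree

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationSpec",
    "constraint_from_support",
    "graft",
    "flag_long_branches",
    "scale_absolute",
    "node_age_triples",
    "round_age",
]


@dataclass(frozen=True)
class CalibrationSpec:
    """Point age plus uncertainty bounds, in Myr, for the unit root age."""

    point_age: float
    low_age: float
    high_age: float

    def __post_init__(self):
        if not 0 < self.low_age <= self.point_age <= self.high_age:
            raise ValueError(
                f"need 0 < low <= point <= high, got "
                f"({self.low_age}, {self.point_age}, {self.high_age})"
            )


def round_age(value: float, decimals: int = 1) -> float:
    """Round half-up to the given number of decimals (report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_age(value: float, decimals: int = 1) -> str:
    """Rounded age string; whole values print without a decimal point."""
    r = round_age(value, decimals)
    if r == int(r):
        return str(int(r))
    return f"{r:.{decimals}f}".rstrip("0").rstrip(".")


def constraint_from_support(tree: TimeTree, min_support: float = 0.7) -> TimeTree:
    """Collapse internal branches with support below ``min_support``.

    Missing support on an internal node counts as below threshold (logged).
    The result is a topology-only tree: branch lengths are dropped (set to 0).
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for nd in list(out.preorder()):
            if nd is out.root or nd.is_tip:
                continue
            if nd.support is None:
                logger.info("internal node %s has no support; collapsing", nd.name)
            if nd.support is None or nd.support < min_support:
                parent = nd.parent
                i = parent.children.index(nd)
                parent.children[i : i + 1] = nd.children
                for ch in nd.children:
                    ch.parent = parent
                changed = True
    for nd in out.preorder():
        nd.length = 0.0
    out.reindex()
    return out


def graft(
    backbone: TimeTree,
    subtree: TimeTree,
    shared_tips: dict[str, str],
    tol: float = 1e-6,
) -> TimeTree:
    """Replace a backbone clade by a rescaled calibrated subtree.

    ``shared_tips`` maps backbone tip labels to subtree tip labels.  The
    backbone MRCA of the shared tips defines the clade to replace (its tip
    set must equal the shared set); the subtree (root age 1) is rescaled so
    its root age equals the replaced clade's crown age, keeping the stem
    branch unchanged and whole-tree ultrametricity intact.
    """
    if not shared_tips:
        raise ValueError("shared_tips mapping is empty")
    backbone.validate(expect_ultrametric=True)
    sub_labels = set(subtree.tip_labels)
    missing = [v for v in shared_tips.values() if v not in sub_labels]
    if missing:
        raise ValueError(f"subtree is missing shared tips: {sorted(missing)}")

    out = backbone.copy()
    mrca = out.mrca(shared_tips.keys())
    clade_tipset = {t.name for t in out.clade_tips(mrca)}
    intruders = clade_tipset - set(shared_tips)
    if intruders:
        raise ValueError(
            f"shared tips are not monophyletic in the backbone; "
            f"intruding tips: {sorted(intruders)}"
        )

    crown_age = out.ages()[mrca.name]
    sub = subtree.copy()
    sub_root_age = sub.root_age
    if abs(sub_root_age - 1.0) > tol:
        logger.warning(
            "subtree root age %.6g != 1; normalizing before grafting", sub_root_age
        )
    sub = sub.scale(crown_age / sub_root_age)

    new_clade = sub.root
    new_clade.length = mrca.length
    new_clade.support = mrca.support
    # drop subtree internal-node names so rebuilding cannot hit collisions
    # with auto-assigned names surviving elsewhere in the backbone
    for nd in sub.preorder():
        if not nd.is_tip:
            nd.name = None
    if mrca is out.root:
        out = TimeTree(new_clade)
    else:
        parent = mrca.parent
        parent.children[parent.children.index(mrca)] = new_clade
        new_clade.parent = parent
        # avoid name collisions between removed clade names and subtree names
        out = TimeTree(out.root)
    out.validate(expect_ultrametric=True, rel_tol=1e-8)
    return out


def flag_long_branches(tree: TimeTree, factor: float = 10.0) -> list[str]:
    """Tips whose terminal branch exceeds ``factor`` x the median terminal branch.

    Returned in decreasing order of excess length.
    """
    tips = tree.tips
    med = statistics.median(t.length for t in tips)
    flagged = [(t.length - factor * med, t.name) for t in tips if t.length > factor * med]
    flagged.sort(key=lambda x: (-x[0], x[1]))
    return [name for _, name in flagged]


def scale_absolute(
    tree: TimeTree, calib: CalibrationSpec, tol: float = 1e-6
) -> dict[str, TimeTree]:
    """Multiply a unit-root relative tree onto the low/point/high calibrations."""
    if abs(tree.root_age - 1.0) > tol:
        raise ValueError(
            f"scale_absolute needs a unit root age, got {tree.root_age:.6g}"
        )
    return {
        "low": tree.scale(calib.low_age),
        "point": tree.scale(calib.point_age),
        "high": tree.scale(calib.high_age),
    }


def node_age_triples(
    tree: TimeTree, calib: CalibrationSpec, decimals: int = 1
) -> dict[str, tuple[float, float, float]]:
    """Per-node (low, point, high) absolute ages, rounded half-up to 0.1 Myr."""
    scaled = scale_absolute(tree, calib)
    ages = {key: t.ages() for key, t in scaled.items()}
    return {
        name: (
            round_age(ages["low"][name], decimals),
            round_age(ages["point"][name], decimals),
            round_age(ages["high"][name], decimals),
        )
        for name in ages["point"]
    }
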