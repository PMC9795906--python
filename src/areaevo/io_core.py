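"""Core data structures and readers/writers for trees, sequences, metadata and rate tables.

The central object is :class:`TimeTree`, a rooted tree with branch lengths in
time units (relative, root crown age = 1, or absolute Myr).  Node ages are
measured backward from the tips (age 0 = present).  Branches are addressed by
the name of their child node; piecewise quantities along branches (rates,
area states) are addressed by ``(older_age, younger_age)`` intervals.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTURYSWKMBDHVN")

__all__ = [
    "Node",
    "TimeTree",
    "SequenceRecord",
    "MetadataRecord",
    "RateMap",
    "NewickParseError",
    "UltrametricityError",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_rate_table",
    "write_rate_table",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class UltrametricityError(ValueError):
    """Raised when a tree flagged as ultrametric is not."""


class Node:
    """A tree node; ``length`` is the branch above it (0.0 at the root)."""

    __slots__ = ("name", "parent", "children", "length", "support")

    def __init__(self, name=None, length=0.0, support=None):
        self.name: Optional[str] = name
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length: float = length
        self.support: Optional[float] = support

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover
        return f"Node({self.name!r}, len={self.length})"


class TimeTree:
    """Rooted tree with branch lengths in time units.

    Every node carries a unique name; unnamed internal nodes are auto-named
    ``nd<i>`` in preorder.  Branches are identified by the child node's name.
    """

    def __init__(self, root: Node):
        self.root = root
        self._assign_names()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _assign_names(self) -> None:
        seen = set()
        for nd in self.preorder():
            if nd.name is not None:
                if nd.name in seen:
                    raise ValueError(f"duplicate node name {nd.name!r}")
                seen.add(nd.name)
        i = 0
        for nd in self.preorder():
            if nd.name is None:
                while f"nd{i}" in seen:
                    i += 1
                nd.name = f"nd{i}"
                seen.add(nd.name)

    def _index(self) -> None:
        self._by_name = {nd.name: nd for nd in self.preorder()}

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    @property
    def nodes(self) -> list[Node]:
        return list(self.preorder())

    @property
    def tips(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [nd.name for nd in self.tips]

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.preorder() if nd.is_tip)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def node(self, name: str) -> Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no node named {name!r} in tree") from None

    # -- metrics --------------------------------------------------------------

    def depths(self) -> dict[str, float]:
        """Distance from the root to every node."""
        d = {self.root.name: 0.0}
        for nd in self.preorder():
            if nd is self.root:
                continue
            d[nd.name] = d[nd.parent.name] + nd.length
        return d

    @property
    def root_age(self) -> float:
        d = self.depths()
        return max(d[t.name] for t in self.tips)

    def ages(self) -> dict[str, float]:
        """Node ages backward from the youngest tip (age 0 = present)."""
        d = self.depths()
        h = max(d[t.name] for t in self.tips)
        return {name: h - x for name, x in d.items()}

    def total_length(self) -> float:
        return sum(nd.length for nd in self.preorder() if nd is not self.root)

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        return self.max_age_deviation() <= rel_tol * max(self.root_age, 1e-300)

    def max_age_deviation(self) -> float:
        d = self.depths()
        tip_depths = [d[t.name] for t in self.tips]
        return max(tip_depths) - min(tip_depths)

    def mrca(self, names: Iterable[str]) -> Node:
        names = list(names)
        if not names:
            raise ValueError("mrca of empty set")
        paths = []
        for n in names:
            nd = self.node(n)
            path = []
            while nd is not None:
                path.append(nd)
                nd = nd.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for level in zip(*paths):
            first = level[0]
            if all(nd is first for nd in level):
                mrca = first
            else:
                break
        return mrca

    def clade_tips(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            if nd.is_tip:
                out.append(nd)
            stack.extend(nd.children)
        return out

    # -- editing --------------------------------------------------------------

    def copy(self) -> "TimeTree":
        def rec(nd: Node) -> Node:
            c = Node(nd.name, nd.length, nd.support)
            for ch in nd.children:
                c.add_child(rec(ch))
            return c

        return TimeTree(rec(self.root))

    def scale(self, factor: float) -> "TimeTree":
        t = self.copy()
        for nd in t.preorder():
            nd.length *= factor
        return t

    def reindex(self) -> None:
        """Re-run name assignment/indexing after structural edits."""
        self._assign_names()
        self._index()

    # -- validation -----------------------------------------------------------

    def validate(self, expect_ultrametric: bool = False, rel_tol: float = 1e-8) -> None:
        for nd in self.preorder():
            if nd is not self.root and nd.length < 0:
                raise ValueError(f"negative branch length on {nd.name!r}: {nd.length}")
            for ch in nd.children:
                if ch.parent is not nd:
                    raise ValueError("broken parent link")
        if expect_ultrametric and not self.is_ultrametric(rel_tol):
            raise UltrametricityError(
                "tree is not ultrametric: max root-to-tip deviation "
                f"{self.max_age_deviation():g} (root age {self.root_age:g})"
            )

    # -- serialization --------------------------------------------------------

    def to_newick(self, include_support: bool = True, include_lengths: bool = True) -> str:
        """Serialize to Newick.

        The internal-node label slot holds the support value when present,
        otherwise the node's name — so branch ids survive a round trip on
        trees without support values (the label slot cannot carry both).
        """

        def rec(nd: Node) -> str:
            if nd.is_tip:
                s = _quote_label(nd.name)
            else:
                s = "(" + ",".join(rec(c) for c in nd.children) + ")"
                if include_support and nd.support is not None and nd is not self.root:
                    s += f"{nd.support:.17g}"
                elif nd.name is not None:
                    s += _quote_label(nd.name)
            if include_lengths and nd is not self.root:
                s += f":{nd.length:.17g}"
            return s

        return rec(self.root) + ";"

    def __repr__(self):  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, root_age={self.root_age:.4g})"


_LABEL_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _quote_label(label: str) -> str:
    if _LABEL_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; support labels post-processed)
# ---------------------------------------------------------------------------


def parse_newick(text: str, expect_ultrametric: bool = False) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Internal-node labels that look numeric are interpreted as support values;
    supports on a 0-100 scale are rescaled to [0, 1] with a logged warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None
    if dtree.seed_node is None or not dtree.seed_node.child_nodes() and dtree.seed_node.taxon is None:
        raise NewickParseError("empty Newick string")

    def rec(dnode) -> Node:
        children = dnode.child_nodes()
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise ValueError(f"negative branch length {length}")
        if children:
            support = None
            name = None
            if label is not None:
                try:
                    support = float(label)
                except ValueError:
                    name = label
            nd = Node(name=name, length=length, support=support)
            for ch in children:
                nd.add_child(rec(ch))
            return nd
        return Node(name=label, length=length)

    root = rec(dtree.seed_node)
    supports = [nd.support for nd in _iter_nodes(root) if nd.support is not None]
    if supports and max(supports) > 1.0:
        logger.warning("support values look like percentages; rescaling to [0, 1]")
        for nd in _iter_nodes(root):
            if nd.support is not None:
                nd.support /= 100.0
    tree = TimeTree(root)
    tree.validate(expect_ultrametric=expect_ultrametric)
    return tree


def _iter_nodes(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(nd.children)


def read_newick(path, expect_ultrametric: bool = False) -> TimeTree:
    text = Path(path).read_text()
    return parse_newick(text, expect_ultrametric=expect_ultrametric)


def write_newick(tree: TimeTree, path, include_support: bool = True) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with IUPAC alphabet, gap-free, nonempty."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence.upper()) - IUPAC_NT
        if bad:
            raise ValueError(
                f"record {self.id!r} has non-IUPAC characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        # distinguish "no records" from silently empty output
        text = Path(path).read_text()
        if text.strip().startswith(">"):
            raise ValueError(f"FASTA {path} contains a header with no sequence")
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sequence_id",
    "otu_id",
    "country",
    "lat",
    "lon",
    "manual_area",
    "introduced",
]


@dataclass(frozen=True)
class MetadataRecord:
    sequence_id: str
    otu_id: Optional[str] = None
    country: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    manual_area: Optional[str] = None
    introduced: bool = False

    def __post_init__(self):
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if (self.lat is None) != (self.lon is None):
            raise ValueError(f"record {self.sequence_id!r}: lat/lon must come in pairs")


def read_metadata(path) -> list[MetadataRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(["sequence_id"]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key):
            v = d.get(key, "")
            return v if v not in ("", "NA", "nan") else None

        lat, lon = opt("lat"), opt("lon")
        out.append(
            MetadataRecord(
                sequence_id=d["sequence_id"],
                otu_id=opt("otu_id"),
                country=opt("country"),
                lat=float(lat) if lat is not None else None,
                lon=float(lon) if lon is not None else None,
                manual_area=opt("manual_area"),
                introduced=str(opt("introduced")).lower() in ("true", "1", "yes"),
            )
        )
    return out


def write_metadata(records: Sequence[MetadataRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "otu_id": r.otu_id or "",
                "country": r.country or "",
                "lat": "" if r.lat is None else repr(r.lat),
                "lon": "" if r.lon is None else repr(r.lon),
                "manual_area": r.manual_area or "",
                "introduced": "true" if r.introduced else "",
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Piecewise per-branch rates
# ---------------------------------------------------------------------------


@dataclass
class RateMap:
    """Piecewise-constant net diversification rates along every branch.

    ``pieces[branch_id]`` is a list of ``(older_age, younger_age, rate)``
    sorted from older to younger; the pieces must tile the branch exactly.
    Negative rates are legal (net rate) but flagged with a warning.
    """

    pieces: dict[str, list[tuple[float, float, float]]]

    def validate(self, tree: TimeTree, tol: float = 1e-9) -> None:
        ages = tree.ages()
        scale = max(tree.root_age, 1.0)
        for nd in tree.preorder():
            if nd is tree.root:
                continue
            if nd.length == 0:
                continue
            if nd.name not in self.pieces:
                raise ValueError(f"branch {nd.name!r} missing from rate map")
            older, younger = ages[nd.parent.name], ages[nd.name]
            ps = self.pieces[nd.name]
            if abs(ps[0][0] - older) > tol * scale or abs(ps[-1][1] - younger) > tol * scale:
                raise ValueError(
                    f"pieces on branch {nd.name!r} do not span ({older:g}, {younger:g})"
                )
            for (a0, a1, r), nxt in zip(ps, ps[1:] + [None]):
                if a1 >= a0:
                    raise ValueError(f"piece on {nd.name!r} has nonpositive duration")
                if nxt is not None and abs(nxt[0] - a1) > tol * scale:
                    raise ValueError(f"gap in rate pieces on branch {nd.name!r}")
                if r < 0:
                    logger.warning("negative net rate %g on branch %s", r, nd.name)
        extra = set(self.pieces) - {nd.name for nd in tree.preorder()}
        if extra:
            raise ValueError(f"rate map references unknown branches: {sorted(extra)}")

    def rate_at(self, branch_id: str, age: float) -> float:
        for a0, a1, r in self.pieces[branch_id]:
            if a1 <= age <= a0:
                return r
        raise ValueError(f"age {age} outside pieces of branch {branch_id!r}")

    def n_pieces(self) -> int:
        return sum(len(v) for v in self.pieces.values())


def read_rate_table(path, tree: TimeTree, tol: float = 1e-9) -> RateMap:
    """Read a plain per-branch rate table (TSV: branch_id, start_age, end_age, rate).

    ``start_age`` is the older bound.  Branches with no rows inherit the
    nearest ancestral regime (the rate at the parent branch's younger end).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"branch_id", "start_age", "end_age", "rate"}
    if not required <= set(df.columns):
        raise ValueError(f"rate table needs columns {sorted(required)}")
    ages = tree.ages()
    names = {nd.name for nd in tree.preorder()}
    pieces: dict[str, list[tuple[float, float, float]]] = {}
    for row in df.itertuples(index=False):
        if row.branch_id not in names:
            raise ValueError(f"rate table references unknown branch {row.branch_id!r}")
        pieces.setdefault(str(row.branch_id), []).append(
            (float(row.start_age), float(row.end_age), float(row.rate))
        )
    scale = max(tree.root_age, 1.0)
    # validate extents of explicit rows before filling gaps by inheritance
    for name, ps in pieces.items():
        nd = tree.node(name)
        older, younger = ages[nd.parent.name], ages[nd.name]
        ps = sorted(ps, key=lambda p: -p[0])
        if ps[0][0] > older + tol * scale or ps[-1][1] < younger - tol * scale:
            raise ValueError(
                f"piece ages outside branch extent on {name!r}: "
                f"branch spans ({older:g}, {younger:g})"
            )
        pieces[name] = ps
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        older, younger = ages[nd.parent.name], ages[nd.name]
        if nd.name not in pieces:
            # inherit nearest ancestral regime
            anc = nd.parent
            rate = None
            while anc is not None and anc is not tree.root:
                if anc.name in pieces:
                    rate = pieces[anc.name][-1][2]
                    break
                anc = anc.parent
            if rate is None:
                raise ValueError(
                    f"branch {nd.name!r} absent from table and has no ancestral regime"
                )
            pieces[nd.name] = [(older, younger, rate)]
    rm = RateMap(pieces)
    rm.validate(tree, tol=tol)
    return rm


def write_rate_table(rate_map: RateMap, path) -> None:
    rows = []
    for branch, ps in rate_map.pieces.items():
        for a0, a1, r in ps:
            rows.append({"branch_id": branch, "start_age": a0, "end_age": a1, "rate": r})
    pd.DataFrame(rows, columns=["branch_id", "start_age", "end_age", "rate"]).to_csv(
        path, sep="\t", index=False
    )
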