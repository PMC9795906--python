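"""Greedy centroid-based OTU clustering at a fixed identity threshold.

Pairwise identity is computed from one optimal global (end-to-end) alignment
under match=+1, mismatch=-1, gap open=-2 (first gap residue), gap extend=-1
(each further residue).  Ties between equally optimal alignments are broken
deterministically: diagonal (match/mismatch) over vertical (gap in the second
sequence) over horizontal.  Identity = matching columns / alignment columns,
gaps counting against identity (the clustered tool's default dialect); an
``exclude_terminal_gaps`` option is provided.

No k-mer prefilter: in-scope inputs are at most thousands of sequences, so
the exact dynamic program is affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from areaevo.io_core import SequenceRecord

__all__ = ["OtuCluster", "pairwise_identity", "greedy_cluster", "clusters_to_rows"]

_NEG = -1_000_000_000


def _gotoh_align(a, b, match, mismatch, gap_open, gap_extend):
    """Affine-gap global alignment; returns (score, matches, columns, lead_gaps, trail_gaps).

    State matrices: M (diagonal), X (gap in b, consumes a), Y (gap in a).
    Deterministic tie-break preferring M, then X, then Y.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    # pointer codes: 0 from M, 1 from X, 2 from Y
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        PX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        PY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            # M: diagonal step
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            PM[i, j] = ptr
            # X: consume a[i-1] against a gap
            best = M[i - 1, j] + gap_open
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                ptr = 2
            X[i, j] = best
            PX[i, j] = ptr
            # Y: consume b[j-1] against a gap
            best = M[i, j - 1] + gap_open
            ptr = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            PY[i, j] = ptr
    # end state with the same preference order
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    # traceback; gap_cols holds 1 for gap columns, walked end->start
    i, j = n, m
    matches = 0
    columns = 0
    gap_cols = np.zeros(n + m, dtype=np.int8)
    while i > 0 or j > 0:
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            gap_cols[columns] = 0
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            gap_cols[columns] = 1
            state = PX[i, j]
            i -= 1
        else:
            gap_cols[columns] = 1
            state = PY[i, j]
            j -= 1
        columns += 1
    lead = 0
    for c in range(columns - 1, -1, -1):
        if gap_cols[c] == 1:
            lead += 1
        else:
            break
    trail = 0
    for c in range(columns):
        if gap_cols[c] == 1:
            trail += 1
        else:
            break
    if lead == columns:
        trail = 0
    return score, matches, columns, lead, trail


try:  # optional numba acceleration; semantics identical
    from numba import njit

    _gotoh_align = njit(cache=False)(_gotoh_align)
except ImportError:  # pragma: no cover
    pass


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
    exclude_terminal_gaps: bool = False,
) -> float:
    """Fraction of matching columns in one optimal global alignment of a and b.

    The pair is put in a canonical order (longer sequence first, ties broken
    lexicographically) before aligning, so the deterministic tie-breaking
    cannot make the result asymmetric.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    x, y = a.sequence, b.sequence
    if (-len(y), y) < (-len(x), x):
        x, y = y, x
    _, matches, columns, lead, trail = _gotoh_align(
        _encode(x), _encode(y), match, mismatch, gap_open, gap_extend
    )
    if exclude_terminal_gaps:
        columns -= lead + trail
    return matches / columns if columns else 0.0


@dataclass
class OtuCluster:
    """One OTU: the centroid (longest member) plus members in assignment order."""

    centroid_id: str
    member_ids: list[str]
    threshold: float


def greedy_cluster(
    seqs: list[SequenceRecord],
    threshold: float = 0.97,
    accept_mode: str = "first",
    exclude_terminal_gaps: bool = False,
) -> list[OtuCluster]:
    """Greedy centroid clustering.

    Sequences are processed in decreasing length order (ties by input order).
    Each query is compared to existing centroids in centroid-creation order
    and joins the first centroid with identity >= threshold
    (``accept_mode='first'``) or the best such centroid (``'best'``);
    otherwise it founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if accept_mode not in ("first", "best"):
        raise ValueError(f"accept_mode must be 'first' or 'best', got {accept_mode!r}")

    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i].sequence), i))
    clusters: list[OtuCluster] = []
    centroids: list[SequenceRecord] = []
    for i in order:
        query = seqs[i]
        chosen = None
        best_ident = -1.0
        for ci, centroid in enumerate(centroids):
            ident = pairwise_identity(
                query, centroid, exclude_terminal_gaps=exclude_terminal_gaps
            )
            if ident >= threshold:
                if accept_mode == "first":
                    chosen = ci
                    break
                if ident > best_ident:
                    best_ident = ident
                    chosen = ci
        if chosen is None:
            clusters.append(OtuCluster(query.id, [query.id], threshold))
            centroids.append(query)
        else:
            clusters[chosen].member_ids.append(query.id)
    return clusters


def clusters_to_rows(clusters: list[OtuCluster]) -> list[tuple[str, str, str]]:
    """Flatten clusters to (otu_id, centroid_id, member_id) rows for TSV output."""
    rows = []
    for n, cl in enumerate(clusters):
        otu = f"OTU{n + 1}"
        for member in cl.member_ids:
            rows.append((otu, cl.centroid_id, member))
    return rows
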