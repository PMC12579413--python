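"""Split-read breakpoint detection and clustering at a target locus.

Long reads crossing a structural-variant junction align in pieces: the
reference coordinates of consecutive query segments jump forward over a
deletion or rewind across a tandem-duplication junction.  This module
extracts per-read segment chains from alignments, infers a breakpoint
pair with a DEL/TANDEM_DUP/INV signature for each adjacent pair, and
single-linkage clusters the pairs; only clusters supported by two or
more reads with consistent breakpoints are reported as calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Optional

__all__ = [
    "AlignmentSegment",
    "BreakpointPair",
    "BreakpointCluster",
    "extract_splits",
    "infer_breakpoint",
    "cluster_breakpoints",
    "scan_splits",
    "DEFAULT_MIN_MAPQ",
    "DEFAULT_MIN_ANCHOR",
    "DEFAULT_JOIN_TOL",
    "DEFAULT_CLUSTER_TOL",
    "DEFAULT_MIN_SUPPORT",
]

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_ANCHOR = 100  # min aligned bases per segment
DEFAULT_JOIN_TOL = 50  # gap/rewind dead zone: smaller offsets are not SVs
DEFAULT_CLUSTER_TOL = 20  # per-coordinate breakpoint consistency (bp)
DEFAULT_MIN_SUPPORT = 2  # the "two or more split reads" rule


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned segment of a read, in reference and query coordinates.

    ``read_start``/``read_end`` are 1-based positions on the original
    read (i.e. already flipped back for reverse-strand alignments, the
    convention split-read callers use to order segments along the
    molecule).  ``cigar`` excludes clip operations.
    """

    read_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str = "+"
    mapq: int = 60
    is_supplementary: bool = False
    cigar: Optional[tuple[tuple[str, int], ...]] = None
    query_length: int = 0

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start > ref_end")
        if self.read_start > self.read_end:
            raise ValueError("read_start > read_end")

    @property
    def aligned_query_bases(self) -> int:
        return self.read_end - self.read_start + 1

    def as_supplementary(self) -> "AlignmentSegment":
        return replace(self, is_supplementary=True)


@dataclass(frozen=True)
class BreakpointPair:
    """A putative SV junction seen on one read."""

    left_bp: int
    right_bp: int
    signature: str  # DEL | TANDEM_DUP | INV | OTHER
    read_id: str


@dataclass(frozen=True)
class BreakpointCluster:
    """Consensus of split-read junctions from >= ``support`` reads."""

    consensus_left: int
    consensus_right: int
    signature: str
    support: int
    reads: tuple[str, ...]


def extract_splits(
    alignments: Iterable[AlignmentSegment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> dict[str, list[AlignmentSegment]]:
    """Group alignment segments by read, ordered along the query.

    Segments below ``min_mapq`` are excluded (multi-mapping reads with
    mapping quality 1 carry no locatable breakpoint evidence), as are
    micro-segments shorter than ``min_anchor`` aligned bases.  Reads
    left with a single segment are retained - they still contribute to
    read depth and reference-allele counts.
    """
    groups: dict[str, list[AlignmentSegment]] = {}
    for seg in alignments:
        if seg.mapq < min_mapq or seg.aligned_query_bases < min_anchor:
            continue
        groups.setdefault(seg.read_id, []).append(seg)
    for segs in groups.values():
        segs.sort(key=lambda x: (x.read_start, x.read_end))
    return groups


def infer_breakpoint(
    seg_a: AlignmentSegment,
    seg_b: AlignmentSegment,
    join_tol: int = DEFAULT_JOIN_TOL,
) -> BreakpointPair:
    """Breakpoint pair implied by two query-adjacent segments of a read.

    With both segments on the same strand, a forward reference gap
    larger than ``join_tol`` is a deletion junction and a reference
    rewind beyond ``join_tol`` is a tandem-duplication junction; offsets
    inside the dead zone are OTHER (ordinary intra-alignment indels).
    Discordant strands give INV.
    """
    if seg_a.read_id != seg_b.read_id:
        raise ValueError("segments belong to different reads")
    left, right = seg_a.ref_end, seg_b.ref_start
    if seg_a.strand != seg_b.strand:
        sig = "INV"
    elif right - left > join_tol:
        sig = "DEL"
    elif right < left - join_tol:
        sig = "TANDEM_DUP"
    else:
        sig = "OTHER"
    return BreakpointPair(left, right, sig, seg_a.read_id)


def cluster_breakpoints(
    pairs: Iterable[BreakpointPair],
    tol_bp: int = DEFAULT_CLUSTER_TOL,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[BreakpointCluster]:
    """Single-linkage clustering of breakpoint pairs.

    Two pairs join a cluster when they share a signature and both
    coordinates agree within ``tol_bp``.  Support counts distinct reads;
    clusters below ``min_support`` are dropped.  Output is sorted by
    (consensus_left, consensus_right).
    """
    if tol_bp < 0:
        raise ValueError("tol_bp must be >= 0")
    items = list(pairs)
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i], items[j]
            if (
                a.signature == b.signature
                and abs(a.left_bp - b.left_bp) <= tol_bp
                and abs(a.right_bp - b.right_bp) <= tol_bp
            ):
                union(i, j)

    members: dict[int, list[BreakpointPair]] = {}
    for i in range(n):
        members.setdefault(find(i), []).append(items[i])

    clusters = []
    for group in members.values():
        # one pair per read: keep the first occurrence
        seen: dict[str, BreakpointPair] = {}
        for p in group:
            seen.setdefault(p.read_id, p)
        uniq = list(seen.values())
        if len(uniq) < min_support:
            continue
        clusters.append(
            BreakpointCluster(
                consensus_left=int(round(median(p.left_bp for p in uniq))),
                consensus_right=int(round(median(p.right_bp for p in uniq))),
                signature=group[0].signature,
                support=len(uniq),
                reads=tuple(sorted(seen)),
            )
        )
    clusters.sort(key=lambda c: (c.consensus_left, c.consensus_right))
    return clusters


def scan_splits(
    alignments: Iterable[AlignmentSegment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    join_tol: int = DEFAULT_JOIN_TOL,
    tol_bp: int = DEFAULT_CLUSTER_TOL,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[list[BreakpointCluster], list[BreakpointCluster]]:
    """Full scan: extract, infer, cluster.

    Returns (clusters with >= min_support reads, sub-threshold clusters)
    so callers can surface weakly supported junctions as warnings.
    """
    groups = extract_splits(alignments, min_mapq=min_mapq, min_anchor=min_anchor)
    pairs: list[BreakpointPair] = []
    for segs in groups.values():
        for a, b in zip(segs, segs[1:]):
            bp = infer_breakpoint(a, b, join_tol=join_tol)
            if bp.signature != "OTHER":
                pairs.append(bp)
    all_clusters = cluster_breakpoints(pairs, tol_bp=tol_bp, min_support=1)
    strong = [c for c in all_clusters if c.support >= min_support]
    weak = [c for c in all_clusters if c.support < min_support]
    return strong, weak
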