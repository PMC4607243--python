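"""Breakpoint and target-site-duplication inference from soft-clipped reads.

For each cross-sample interval, the read pairs whose host footprints overlap
the interval are realigned to the element LTR with a windowed seed-and-extend
local aligner (exact k-mer seeds, ungapped +1/-1 extension with an x-drop).
Soft-clipped segments of at least 20 bases on the LTR alignments carry host
flank sequence; aligning them back to the host reference within the interval
window places the host/element junction.  When the two junctions of one
insertion are recovered, their breakpoints differ by exactly the length of
the target-site duplication (6 bp for this element family), because the
duplicated host bases flank the element on both sides.

Breakpoint convention: the reported coordinate is the 1-based host position
immediately 5' of the element junction — the last host base before the
element for a left junction, and (first host base after the element) - 1 for
a right junction.  Under this convention the two breakpoints of a TSD-t
insertion at truth junction j are exactly {j, j + t}.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .alignment_io import read_sam, softclips
from .model import (
    BreakpointCall,
    GenomicInterval,
    IntervalCluster,
    LocalHit,
    LTRModel,
    ReadRecord,
    RegionCoverage,
)

DEFAULT_K = 11
DEFAULT_MIN_SCORE = 20
DEFAULT_XDROP = 5
DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_TSD = 6
DEFAULT_MIN_SUPPORT = 2
DEFAULT_FLANK = 5000

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# seed-and-extend engine

@dataclass(slots=True)
class _Segment:
    """An ungapped local alignment segment (forward/forward coordinates)."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    matches: int
    mismatches: int
    score: int


class SeqIndex:
    """Exact k-mer index over a reference sequence."""

    def __init__(self, seq: str, k: int = DEFAULT_K):
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = index

    def seed_diagonals(self, query: str) -> dict[int, int]:
        """Map diagonal (r - q) -> smallest query seed offset on it."""
        k = self.k
        diags: dict[int, int] = {}
        for q in range(len(query) - k + 1):
            for r in self.index.get(query[q : q + k], ()):
                d = r - q
                if d not in diags or q < diags[d]:
                    diags[d] = q
        return diags


def _extend_seed(
    query: str, ref: str, q0: int, r0: int, k: int, xdrop: int
) -> _Segment:
    """Ungapped extension of an exact k-mer seed in both directions.

    Match +1, mismatch -1; each direction stops when the running score drops
    ``xdrop`` below the best seen, and the best-scoring endpoint is kept.
    """
    # right of the seed
    score = best = k
    qe, re_ = q0 + k, r0 + k
    best_qe, best_re = qe, re_
    while qe < len(query) and re_ < len(ref):
        score += 1 if query[qe] == ref[re_] else -1
        qe += 1
        re_ += 1
        if score > best:
            best, best_qe, best_re = score, qe, re_
        elif best - score > xdrop:
            break
    # left of the seed
    score = best2 = best
    qs, rs = q0, r0
    best_qs, best_rs = qs, rs
    while qs > 0 and rs > 0:
        score += 1 if query[qs - 1] == ref[rs - 1] else -1
        qs -= 1
        rs -= 1
        if score > best2:
            best2, best_qs, best_rs = score, qs, rs
        elif best2 - score > xdrop:
            break
    matches = sum(
        1 for a, b in zip(query[best_qs:best_qe], ref[best_rs:best_re]) if a == b
    )
    length = best_qe - best_qs
    return _Segment(
        best_qs, best_qe, best_rs, best_re,
        matches, length - matches, 2 * matches - length,
    )


def local_align(
    query: str,
    index: SeqIndex,
    min_score: int = DEFAULT_MIN_SCORE,
    xdrop: int = DEFAULT_XDROP,
) -> list[_Segment]:
    """All seeded ungapped segments of ``query`` vs the indexed reference.

    One extension per seeded diagonal (from its leftmost seed); segments
    below ``min_score`` are dropped.  Sorted best-first, ties broken by
    lowest reference position.
    """
    segments: list[_Segment] = []
    seen: set[tuple[int, int]] = set()
    for diag, q0 in sorted(index.seed_diagonals(query).items()):
        seg = _extend_seed(query, index.seq, q0, q0 + diag, index.k, xdrop)
        key = (seg.r_start, seg.r_end)
        if seg.score >= min_score and key not in seen:
            seen.add(key)
            segments.append(seg)
    segments.sort(key=lambda s: (-s.score, s.r_start))
    return segments


# ---------------------------------------------------------------------------
# LTR realignment

def realign_to_ltr(
    reads: Iterable[ReadRecord],
    ltr: LTRModel,
    k: int = DEFAULT_K,
    min_score: int = DEFAULT_MIN_SCORE,
    xdrop: int = DEFAULT_XDROP,
) -> list[ReadRecord]:
    """Realign reads to the LTR sequence; best local placement per read.

    Both strands are searched; unaligned read ends become soft-clips.  Reads
    whose best segment scores below ``min_score`` are returned unmapped.
    Minus-strand placements store the reverse-complemented sequence (SAM
    convention) with the CIGAR in reference order.  Ties between co-optimal
    placements are broken by lowest LTR position, plus strand first.
    """
    index = SeqIndex(ltr.seq, k)
    out: list[ReadRecord] = []
    for r in reads:
        seq = r.seq
        if not seq:
            continue
        best: tuple[int, int, int, _Segment, str] | None = None
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            segs = local_align(q, index, min_score, xdrop)
            if segs:
                s = segs[0]
                key = (-s.score, s.r_start, 0 if strand == "+" else 1)
                if best is None or key < best[:3]:
                    best = (*key, s, q)
        if best is None:
            out.append(
                ReadRecord(r.name, r.mate, False, None, None, 0, None, seq,
                           False, r.mate_is_mapped)
            )
            continue
        _, _, strand_rank, seg, oriented = best
        cigar: list[tuple[str, int]] = []
        if seg.q_start:
            cigar.append(("S", seg.q_start))
        cigar.append(("M", seg.q_end - seg.q_start))
        if len(oriented) - seg.q_end:
            cigar.append(("S", len(oriented) - seg.q_end))
        out.append(
            ReadRecord(
                name=r.name,
                mate=r.mate,
                is_mapped=True,
                ref_name="LTR",
                pos_1based=seg.r_start + 1,
                mq=60,
                cigar=cigar,
                seq=oriented,
                is_reverse=strand_rank == 1,
                mate_is_mapped=r.mate_is_mapped,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clip placement on the host reference

def clip_to_host(
    clip_seq: str,
    chrom_seq: str,
    window: GenomicInterval,
    flank: int = DEFAULT_FLANK,
    k: int = DEFAULT_K,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    xdrop: int = DEFAULT_XDROP,
    _index: "tuple[int, SeqIndex] | None" = None,
) -> list[LocalHit]:
    """Place a clipped sequence on the host reference near an interval.

    The search is restricted to ``window`` expanded by ``flank`` on each side
    (clamped to the chromosome); both strands are searched.  Hits are sorted
    by score, ties broken by lowest reference position then plus strand.
    ``query_start/query_end`` are always in original clip coordinates;
    ``_index`` allows callers scoring many clips against one window to reuse
    the k-mer index (as built by :func:`window_index`).
    """
    if _index is not None:
        wstart, index = _index
    else:
        wstart, index = window_index(chrom_seq, window, flank, k)
    hits: list[LocalHit] = []
    n = len(clip_seq)
    for strand, q in (("+", clip_seq), ("-", revcomp(clip_seq))):
        for seg in local_align(q, index, min_score, xdrop):
            ident = seg.matches / (seg.matches + seg.mismatches)
            if ident < min_identity:
                continue
            if strand == "+":
                qs, qe = seg.q_start, seg.q_end
            else:
                qs, qe = n - seg.q_end, n - seg.q_start
            hits.append(
                LocalHit(
                    query_start=qs,
                    query_end=qe,
                    ref_name=window.chrom,
                    ref_start=wstart + seg.r_start,
                    ref_end=wstart + seg.r_end,
                    strand=strand,
                    matches=seg.matches,
                    mismatches=seg.mismatches,
                    score=seg.score,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.ref_start, h.strand != "+"))
    return hits


def window_index(
    chrom_seq: str, window: GenomicInterval, flank: int = DEFAULT_FLANK,
    k: int = DEFAULT_K,
) -> tuple[int, SeqIndex]:
    wstart = max(0, window.start - flank)
    wend = min(len(chrom_seq), window.end + flank)
    return wstart, SeqIndex(chrom_seq[wstart:wend], k)


def breakpoint_from_clip(side: str, hit: LocalHit) -> int:
    """Junction coordinate implied by one clip's host placement.

    The clip base adjacent to the LTR junction is the clip's last base for a
    left clip and its first base for a right clip (record orientation).  If
    that base falls at the hit's high-coordinate end, the host flank runs
    leftward (left junction) and the breakpoint is the hit end; if at the
    low end, the flank runs rightward (right junction) and the breakpoint is
    the base before the hit start.  Coordinates are 1-based.
    """
    adjacent_last = side == "left"
    at_high_end = adjacent_last == (hit.strand == "+")
    if at_high_end:
        return hit.ref_end  # 1-based inclusive end == 0-based half-open end
    return hit.ref_start  # (ref_start + 1) - 1


def call_breakpoints(
    observations: Sequence[tuple[str, int]],
    cluster_id: str,
    tsd_expected: int = DEFAULT_TSD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> BreakpointCall:
    """Aggregate per-read breakpoint observations into a call.

    Observations are (chrom, position) pairs, one per placed clip.  Positions
    supported by fewer than ``min_support`` reads are treated as noise (the
    automated stand-in for manual curation of clip alignments).  If exactly
    two positions remain and their separation equals ``tsd_expected``, they
    are the two junctions of a single integration and ``tsd_len`` is set.
    Conflicting chromosomes flag the call as ambiguous with no breakpoint.
    """
    if not observations:
        return BreakpointCall(cluster_id, None, [], [], note="no observations")
    counts = Counter(observations)
    supported = {k: c for k, c in counts.items() if c >= min_support}
    if not supported:
        return BreakpointCall(
            cluster_id, None, [], [], note="insufficient support"
        )
    chroms = {chrom for chrom, _ in supported}
    if len(chroms) > 1:
        return BreakpointCall(
            cluster_id, None, [], [], ambiguous=True,
            note="conflicting chromosomes",
        )
    chrom = chroms.pop()
    positions = sorted(pos for _, pos in supported)
    support = [supported[(chrom, p)] for p in positions]
    tsd = None
    note = ""
    if len(positions) == 2 and positions[1] - positions[0] == tsd_expected:
        tsd = tsd_expected
    elif len(positions) == 2:
        note = "breakpoint separation does not match expected TSD"
    elif len(positions) > 2:
        note = "more than two breakpoint positions"
    return BreakpointCall(cluster_id, chrom, positions, support, tsd, note=note)


# ---------------------------------------------------------------------------
# LTR region coverage

def ltr_region_coverage(
    ltr_records: Iterable[ReadRecord], ltr: LTRModel
) -> RegionCoverage:
    """Fraction of U3/R/U5 positions covered by at least one aligned base."""
    depth = np.zeros(len(ltr.seq), dtype=np.int32)
    for r in ltr_records:
        if not r.is_mapped or not r.cigar:
            continue
        ptr = r.pos_1based - 1
        for op, n in r.cigar:
            if op in "M=X":
                depth[ptr : ptr + n] += 1
                ptr += n
            elif op in "DN":
                ptr += n
    fracs = {}
    for name, (a, b) in ltr.regions.items():
        region = depth[a - 1 : b]
        fracs[name] = float(np.count_nonzero(region)) / len(region)
    return RegionCoverage(fracs["u3"], fracs["r"], fracs["u5"])


# ---------------------------------------------------------------------------
# per-cluster orchestration

def retrieve_cluster_reads(
    host_sams: dict[str, str],
    clusters: Sequence[IntervalCluster],
) -> dict[str, list[ReadRecord]]:
    """Collect read pairs with a host footprint overlapping each cluster.

    Pairs are retrieved by name across all samples (both mates, including
    host-unmapped mates whose sequence is element-internal).  Two streaming
    passes per SAM: one to assign names to clusters, one to collect records.
    """
    from bisect import bisect_right

    by_chrom: dict[str, tuple[list[int], list[int], list[str]]] = {}
    for c in sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start)):
        starts, ends, ids = by_chrom.setdefault(c.interval.chrom, ([], [], []))
        starts.append(c.interval.start)
        ends.append(c.interval.end)
        ids.append(c.cluster_id)

    out: dict[str, list[ReadRecord]] = {c.cluster_id: [] for c in clusters}
    for sample, path in host_sams.items():
        name_to_clusters: dict[str, list[str]] = {}
        for rec in read_sam(path):
            if not rec.is_mapped:
                continue
            entry = by_chrom.get(rec.ref_name)
            if entry is None:
                continue
            starts, ends, ids = entry
            fp_start = rec.pos_1based - 1
            fp_end = fp_start + rec.reference_consumed()
            i = bisect_right(starts, fp_end) - 1
            # clusters are non-overlapping; a short footprint can touch at
            # most the cluster at i and its left neighbour
            for j in (i, i - 1):
                if 0 <= j and starts[j] < fp_end and fp_start < ends[j]:
                    name_to_clusters.setdefault(rec.name, []).append(ids[j])
                    break
        for rec in read_sam(path):
            targets = name_to_clusters.get(rec.name)
            if targets:
                for cid in set(targets):
                    out[cid].append(rec)
    return out


def analyze_cluster(
    cluster: IntervalCluster,
    reads: Sequence[ReadRecord],
    chrom_seq: str,
    ltr: LTRModel,
    min_clip: int = DEFAULT_MIN_CLIP,
    tsd_expected: int = DEFAULT_TSD,
    min_support: int = DEFAULT_MIN_SUPPORT,
    flank: int = DEFAULT_FLANK,
    k: int = DEFAULT_K,
    min_score: int = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[BreakpointCall, RegionCoverage]:
    """Breakpoint call and LTR region coverage for one interval."""
    ltr_recs = realign_to_ltr(reads, ltr, k=k, min_score=min_score)
    coverage = ltr_region_coverage(ltr_recs, ltr)
    widx = window_index(chrom_seq, cluster.interval, flank, k)
    observations: list[tuple[str, int]] = []
    for rec in ltr_recs:
        if not rec.is_mapped:
            continue
        for side, clip_seq, _ in softclips(rec, min_clip):
            hits = clip_to_host(
                clip_seq, chrom_seq, cluster.interval,
                flank=flank, k=k, min_score=min_score,
                min_identity=min_identity, _index=widx,
            )
            if hits:
                observations.append(
                    (cluster.interval.chrom, breakpoint_from_clip(side, hits[0]))
                )
    call = call_breakpoints(
        observations, cluster.cluster_id, tsd_expected, min_support
    )
    return call, coverage
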