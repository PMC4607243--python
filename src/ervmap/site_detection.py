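"""Per-sample integration-site detection.

The detection strategy mirrors a paired-end mapping approach for endogenous
retroviruses: reads are aligned both to the element LTR and to the host
genome; reads unmapped against the LTR but anchored by an LTR-mapped mate
evidence the host-side flanks of an integration.  Their host alignments are
filtered by mapping quality (MQ >= 20 by default), merged into features
(mergeBed semantics: overlapping or book-ended footprints chain), and
features supported by a read count below a quarter of the sample's mean
genome-wide depth are discarded.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from pathlib import Path

from .alignment_io import read_sam
from .model import GenomicInterval, IntegrationSite, ReadRecord, SampleDepth

DEFAULT_MQ_MIN = 20
DEFAULT_RC_FRAC = 0.25
DEFAULT_LINK_DIST = 5000


def candidate_reads(
    ltr_records: Iterable[ReadRecord], mate_mapped_only: bool = False
) -> set[str]:
    """Names of reads recovered from the LTR alignment for host remapping.

    By default every read that failed to map against the LTR is recovered
    (it may map to the host genome or to element sequence outside the LTR).
    With ``mate_mapped_only=True`` only reads whose mate *is* LTR-mapped are
    returned — the anchored subset appropriate when the LTR alignment covers
    the whole library rather than an element-targeted extract.
    """
    unmapped_names: set[str] = set()
    unmapped_mates: dict[str, set[int]] = {}
    mapped_mates: dict[str, set[int]] = {}
    for rec in ltr_records:
        if rec.is_mapped:
            mapped_mates.setdefault(rec.name, set()).add(rec.mate)
        else:
            unmapped_names.add(rec.name)
            unmapped_mates.setdefault(rec.name, set()).add(rec.mate)
    if not mate_mapped_only:
        return unmapped_names
    out: set[str] = set()
    for name, mates in unmapped_mates.items():
        mapped = mapped_mates.get(name, set())
        if any((3 - m) in mapped for m in mates):
            out.add(name)
    return out


def mq_filter(
    records: Iterable[ReadRecord], mq_min: int = DEFAULT_MQ_MIN
) -> list[ReadRecord]:
    """Retain mapped records with mapping quality >= ``mq_min``.

    Records with MQ below the threshold are excluded exactly ("below 20"
    excludes 19 and retains 20).
    """
    return [r for r in records if r.is_mapped and r.mq >= mq_min]


def merge_features(
    records: Iterable[ReadRecord], sample_id: str
) -> list[IntegrationSite]:
    """Merge overlapping (or book-ended) alignment footprints into sites.

    Maximal chains of pairwise-overlapping footprints become one site whose
    interval is the union span; ``read_count`` counts member reads.  Matches
    the default behaviour of interval-merging tools: a gap of exactly zero
    (book-ended features) still merges.
    """
    feats: list[tuple[str, int, int, int]] = []
    for r in records:
        fp = r.footprint()
        if fp is not None:
            feats.append((fp.chrom, fp.start, fp.end, r.mq))
    feats.sort(key=lambda t: (t[0], t[1], t[2]))
    sites: list[IntegrationSite] = []
    cur = None  # [chrom, start, end, count, mq_sum]
    for chrom, start, end, mq in feats:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] += 1
            cur[4] += mq
        else:
            if cur is not None:
                sites.append(_close_site(cur, sample_id))
            cur = [chrom, start, end, 1, mq]
    if cur is not None:
        sites.append(_close_site(cur, sample_id))
    return sites


def _close_site(cur: list, sample_id: str) -> IntegrationSite:
    chrom, start, end, count, mq_sum = cur
    return IntegrationSite(
        sample_id=sample_id,
        interval=GenomicInterval(chrom, start, end),
        read_count=count,
        mean_mq=mq_sum / count,
    )


def rc_filter(
    sites: Iterable[IntegrationSite],
    depth: SampleDepth,
    frac: float = DEFAULT_RC_FRAC,
) -> list[IntegrationSite]:
    """Exclude sites with read count strictly below ``frac * mean_depth``.

    The exclusion rule is "less than", so a site whose read count exactly
    equals the threshold is retained.
    """
    if frac <= 0:
        raise ValueError(f"rc_filter fraction must be positive, got {frac}")
    threshold = frac * depth.mean_depth
    return [s for s in sites if s.read_count >= threshold]


def mean_depth(
    records: Iterable[ReadRecord], genome_length: int, sample_id: str = ""
) -> SampleDepth:
    """Genome-wide mean depth: aligned reference-consuming bases / genome length.

    Only mapped primary reads contribute (the readers already drop
    secondary/supplementary records); no MQ filter is applied at this stage.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    total = 0
    n = 0
    for r in records:
        if r.is_mapped:
            total += r.reference_consumed()
            n += 1
    if n == 0:
        warnings.warn("no mapped reads; mean depth is 0", stacklevel=2)
    return SampleDepth(sample_id=sample_id, mean_depth=total / genome_length)


def evaluate_detection(
    detected: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    link_dist: int = DEFAULT_LINK_DIST,
) -> tuple[float | None, float | None]:
    """Sensitivity and precision of detected intervals against a truth set.

    A truth locus is recovered when some detected interval lies within
    ``link_dist`` of it (distance 0 for overlap).  Sensitivity is the
    recovered fraction of truth loci; precision the fraction of detected
    intervals matching at least one truth locus.  Empty inputs yield None
    for the corresponding undefined measure.
    """

    def linked(a: GenomicInterval, b: GenomicInterval) -> bool:
        gap = a.gap_to(b)
        return gap is not None and gap <= link_dist

    sensitivity: float | None = None
    if truth:
        recovered = sum(1 for t in truth if any(linked(d, t) for d in detected))
        sensitivity = recovered / len(truth)
    precision: float | None = None
    if detected:
        matching = sum(1 for d in detected if any(linked(d, t) for t in truth))
        precision = matching / len(detected)
    return sensitivity, precision


def detect_sites(
    host_sam: str | Path,
    ltr_sam: str | Path,
    chrom_lengths: dict[str, int],
    sample_id: str,
    mq_min: int = DEFAULT_MQ_MIN,
    rc_frac: float = DEFAULT_RC_FRAC,
    mate_mapped_only: bool = True,
) -> tuple[list[IntegrationSite], SampleDepth]:
    """Full per-sample detection from host and LTR SAM files.

    Streams the LTR alignment to recover candidate read names, then streams
    the host alignment once, simultaneously accumulating the genome-wide
    depth (over all mapped reads) and collecting candidate host alignments.
    """
    if rc_frac <= 0:
        raise ValueError(f"rc_frac must be positive, got {rc_frac}")
    candidates = candidate_reads(
        read_sam(ltr_sam), mate_mapped_only=mate_mapped_only
    )
    genome_length = sum(chrom_lengths.values())
    if genome_length <= 0:
        raise ValueError("chromosome table has zero total length")
    depth_bases = 0
    n_mapped = 0
    kept: list[ReadRecord] = []
    for rec in read_sam(host_sam):
        if rec.is_mapped:
            depth_bases += rec.reference_consumed()
            n_mapped += 1
            if rec.name in candidates and rec.mq >= mq_min:
                kept.append(rec)
    if n_mapped == 0:
        warnings.warn(f"sample {sample_id}: host SAM has no mapped reads",
                      stacklevel=2)
    depth = SampleDepth(sample_id=sample_id, mean_depth=depth_bases / genome_length)
    sites = merge_features(kept, sample_id)
    return rc_filter(sites, depth, rc_frac), depth
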