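"""Readers and writers for SAM, BED, FASTA/FASTQ, GTF and chromosome tables.

SAM parsing is delegated to :mod:`pysam` (text SAM, optionally gzipped);
records are normalised into light-weight :class:`~ervmap.model.ReadRecord`
objects.  Secondary and supplementary alignments (flags 0x100/0x800) are
skipped: the mapping-quality filter downstream targets unique placements and
secondaries would double-count read support.
"""

from __future__ import annotations

import gzip
import re
from collections.abc import Iterable, Iterator
from pathlib import Path

import pysam

from .model import GenomicInterval, ReadRecord, Transcript

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

_PYSAM_OPS = "MIDNSHP=XB"


class SamParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CIGAR

def parse_cigar(cigar: str) -> list[tuple[str, int]] | None:
    """Parse a CIGAR string into ``(op, length)`` pairs; '*' -> None."""
    if cigar == "*":
        return None
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise SamParseError(f"malformed CIGAR string: {cigar!r}")
    return ops


def cigar_to_str(cigar: list[tuple[str, int]] | None) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{op}" for op, n in cigar)


def softclips(
    record: ReadRecord, min_clip: int = 20
) -> list[tuple[str, str, int]]:
    """Extract soft-clipped segments of at least ``min_clip`` bases.

    Returns ``(side, clipped_seq, host_anchor_pos)`` tuples where ``side`` is
    ``"left"`` or ``"right"`` and ``host_anchor_pos`` is the 1-based reference
    coordinate adjacent to the clip: the alignment start for a left clip, the
    alignment end for a right clip.  Hard clips carry no sequence and are
    never returned.
    """
    if not record.is_mapped or not record.cigar:
        raise ValueError("softclips requires a mapped record with a CIGAR")
    out: list[tuple[str, str, int]] = []
    cigar = record.cigar
    seq = record.seq or ""
    # leading clip (possibly behind a hard clip)
    idx = 1 if cigar[0][0] == "H" else 0
    if idx < len(cigar) and cigar[idx][0] == "S":
        n = cigar[idx][1]
        if n >= min_clip:
            out.append(("left", seq[:n], record.pos_1based))
    jdx = len(cigar) - (2 if cigar[-1][0] == "H" else 1)
    if jdx >= 0 and cigar[jdx][0] == "S" and jdx != idx:
        n = cigar[jdx][1]
        if n >= min_clip:
            out.append(("right", seq[len(seq) - n :], record.end_1based()))
    return out


# ---------------------------------------------------------------------------
# SAM

def _record_from_pysam(aln: pysam.AlignedSegment) -> ReadRecord:
    if aln.cigartuples is None:
        cigar = None
    else:
        cigar = [(_PYSAM_OPS[op], n) for op, n in aln.cigartuples]
    mapped = not aln.is_unmapped
    return ReadRecord(
        name=aln.query_name,
        mate=2 if aln.is_read2 else 1,
        is_mapped=mapped,
        ref_name=aln.reference_name if mapped else None,
        pos_1based=aln.reference_start + 1 if mapped else None,
        mq=aln.mapping_quality,
        cigar=cigar,
        seq=aln.query_sequence,
        is_reverse=aln.is_reverse,
        mate_is_mapped=(not aln.mate_is_unmapped) if aln.is_paired else False,
    )


def read_sam(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a SAM file (with @SQ header lines) as ReadRecord objects.

    Secondary and supplementary alignments are skipped.  Malformed records
    raise :class:`SamParseError` naming the offending line.
    """
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for i, aln in enumerate(fh):
                if aln.is_secondary or aln.is_supplementary:
                    continue
                yield _record_from_pysam(aln)
    except (ValueError, OSError) as exc:  # pysam raises ValueError on bad SAM
        raise SamParseError(f"failed to parse SAM {path}: {exc}") from exc


def sam_flag(record: ReadRecord, paired: bool = True) -> int:
    flag = 0
    if paired:
        flag |= 0x1
        flag |= 0x40 if record.mate == 1 else 0x80
        if not record.mate_is_mapped:
            flag |= 0x8
    if not record.is_mapped:
        flag |= 0x4
    if record.is_reverse:
        flag |= 0x10
    return flag


def write_sam(
    records: Iterable[ReadRecord],
    chrom_lengths: dict[str, int],
    path: str | Path,
    paired: bool = True,
) -> None:
    """Write ReadRecords as a minimal valid SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in records:
            fields = [
                r.name,
                str(sam_flag(r, paired=paired)),
                r.ref_name if r.is_mapped else "*",
                str(r.pos_1based) if r.is_mapped else "0",
                str(r.mq),
                cigar_to_str(r.cigar),
                "*",
                "0",
                "0",
                r.seq or "*",
                "*",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence, entry.quality


# ---------------------------------------------------------------------------
# BED

def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Iterable[int | float] | None = None,
) -> None:
    """Write BED6 (0-based half-open); score column defaults to 0."""
    intervals = list(intervals)
    if scores is None:
        score_list: list[int | float] = [0] * len(intervals)
    else:
        score_list = list(scores)
    with open(path, "w") as fh:
        for iv, score in zip(intervals, score_list):
            name = iv.label or iv.display()
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t+\n")


def read_bed(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Read BED (>=3 columns); validates chromosomes against a length table."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise ValueError(
                        f"{path}:{lineno}: unknown chromosome {chrom!r}"
                    )
                if end > chrom_lengths[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} exceeds "
                        f"{chrom} length {chrom_lengths[chrom]}"
                    )
            label = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label))
    return out


# ---------------------------------------------------------------------------
# GTF (Ensembl dialect)

def read_gtf(path: str | Path, feature: str = "transcript") -> list[Transcript]:
    """Read transcripts from an Ensembl-style GTF.

    1-based inclusive GTF coordinates are converted to the internal 0-based
    half-open convention.  If the file carries no ``transcript`` feature
    lines, transcript extents are aggregated from ``exon`` lines.
    """
    transcripts: list[Transcript] = []
    exon_spans: dict[str, tuple[str, str, int, int]] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            seqname, _, feat, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if feat not in (feature, "exon"):
                continue
            attrs = dict(_GTF_ATTR_RE.findall(parts[8]))
            gene_id = attrs.get("gene_id", "")
            tx_id = attrs.get("transcript_id", "")
            if not tx_id:
                continue
            s0, e0 = int(start) - 1, int(end)
            if feat == feature:
                transcripts.append(
                    Transcript(gene_id, tx_id, GenomicInterval(seqname, s0, e0))
                )
            else:
                if tx_id in exon_spans:
                    c, g, a, b = exon_spans[tx_id]
                    exon_spans[tx_id] = (c, g, min(a, s0), max(b, e0))
                else:
                    exon_spans[tx_id] = (seqname, gene_id, s0, e0)
    if not transcripts:
        for tx_id, (chrom, gene_id, s0, e0) in exon_spans.items():
            transcripts.append(
                Transcript(gene_id, tx_id, GenomicInterval(chrom, s0, e0))
            )
    return transcripts


# ---------------------------------------------------------------------------
# chromosome-length table

def read_chrom_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column whitespace-delimited chromosome-length table."""
    out: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need <chrom> <length>")
            out[parts[0]] = int(parts[1])
    return out


def write_chrom_table(chrom_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
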