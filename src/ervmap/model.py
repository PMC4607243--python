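"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (``[start, end)``), the
convention of BED and of Python slicing.  SAM and GTF coordinates (1-based
inclusive) are converted at the I/O boundary, and all *displayed* coordinates
(e.g. cluster identifiers such as ``chr3:84550518-84551452``) are 1-based
inclusive, matching how genomic loci are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# CIGAR operation classes (SAM v1.6)
QUERY_CONSUMING = frozenset("MIS=X")
REFERENCE_CONSUMING = frozenset("MDN=X")
CIGAR_OPS = "MIDNSHP=X"


@dataclass(slots=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Intervening distance in bases; 0 when overlapping or book-ended.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def display(self) -> str:
        """1-based inclusive representation, e.g. ``chr1:100-200``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(slots=True)
class ReadRecord:
    """One SAM alignment line (or unmapped read).

    ``cigar`` is a list of ``(op, length)`` pairs with ``op`` one of
    ``MIDNSHP=X``.  Invariant: the query-consuming ops (M, I, S, =, X) sum to
    ``len(seq)`` whenever a sequence is present; ``pos_1based >= 1`` when
    mapped.  These are guaranteed by the readers rather than re-checked on
    every construction (records are created in bulk).
    """

    name: str
    mate: int  # 1 or 2
    is_mapped: bool
    ref_name: str | None
    pos_1based: int | None
    mq: int
    cigar: list[tuple[str, int]] | None
    seq: str | None
    is_reverse: bool = False
    mate_is_mapped: bool = True

    def query_consumed(self) -> int:
        if not self.cigar:
            return 0
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    def reference_consumed(self) -> int:
        if not self.cigar:
            return 0
        return sum(n for op, n in self.cigar if op in REFERENCE_CONSUMING)

    def end_1based(self) -> int | None:
        """1-based inclusive reference coordinate of the last aligned base."""
        if not self.is_mapped or self.pos_1based is None:
            return None
        return self.pos_1based + self.reference_consumed() - 1

    def footprint(self) -> GenomicInterval | None:
        """Reference span covered by the alignment (0-based half-open)."""
        if not self.is_mapped or self.pos_1based is None or not self.cigar:
            return None
        start = self.pos_1based - 1
        return GenomicInterval(self.ref_name, start, start + self.reference_consumed())


@dataclass(slots=True)
class Transcript:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval


@dataclass(slots=True)
class LTRModel:
    """An LTR sequence with its U3/R/U5 partition (1-based inclusive ranges).

    The three sub-regions must be ordered, contiguous and jointly tile the
    whole sequence; the default partition follows the 287-bp EAV-HP LTR:
    U3 = 1-146, R = 147-163, U5 = 164-287.
    """

    seq: str
    u3: tuple[int, int] = (1, 146)
    r: tuple[int, int] = (147, 163)
    u5: tuple[int, int] = (164, 287)

    def __post_init__(self) -> None:
        ranges = [self.u3, self.r, self.u5]
        if self.u3[0] != 1:
            raise ValueError("U3 must start at position 1")
        for (a, b), (c, d) in zip(ranges, ranges[1:]):
            if not (a <= b and c == b + 1 and c <= d):
                raise ValueError("U3/R/U5 ranges must be ordered and contiguous")
        if self.u5[1] != len(self.seq):
            raise ValueError(
                f"U3/R/U5 ranges must tile the LTR (got end {self.u5[1]}, "
                f"sequence length {len(self.seq)})"
            )

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"u3": self.u3, "r": self.r, "u5": self.u5}


@dataclass(slots=True)
class IntegrationSite:
    """A per-sample merged feature supported by element-linked reads."""

    sample_id: str
    interval: GenomicInterval
    read_count: int
    mean_mq: float = 0.0

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("integration site requires read_count >= 1")


@dataclass(slots=True)
class SampleDepth:
    """Genome-wide mean depth of coverage for one sample (muX_i)."""

    sample_id: str
    mean_depth: float


@dataclass(slots=True)
class IntervalCluster:
    """A cross-sample interval: the min/max span of its member sites.

    ``frequency`` is the fraction of analysed samples carrying the interval.
    """

    interval: GenomicInterval
    members: dict[str, list[IntegrationSite]] = field(default_factory=dict)
    frequency: float = 0.0

    @property
    def cluster_id(self) -> str:
        return self.interval.display()

    @property
    def samples_present(self) -> list[str]:
        return sorted(self.members)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass(slots=True)
class LocalHit:
    """One local alignment of a (clipped) query against a reference window."""

    query_start: int
    query_end: int
    ref_name: str
    ref_start: int  # 0-based half-open, absolute chromosome coordinates
    ref_end: int
    strand: str  # '+' or '-'
    matches: int
    mismatches: int
    score: int

    @property
    def identity(self) -> float:
        aligned = self.matches + self.mismatches
        return self.matches / aligned if aligned else 0.0


@dataclass(slots=True)
class BreakpointCall:
    """Inferred host-genome junction position(s) for one interval.

    ``breakpoints`` are 1-based host coordinates of the junction (the host
    base immediately 5' of the element on each side).  When exactly two
    positions are observed and their separation equals the expected
    target-site duplication length, both belong to a single integration and
    ``tsd_len`` is set.
    """

    cluster_id: str
    chrom: str | None
    breakpoints: list[int]
    support: list[int]
    tsd_len: int | None = None
    ambiguous: bool = False
    note: str = ""


@dataclass(slots=True)
class RegionCoverage:
    """Fractions of LTR region positions covered by >= 1 read."""

    u3_frac: float
    r_frac: float
    u5_frac: float

    @property
    def full_ltr(self) -> bool:
        return self.u3_frac == 1.0 and self.r_frac == 1.0 and self.u5_frac == 1.0


@dataclass(slots=True)
class TruthRecord:
    """Ground truth for one implanted element (simulator bookkeeping).

    ``junction_pos`` is the 1-based coordinate of the last host base before
    the insertion point in the *original* host reference; with a TSD of
    length t the two junction breakpoints of the insertion are expected at
    ``junction_pos`` and ``junction_pos + t``.
    """

    chrom: str
    junction_pos: int
    tsd_len: int
    element_orientation: str  # '+' or '-'
    full_element: bool = True

    def window(self, pad: int = 0) -> GenomicInterval:
        start = max(0, self.junction_pos - 1 - pad)
        return GenomicInterval(
            self.chrom, start, self.junction_pos + self.tsd_len + pad
        )
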