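"""Synthetic test universe: genomes, implanted proviruses and read libraries.

The simulator builds a random multi-chromosome host genome, implants
LTR-flanked elements with target-site duplications, and samples paired-end
reads from the modified genome.  Because every read's true origin is known,
the simulator doubles as a truth aligner: it emits the SAM records an ideal
aligner would produce against the *unmodified* host reference (junction
reads soft-clipped, element-internal reads unmapped) and against the element
LTR (reads overlapping an LTR copy mapped, everything else unmapped).  Real
data enters the pipeline as SAM from any external aligner; these truth
alignments exist so every stage can be validated without downloads.

Insertion geometry: an insertion after 1-based host position p with TSD
length t duplicates host bases p+1..p+t on both sides of the element, so
the modified chromosome reads ``host[1..p+t] + element + host[p+1..]``.
The two junction breakpoints of such an insertion are p + t (left) and p
(right), exactly t apart.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import GenomicInterval, LTRModel, TruthRecord
from .alignment_io import write_chrom_table, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class SimulationConfig:
    """Study conditions for the synthetic universe.

    Defaults describe a desk-scale genome that still exercises every
    pipeline stage: three 1-Mb chromosomes carrying 20 insertions of a
    ~4.3-kb element whose 287-bp LTRs follow the U3/R/U5 partition
    1-146/147-163/164-287, sequenced at 30x with 100-bp paired reads,
    400 +/- 50 bp inserts and a 0.2% substitution error rate.
    """

    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000, 1_000_000)
    n_integrations: int = 20
    tsd_len: int = 6
    ltr_len: int = 287
    element_len: int = 4302
    read_len: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    depth: float = 30.0
    error_rate: float = 0.002
    seed: int = 42
    min_spacing: int = 20_000
    edge_margin: int = 10_000
    min_anchor: int = 20

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.element_len < 2 * self.ltr_len + 1:
            raise ValueError("element must be longer than its two LTRs")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_lengths)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(slots=True)
class _Segment:
    """One block of a modified chromosome.

    ``kind`` is "host" (payload = 0-based start in the original chromosome)
    or "elem" (payload = (orientation, truth index)).
    """

    mod_start: int
    mod_end: int
    kind: str
    payload: object


@dataclass(slots=True)
class ModifiedChrom:
    seq: str
    segments: list[_Segment]
    seg_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seg_starts = [s.mod_start for s in self.segments]

    def parts(self, start: int, end: int) -> list[tuple[int, int, _Segment]]:
        """Decompose a modified-coordinate span into per-segment pieces.

        Returns ``(read_offset, length, segment)`` tuples covering
        ``[start, end)`` in order.
        """
        out = []
        i = bisect_right(self.seg_starts, start) - 1
        pos = start
        while pos < end:
            seg = self.segments[i]
            take = min(end, seg.mod_end) - pos
            out.append((pos - start, take, seg))
            pos += take
            i += 1
        return out


@dataclass(slots=True)
class Simulation:
    """A simulated host genome with implanted elements and full truth."""

    config: SimulationConfig
    genome: dict[str, str]
    modified: dict[str, ModifiedChrom]
    truth: list[TruthRecord]
    element_seq: str
    ltr_model: LTRModel

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def truth_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(
                t.chrom, max(0, t.junction_pos - 1),
                t.junction_pos + t.tsd_len, label=f"ins{i + 1}",
            )
            for i, t in enumerate(self.truth)
        ]

    # -- writers ---------------------------------------------------------
    def write_host_fasta(self, path: str | Path) -> None:
        write_fasta(self.genome, path)

    def write_modified_fasta(self, path: str | Path) -> None:
        write_fasta({c: m.seq for c, m in self.modified.items()}, path)

    def write_ltr_fasta(self, path: str | Path) -> None:
        write_fasta({"LTR": self.ltr_model.seq}, path)

    def write_chrom_table(self, path: str | Path) -> None:
        write_chrom_table(self.chrom_lengths, path)

    def write_truth_bed(self, path: str | Path) -> None:
        from .alignment_io import write_bed

        write_bed(self.truth_intervals(), path)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """I.i.d. uniform-nucleotide chromosomes; deterministic under the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return {
        name: _random_seq(rng, length)
        for name, length in zip(config.chrom_names, config.chrom_lengths)
    }


def make_element(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, LTRModel]:
    """Random LTR-internal-LTR element with identical terminal LTR copies."""
    ltr = _random_seq(rng, config.ltr_len)
    internal = _random_seq(rng, config.element_len - 2 * config.ltr_len)
    u3_end = min(146, config.ltr_len - 2)
    r_end = min(163, config.ltr_len - 1)
    model = LTRModel(ltr, (1, u3_end), (u3_end + 1, r_end), (r_end + 1, config.ltr_len))
    return ltr + internal + ltr, model


def _sample_positions(
    rng: np.random.Generator, length: int, k: int, spacing: int, margin: int
) -> list[int]:
    lo, hi = margin, length - margin
    if hi - lo < (k - 1) * spacing:
        raise ValueError(
            f"cannot place {k} integrations {spacing} bp apart on a "
            f"{length} bp chromosome"
        )
    for _ in range(1000):
        pos = np.sort(rng.integers(lo, hi, size=k))
        if k < 2 or np.all(np.diff(pos) >= spacing):
            return [int(p) for p in pos]
    raise ValueError("failed to place integrations with required spacing")


def implant(
    genome: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    element_seq: str,
) -> tuple[dict[str, ModifiedChrom], list[TruthRecord]]:
    """Insert elements with TSDs at spaced random positions.

    Each insertion site is at least ``min_spacing`` from its neighbours so
    truth loci stay distinct under the 5-kb interval clustering.
    """
    chroms = list(genome)
    weights = np.array([len(genome[c]) for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=config.n_integrations,
                            p=weights / weights.sum())
    counts = {c: int((assignment == i).sum()) for i, c in enumerate(chroms)}
    t = config.tsd_len
    truth: list[TruthRecord] = []
    modified: dict[str, ModifiedChrom] = {}
    for chrom in chroms:
        host = genome[chrom]
        k = counts[chrom]
        positions = (
            _sample_positions(rng, len(host), k, config.min_spacing,
                              config.edge_margin)
            if k else []
        )
        parts: list[str] = []
        segments: list[_Segment] = []
        prev = 0
        mod_pos = 0
        for p in positions:
            orientation = "+" if rng.random() < 0.5 else "-"
            truth.append(TruthRecord(chrom, p, t, orientation))
            chunk = host[prev : p + t]
            parts.append(chunk)
            segments.append(_Segment(mod_pos, mod_pos + len(chunk), "host", prev))
            mod_pos += len(chunk)
            eseq = element_seq if orientation == "+" else _revcomp(element_seq)
            parts.append(eseq)
            segments.append(
                _Segment(mod_pos, mod_pos + len(eseq), "elem",
                         (orientation, len(truth) - 1))
            )
            mod_pos += len(eseq)
            prev = p
        chunk = host[prev:]
        parts.append(chunk)
        segments.append(_Segment(mod_pos, mod_pos + len(chunk), "host", prev))
        modified[chrom] = ModifiedChrom("".join(parts), segments)
    truth.sort(key=lambda tr: (tr.chrom, tr.junction_pos))
    return modified, truth


def _screen_element(element_seq: str, genome: dict[str, str],
                    rng: np.random.Generator, k: int = 50, n: int = 20) -> None:
    """Spot-check that the element shares no exact k-mers with the host."""
    starts = rng.integers(0, len(element_seq) - k + 1, size=n)
    for s in starts:
        kmer = element_seq[int(s) : int(s) + k]
        for seq in genome.values():
            if kmer in seq:
                raise ValueError(
                    "element sequence collides with host genome; "
                    "re-run with a different seed"
                )


def simulate(config: SimulationConfig | None = None) -> Simulation:
    """Full deterministic simulation: genome, element, implantation."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    element_seq, ltr_model = make_element(config, rng)
    _screen_element(element_seq, genome, rng)
    modified, truth = implant(genome, config, rng, element_seq)
    return Simulation(config, genome, modified, truth, element_seq, ltr_model)


# ---------------------------------------------------------------------------
# read simulation / truth aligner

def _flag(mate: int, mapped: bool, reverse: bool, mate_mapped: bool,
          mate_reverse: bool) -> int:
    f = 0x1 | (0x40 if mate == 1 else 0x80)
    if not mapped:
        f |= 0x4
    if not mate_mapped:
        f |= 0x8
    if reverse:
        f |= 0x10
    if mate_reverse:
        f |= 0x20
    return f


def _ltr_overlap(
    eF_start: int, eF_end: int, element_len: int, ltr_len: int, min_anchor: int
) -> tuple[int, int] | None:
    """Best overlap of an element-forward span with either LTR copy.

    Returns the overlapping (element-forward) span, or None if neither copy
    is overlapped by at least ``min_anchor`` bases.
    """
    best = None
    for c_start, c_end in ((0, ltr_len), (element_len - ltr_len, element_len)):
        a, b = max(eF_start, c_start), min(eF_end, c_end)
        if b - a >= min_anchor and (best is None or b - a > best[1] - best[0]):
            best = (a, b)
    return best


def simulate_reads(
    sim: Simulation,
    seed: int,
    host_sam: str | Path,
    ltr_sam: str | Path,
    sample_id: str = "S1",
    fastq_prefix: str | Path | None = None,
) -> dict[str, int]:
    """Sample a paired-end library and write truth SAM files.

    Fragment count per chromosome targets ``depth``; fragment lengths are
    normal(insert_mean, insert_sd) clipped to [read_len, chromosome length].
    Substitution errors only.  The same errored sequences appear in the host
    SAM, the LTR SAM and the optional FASTQ pair, so the three views of one
    library are mutually consistent.
    """
    cfg = sim.config
    rng = np.random.default_rng(seed)
    rl = cfg.read_len
    elen = len(sim.element_seq)
    host_lines: list[str] = []
    ltr_lines: list[str] = []
    fq1: list[str] = []
    fq2: list[str] = []
    n_pairs = 0
    qual = "I" * rl

    for chrom, mod in sim.modified.items():
        mlen = len(mod.seq)
        n_frags = int(round(cfg.depth * mlen / (2 * rl)))
        frag_lens = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frags)),
            rl, mlen,
        ).astype(np.int64)
        starts = rng.integers(0, mlen - frag_lens + 1)
        n_err = rng.binomial(rl, cfg.error_rate, size=(n_frags, 2))
        for i in range(n_frags):
            s, fl = int(starts[i]), int(frag_lens[i])
            name = f"{sample_id}.{chrom}.{i}"
            spans = ((s, s + rl), (s + fl - rl, s + fl))
            recs = []
            for mate in (1, 2):
                rs, re_ = spans[mate - 1]
                seq = mod.seq[rs:re_]
                k_err = int(n_err[i, mate - 1])
                if k_err:
                    seq = _inject_errors(seq, k_err, rng)
                recs.append(_classify_read(
                    mod, rs, seq, mate, chrom, elen, cfg, sim,
                ))
            _emit_pair(name, recs, chrom, host_lines, ltr_lines)
            if fastq_prefix is not None:
                r1, r2 = recs[0]["seq"], recs[1]["seq"]
                fq1.append(f"@{name}/1\n{r1}\n+\n{qual}")
                fq2.append(f"@{name}/2\n{_revcomp(r2)}\n+\n{qual}")
            n_pairs += 1

    _write_sam_lines(host_sam, sim.chrom_lengths, host_lines)
    _write_sam_lines(ltr_sam, {"LTR": cfg.ltr_len}, ltr_lines)
    if fastq_prefix is not None:
        Path(f"{fastq_prefix}_R1.fq").write_text("\n".join(fq1) + "\n")
        Path(f"{fastq_prefix}_R2.fq").write_text("\n".join(fq2) + "\n")
    return {"sample_id": sample_id, "n_pairs": n_pairs}


def _inject_errors(seq: str, k: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.integers(0, len(seq), size=k)
    for p in positions:
        p = int(p)
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _classify_read(
    mod: ModifiedChrom,
    rs: int,
    seq: str,
    mate: int,
    chrom: str,
    elen: int,
    cfg: SimulationConfig,
    sim: Simulation,
) -> dict:
    """Truth alignment of one read against host and LTR references."""
    rl = len(seq)
    parts = mod.parts(rs, rs + rl)
    host_parts = [(ro, ln, seg) for ro, ln, seg in parts if seg.kind == "host"]
    elem_parts = [(ro, ln, seg) for ro, ln, seg in parts if seg.kind == "elem"]

    rec: dict = {"seq": seq, "mate": mate, "reverse": mate == 2}
    # --- host view
    if len(host_parts) == 1 and host_parts[0][1] >= cfg.min_anchor:
        ro, ln, seg = host_parts[0]
        pos = seg.payload + (rs + ro - seg.mod_start) + 1
        cigar = []
        if ro:
            cigar.append(f"{ro}S")
        cigar.append(f"{ln}M")
        if rl - ro - ln:
            cigar.append(f"{rl - ro - ln}S")
        rec["host"] = (chrom, pos, "".join(cigar))
    else:
        rec["host"] = None
    # --- LTR view
    rec["ltr"] = None
    if elem_parts:
        ro, ln, seg = elem_parts[0]
        orientation, _ = seg.payload
        off = rs + ro - seg.mod_start
        if orientation == "+":
            ef_start, ef_end = off, off + ln
        else:
            ef_start, ef_end = elen - off - ln, elen - off
        ov = _ltr_overlap(ef_start, ef_end, elen, cfg.ltr_len, cfg.min_anchor)
        if ov is not None:
            a, b = ov
            la = a if a < cfg.ltr_len else a - (elen - cfg.ltr_len)
            ol = b - a
            if orientation == "+":
                r2s = ro + (a - off)
                out_seq = seq
                left_clip = r2s
            else:
                r2s = ro + (elen - b - off)
                out_seq = _revcomp(seq)
                left_clip = rl - (r2s + ol)
            cigar = []
            if left_clip:
                cigar.append(f"{left_clip}S")
            cigar.append(f"{ol}M")
            right_clip = rl - left_clip - ol
            if right_clip:
                cigar.append(f"{right_clip}S")
            ltr_reverse = (orientation == "-") != (mate == 2)
            rec["ltr"] = (la + 1, "".join(cigar), out_seq, ltr_reverse)
    return rec


def _emit_pair(
    name: str,
    recs: list[dict],
    chrom: str,
    host_lines: list[str],
    ltr_lines: list[str],
) -> None:
    # host SAM: SEQ in reference-forward orientation for mapped reads,
    # as-sequenced for unmapped ones
    for rec, other in ((recs[0], recs[1]), (recs[1], recs[0])):
        mate = rec["mate"]
        if rec["host"] is not None:
            ref, pos, cigar = rec["host"]
            flag = _flag(mate, True, rec["reverse"], other["host"] is not None,
                         other["reverse"] if other["host"] else False)
            if other["host"] is not None:
                rnext, pnext = "=", other["host"][1]
            else:
                rnext, pnext = "*", 0
            host_lines.append(
                f"{name}\t{flag}\t{ref}\t{pos}\t60\t{cigar}\t{rnext}\t{pnext}"
                f"\t0\t{rec['seq']}\t*"
            )
        else:
            flag = _flag(mate, False, False, other["host"] is not None, False)
            seq = rec["seq"] if mate == 1 else _revcomp(rec["seq"])
            host_lines.append(
                f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*"
            )
        if rec["ltr"] is not None:
            pos, cigar, out_seq, reverse = rec["ltr"]
            flag = _flag(mate, True, reverse, other["ltr"] is not None,
                         other["ltr"][3] if other["ltr"] else False)
            ltr_lines.append(
                f"{name}\t{flag}\tLTR\t{pos}\t60\t{cigar}\t*\t0\t0"
                f"\t{out_seq}\t*"
            )
        else:
            flag = _flag(mate, False, False, other["ltr"] is not None, False)
            ltr_lines.append(f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t*\t*")


def _write_sam_lines(
    path: str | Path, chrom_lengths: dict[str, int], lines: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c, l in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{l}\n")
        if lines:
            fh.write("\n".join(lines) + "\n")


def replicate_libraries(
    sim: Simulation,
    out_dir: str | Path,
    seeds: tuple[int, int] = (1, 2),
    sample_ids: tuple[str, str] = ("lib1", "lib2"),
    fastq: bool = False,
) -> dict[str, dict[str, Path]]:
    """Two independent libraries from one genome (same truth, new sampling)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, dict[str, Path]] = {}
    for seed, sample_id in zip(seeds, sample_ids):
        host = out_dir / f"{sample_id}.host.sam"
        ltr = out_dir / f"{sample_id}.ltr.sam"
        prefix = out_dir / sample_id if fastq else None
        simulate_reads(sim, seed, host, ltr, sample_id=sample_id,
                       fastq_prefix=prefix)
        out[sample_id] = {"host_sam": host, "ltr_sam": ltr}
    return out
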