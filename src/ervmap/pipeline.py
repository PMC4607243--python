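"""End-to-end orchestration: detect -> cluster -> breakpoint -> compare.

All thresholds live in :class:`PipelineConfig`; the defaults are the
method's canonical operating point (MQ >= 20, read count >= 0.25 x mean
depth, 5-kb interval clustering, >= 20-base soft-clips, 6-bp target-site
duplication, 5-kb transcript proximity).  A run writes stable filenames
into the output directory plus a machine-readable ``report.json``; rerun
with identical inputs is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment_io import (
    read_chrom_table,
    read_fasta,
    read_gtf,
    write_bed,
)
from .breakpoint_inference import analyze_cluster, retrieve_cluster_reads
from .comparative_analysis import (
    binary_distance,
    length_correlation,
    proximity_fraction,
    transcript_proximity,
    transcribed_fraction,
    tree_to_edges,
    tree_to_newick,
    ward_cluster,
)
from .interval_clustering import cluster_sites, presence_matrix
from .model import IntegrationSite, IntervalCluster, LTRModel
from .site_detection import detect_sites

log = logging.getLogger("ervmap")


class InputError(ValueError):
    """Missing or mutually inconsistent pipeline inputs."""


@dataclass(slots=True)
class PipelineConfig:
    mq_min: int = 20
    rc_frac: float = 0.25
    cluster_gap: int = 5000
    min_clip: int = 20
    tsd_expected: int = 6
    proximity_dist: int = 5000
    min_support: int = 2
    seed: int = 0
    mate_mapped_only: bool = True

    def __post_init__(self) -> None:
        for name in ("mq_min", "rc_frac", "cluster_gap", "min_clip",
                     "tsd_expected", "proximity_dist", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"pipeline threshold {name} must be positive")


@dataclass(slots=True)
class PipelineInputs:
    samples: list[tuple[str, str, str]]  # (sample_id, host_sam, ltr_sam)
    chrom_table: str
    host_fasta: str | None = None
    ltr_fasta: str | None = None
    ltr_regions: tuple[tuple[int, int], ...] = ((1, 146), (147, 163), (164, 287))
    gtf: str | None = None
    populations: dict[str, str] = field(default_factory=dict)


@dataclass(slots=True)
class PipelineResult:
    sites: dict[str, list[IntegrationSite]]
    depths: dict[str, float]
    clusters: list[IntervalCluster]
    matrix: pd.DataFrame
    breakpoints: pd.DataFrame | None
    correlation: tuple[float, float | None, int] | None
    proximity: pd.DataFrame | None
    report: dict


def _require(path: str | None, what: str) -> None:
    if path is not None and not Path(path).exists():
        raise InputError(f"{what} not found: {path}")


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "ervmap_out",
) -> PipelineResult:
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- validate everything before any stage runs
    _require(inputs.chrom_table, "chromosome table")
    for sample_id, host_sam, ltr_sam in inputs.samples:
        _require(host_sam, f"host SAM for {sample_id}")
        _require(ltr_sam, f"LTR SAM for {sample_id}")
    for path, what in ((inputs.host_fasta, "host FASTA"),
                       (inputs.ltr_fasta, "LTR FASTA"),
                       (inputs.gtf, "GTF")):
        _require(path, what)
    chrom_lengths = read_chrom_table(inputs.chrom_table)
    host_seqs = None
    if inputs.host_fasta:
        host_seqs = read_fasta(inputs.host_fasta)
        if set(host_seqs) != set(chrom_lengths):
            missing = sorted(set(chrom_lengths) - set(host_seqs))
            extra = sorted(set(host_seqs) - set(chrom_lengths))
            raise InputError(
                "chromosome naming mismatch between FASTA and table: "
                f"missing from FASTA {missing}, extra in FASTA {extra}"
            )

    report: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "samples": [s for s, _, _ in inputs.samples],
        "stages": {},
    }

    # -- stage 1: per-sample site detection
    t0 = time.perf_counter()
    sites: dict[str, list[IntegrationSite]] = {}
    depths: dict[str, float] = {}
    for sample_id, host_sam, ltr_sam in inputs.samples:
        s, depth = detect_sites(
            host_sam, ltr_sam, chrom_lengths, sample_id,
            mq_min=config.mq_min, rc_frac=config.rc_frac,
            mate_mapped_only=config.mate_mapped_only,
        )
        sites[sample_id] = s
        depths[sample_id] = depth.mean_depth
        write_bed(
            [st.interval for st in s],
            out / f"sites.{sample_id}.bed",
            scores=[st.read_count for st in s],
        )
    report["stages"]["detect"] = {
        "sites_per_sample": {k: len(v) for k, v in sites.items()},
        "mean_depth": {k: round(v, 4) for k, v in depths.items()},
    }
    log.info("detect: %d samples in %.1fs", len(sites), time.perf_counter() - t0)

    # -- stage 2: cross-sample interval clustering
    t0 = time.perf_counter()
    all_sites = [s for sample in sites.values() for s in sample]
    sample_ids = [s for s, _, _ in inputs.samples]
    clusters = cluster_sites(all_sites, sample_ids, gap=config.cluster_gap)
    matrix = presence_matrix(clusters, sample_ids)
    write_bed(
        [c.interval for c in clusters],
        out / "clusters.bed",
        scores=[c.n_sites for c in clusters],
    )
    matrix.to_csv(out / "matrix.tsv", sep="\t")
    report["stages"]["cluster"] = {
        "n_sites": len(all_sites),
        "n_clusters": len(clusters),
    }
    log.info("cluster: %d intervals in %.1fs", len(clusters),
             time.perf_counter() - t0)

    # -- stage 3: breakpoints and LTR coverage (needs host + LTR references)
    breakpoints_df = None
    if host_seqs is not None and inputs.ltr_fasta:
        t0 = time.perf_counter()
        ltr_seq = next(iter(read_fasta(inputs.ltr_fasta).values()))
        u3, r, u5 = inputs.ltr_regions
        ltr_model = LTRModel(ltr_seq, u3, r, u5)
        host_sams = {s: h for s, h, _ in inputs.samples}
        cluster_reads = retrieve_cluster_reads(host_sams, clusters)
        rows = []
        for c in clusters:
            call, cov = analyze_cluster(
                c, cluster_reads[c.cluster_id], host_seqs[c.interval.chrom],
                ltr_model, min_clip=config.min_clip,
                tsd_expected=config.tsd_expected,
                min_support=config.min_support,
                flank=config.cluster_gap,
            )
            rows.append({
                "cluster_id": c.cluster_id,
                "chrom": call.chrom,
                "breakpoints": ",".join(map(str, call.breakpoints)),
                "tsd_len": call.tsd_len,
                "support": ",".join(map(str, call.support)),
                "u3_frac": round(cov.u3_frac, 4),
                "r_frac": round(cov.r_frac, 4),
                "u5_frac": round(cov.u5_frac, 4),
                "note": call.note,
            })
        breakpoints_df = pd.DataFrame(rows)
        breakpoints_df.to_csv(out / "breakpoints.tsv", sep="\t", index=False)
        n_tsd = int((breakpoints_df["tsd_len"].notna()).sum()) if rows else 0
        report["stages"]["breakpoint"] = {
            "n_called": sum(1 for r_ in rows if r_["breakpoints"]),
            "n_tsd": n_tsd,
        }
        log.info("breakpoint: %d clusters in %.1fs", len(clusters),
                 time.perf_counter() - t0)

    # -- stage 4: comparative analyses
    correlation = None
    proximity_df = None
    if len(sample_ids) >= 2:
        dmat = binary_distance(matrix)
        pd.DataFrame(dmat.d, index=dmat.labels, columns=dmat.labels).to_csv(
            out / "dist.tsv", sep="\t"
        )
        tree = ward_cluster(dmat)
        (out / "tree.nwk").write_text(tree_to_newick(tree) + "\n")
        edges = tree_to_edges(tree)
        pd.DataFrame(edges, columns=["parent", "child", "length"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.interval.chrom] = counts.get(c.interval.chrom, 0) + 1
    if len(chrom_lengths) >= 3:
        correlation = length_correlation(counts, chrom_lengths)
        pd.DataFrame(
            [{"r": correlation[0], "p": correlation[1], "n": correlation[2]}]
        ).to_csv(out / "correlation.tsv", sep="\t", index=False)
    if inputs.gtf:
        transcripts = read_gtf(inputs.gtf)
        proximity_df = transcript_proximity(
            clusters, transcripts, max_dist=config.proximity_dist
        )
        proximity_df.to_csv(out / "proximity.tsv", sep="\t", index=False)
        genome_length = sum(chrom_lengths.values())
        report["stages"]["compare"] = {
            "proximity_fraction": round(proximity_fraction(proximity_df), 4),
            "transcribed_fraction": round(
                transcribed_fraction(transcripts, genome_length), 4
            ),
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        sites=sites,
        depths=depths,
        clusters=clusters,
        matrix=matrix,
        breakpoints=breakpoints_df,
        correlation=correlation,
        proximity=proximity_df,
        report=report,
    )
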