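"""Population-level analyses of the interval presence/absence matrix.

Samples are compared through the Euclidean distance between their binary
presence rows (the square root of the Hamming count), clustered with Ward's
minimum variance method, and exported as a Newick tree or an edge list.
Further summaries: Pearson correlation of per-chromosome interval counts
against chromosome length, nearest-transcript proximity of intervals, and
the transcribed fraction of the genome.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .model import IntervalCluster, Transcript

DEFAULT_PROXIMITY_DIST = 5000


@dataclass(slots=True)
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass(slots=True)
class MergeTree:
    """Agglomerative merge sequence (scipy linkage encoding).

    ``merges[i] = (left, right, height, size)``; indices < n refer to
    leaves, index n + i to the cluster formed at merge i.
    """

    leaves: list[str]
    merges: np.ndarray  # (n-1, 4) linkage matrix


def binary_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between binary presence rows.

    For 0/1 rows this is ``sqrt(number of differing intervals)``.
    """
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(matrix.index), d)


def ward_cluster(dmat: DistanceMatrix) -> MergeTree:
    """Ward's minimum variance agglomerative clustering.

    Uses the Lance–Williams Ward update (scipy's ``linkage`` with
    ``method="ward"``, identical to R ``hclust``'s ``ward.D2`` on a
    Euclidean distance matrix); deterministic for a fixed input.
    """
    DistanceMatrix(dmat.labels, dmat.d)  # re-validate (symmetry, diagonal)
    if len(dmat.labels) < 2:
        raise ValueError("need at least two samples to cluster")
    z = linkage(squareform(dmat.d, checks=False), method="ward")
    return MergeTree(list(dmat.labels), z)


def _node_heights(tree: MergeTree) -> list[float]:
    n = len(tree.leaves)
    heights = [0.0] * n + [float(m[2]) for m in tree.merges]
    return heights


def tree_to_newick(tree: MergeTree) -> str:
    """Newick string with branch lengths derived from merge heights.

    Each node sits at its merge height (leaves at 0); a branch length is the
    height difference between a node and its parent.
    """
    n = len(tree.leaves)
    heights = _node_heights(tree)

    def render(idx: int, parent_height: float) -> str:
        length = parent_height - heights[idx]
        if idx < n:
            return f"{tree.leaves[idx]}:{length:.6g}"
        left, right = int(tree.merges[idx - n][0]), int(tree.merges[idx - n][1])
        h = heights[idx]
        return f"({render(left, h)},{render(right, h)}):{length:.6g}"

    root = n + len(tree.merges) - 1
    h_root = heights[root]
    left, right = int(tree.merges[-1][0]), int(tree.merges[-1][1])
    return f"({render(left, h_root)},{render(right, h_root)});"


def tree_to_edges(tree: MergeTree) -> list[tuple[str, str, float]]:
    """Edge list (parent, child, length): 2n-2 edges for n leaves."""
    n = len(tree.leaves)
    heights = _node_heights(tree)

    def name(idx: int) -> str:
        return tree.leaves[idx] if idx < n else f"node{idx - n + 1}"

    edges: list[tuple[str, str, float]] = []
    for i, (left, right, _, _) in enumerate(tree.merges):
        parent = name(n + i)
        for child in (int(left), int(right)):
            edges.append((parent, name(child), heights[n + i] - heights[child]))
    return edges


def length_correlation(
    counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    per_mb: bool = False,
) -> tuple[float, float | None, int]:
    """Pearson correlation of per-chromosome interval counts vs length.

    Chromosomes in ``chrom_lengths`` missing from ``counts`` contribute a
    count of zero.  With ``per_mb`` the counts are first normalised to
    intervals per megabase ("density" in the strict sense).  Returns
    ``(r, p, n)``; the two-sided p-value comes from the t-distribution with
    n - 2 degrees of freedom and is None for n < 3.
    """
    chroms = sorted(chrom_lengths)
    x = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    y = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    if per_mb:
        y = y / (x / 1e6)
    n = len(chroms)
    if n < 2:
        raise ValueError("need at least two chromosomes")
    if np.std(x) == 0 or np.std(y) == 0:
        # constant input: the coefficient is undefined
        return float("nan"), None, n
    if n < 3:
        r = float(pearsonr(x, y).statistic)
        return r, None, n
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def transcript_proximity(
    clusters: Sequence[IntervalCluster],
    transcripts: Sequence[Transcript],
    max_dist: int = DEFAULT_PROXIMITY_DIST,
) -> pd.DataFrame:
    """Nearest transcript per interval and a within-``max_dist`` flag.

    Distance is 0 for overlap, otherwise the minimal gap to a transcript
    boundary; ``within`` means distance <= ``max_dist`` (a gap of exactly
    5000 counts as within, 5001 does not).
    """
    by_chrom: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    rows = []
    for c in clusters:
        best_t: Transcript | None = None
        best_d: int | None = None
        for t in by_chrom.get(c.interval.chrom, ()):
            d = c.interval.gap_to(t.interval)
            if best_d is None or d < best_d or (
                d == best_d and t.transcript_id < best_t.transcript_id
            ):
                best_t, best_d = t, d
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "transcript_id": best_t.transcript_id if best_t else None,
                "gene_id": best_t.gene_id if best_t else None,
                "distance": best_d,
                "within": best_d is not None and best_d <= max_dist,
            }
        )
    return pd.DataFrame(rows)


def proximity_fraction(proximity: pd.DataFrame) -> float:
    """Fraction of intervals within the proximity distance of a transcript."""
    if proximity.empty:
        return 0.0
    return float(proximity["within"].mean())


def transcribed_fraction(
    transcripts: Sequence[Transcript],
    genome_length: int,
    one_per_gene: bool = True,
) -> float:
    """Sum of transcript lengths divided by genome length.

    With ``one_per_gene`` only the longest transcript per gene is counted
    (ties resolved by transcript ID) so that multiple isoforms of one gene
    do not inflate the fraction.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if not transcripts:
        return 0.0
    if one_per_gene:
        chosen: dict[str, Transcript] = {}
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            cur = chosen.get(t.gene_id)
            if cur is None or t.interval.length > cur.interval.length:
                chosen[t.gene_id] = t
        pool: Sequence[Transcript] = list(chosen.values())
    else:
        pool = transcripts
    return sum(t.interval.length for t in pool) / genome_length
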