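"""Cross-sample clustering of integration sites into intervals.

Integration sites from all samples are chained per chromosome whenever the
intervening genomic sequence between two site footprints is shorter than the
clustering gap (5 kb by default, chosen to exceed the ~4.3 kb element
length so that flank evidence from either end of one provirus falls into a
single interval).  Chaining is single-linkage and transitive; isolated
sites form singleton clusters.  The resulting intervals feed a binary
presence/absence matrix over samples.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenomicInterval, IntegrationSite, IntervalCluster

DEFAULT_GAP = 5000


def cluster_sites(
    sites: Iterable[IntegrationSite],
    samples: Sequence[str],
    gap: int = DEFAULT_GAP,
) -> list[IntervalCluster]:
    """Chain sites within ``gap`` of one another into cross-sample intervals.

    Two sites join one cluster iff the intervening sequence between their
    footprints is strictly less than ``gap`` (overlap counts as distance 0).
    The cluster interval is the min-start/max-end span of its members, and
    ``frequency`` is the fraction of ``samples`` with at least one member
    site.  Output is sorted by (chrom, start) and independent of input order.
    """
    if gap <= 0:
        raise ValueError(f"clustering gap must be positive, got {gap}")
    n_samples = len(samples)
    by_chrom: dict[str, list[IntegrationSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    clusters: list[IntervalCluster] = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(
            by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end)
        )
        group: list[IntegrationSite] = []
        max_end = None
        for s in chrom_sites:
            if max_end is not None and s.interval.start - max_end < gap:
                group.append(s)
                max_end = max(max_end, s.interval.end)
            else:
                if group:
                    clusters.append(_close_cluster(group, n_samples))
                group = [s]
                max_end = s.interval.end
        if group:
            clusters.append(_close_cluster(group, n_samples))
    return clusters


def _close_cluster(group: list[IntegrationSite], n_samples: int) -> IntervalCluster:
    chrom = group[0].interval.chrom
    start = min(s.interval.start for s in group)
    end = max(s.interval.end for s in group)
    members: dict[str, list[IntegrationSite]] = {}
    for s in group:
        members.setdefault(s.sample_id, []).append(s)
    freq = len(members) / n_samples if n_samples else 0.0
    return IntervalCluster(
        interval=GenomicInterval(chrom, start, end),
        members=members,
        frequency=freq,
    )


def presence_matrix(
    clusters: Sequence[IntervalCluster], samples: Sequence[str]
) -> pd.DataFrame:
    """Binary presence/absence matrix: rows = samples, columns = intervals."""
    data = np.zeros((len(samples), len(clusters)), dtype=np.int8)
    index = {s: i for i, s in enumerate(samples)}
    cols = [c.cluster_id for c in clusters]
    for j, c in enumerate(clusters):
        for sample in c.members:
            if sample in index:
                data[index[sample], j] = 1
    return pd.DataFrame(data, index=list(samples), columns=cols)


def classify_frequency(
    matrix: pd.DataFrame,
    populations: Mapping[str, str] | None = None,
    high: float = 0.9,
    diff_high: float = 0.8,
    diff_low: float = 0.2,
) -> pd.Series:
    """Label each interval as shared_high, population_differential or other.

    ``shared_high``: presence frequency across all samples >= ``high``.
    ``population_differential``: frequency >= ``diff_high`` in exactly one
    population while <= ``diff_low`` in every other population.
    """
    freq = matrix.mean(axis=0)
    labels = pd.Series("other", index=matrix.columns, dtype=object)
    labels[freq >= high] = "shared_high"
    if populations:
        pops = sorted(set(populations.values()))
        pop_freq = pd.DataFrame(
            {
                p: matrix.loc[[s for s in matrix.index if populations.get(s) == p]].mean(axis=0)
                for p in pops
            }
        )
        for col in matrix.columns:
            if labels[col] == "shared_high":
                continue
            f = pop_freq.loc[col]
            high_pops = [p for p in pops if f[p] >= diff_high]
            if len(high_pops) == 1 and all(
                f[p] <= diff_low for p in pops if p != high_pops[0]
            ):
                labels[col] = "population_differential"
    return labels


def interval_to_integration_ratio(
    clusters: Sequence[IntervalCluster],
    sites: Sequence[IntegrationSite],
    grouping: Mapping[str, str],
) -> dict[str, float]:
    """Per-group ratio of intervals to integration sites.

    For each group of samples, the number of clusters containing at least
    one member site from the group divided by the number of sites from the
    group.  A ratio of 1.0 means no clustering; lower values indicate sites
    collapsing into shared intervals.
    """
    groups = sorted(set(grouping.values()))
    out: dict[str, float] = {}
    for g in groups:
        g_samples = {s for s, grp in grouping.items() if grp == g}
        n_sites = sum(1 for s in sites if s.sample_id in g_samples)
        n_clusters = sum(
            1 for c in clusters if any(m in g_samples for m in c.members)
        )
        out[g] = n_clusters / n_sites if n_sites else float("nan")
    return out


def clustered_fraction(ratios: Iterable[float]) -> float:
    """Average fraction of integration sites collapsed by clustering.

    One minus the mean of per-group interval/integration ratios.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("need at least one ratio")
    return 1.0 - sum(ratios) / len(ratios)
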