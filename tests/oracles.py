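"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a pipeline result by a different route (exhaustive
search, union-find, naive matrix recurrences) so that agreement is a real
cross-check rather than the same code run twice.
"""

from __future__ import annotations

import numpy as np


def merge_oracle(
    features: list[tuple[str, int, int]]
) -> list[tuple[str, int, int, int]]:
    """Transitive closure of the pairwise overlap-or-book-ended relation.

    Returns merged (chrom, start, end, member_count) tuples sorted by
    position.  O(n^2); for cross-checking the sweep implementation only.
    """
    n = len(features)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, si, ei = features[i]
        for j in range(i + 1, n):
            cj, sj, ej = features[j]
            if ci == cj and si <= ej and sj <= ei:  # overlap or book-ended
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        chrom = features[members[0]][0]
        start = min(features[m][1] for m in members)
        end = max(features[m][2] for m in members)
        out.append((chrom, start, end, len(members)))
    return sorted(out)


def cluster_oracle(
    sites: list[tuple[str, int, int]], gap: int
) -> list[tuple[str, int, int, int]]:
    """Union-find over the pairwise 'intervening sequence < gap' test."""
    n = len(sites)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ci, si, ei = sites[i]
        for j in range(i + 1, n):
            cj, sj, ej = sites[j]
            if ci != cj:
                continue
            between = max(si, sj) - min(ei, ej)
            if between < gap:  # overlap gives a negative 'between'
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        chrom = sites[members[0]][0]
        start = min(sites[m][1] for m in members)
        end = max(sites[m][2] for m in members)
        out.append((chrom, start, end, len(members)))
    return sorted(out)


def ward_heights_oracle(x: np.ndarray) -> tuple[list[float], bool]:
    """Naive O(n^3) Ward clustering via the Lance-Williams update.

    Operates on squared Euclidean distances; merge heights are reported on
    the distance scale (square roots), matching hclust's ward.D2 and
    scipy's "ward".  Ties broken by lowest index pair.

    Returns ``(heights, had_ties)``.  When tied minimum distances occurred,
    several valid Ward dendrograms exist and only tie-invariant quantities
    (e.g. the sum of squared merge heights, which telescopes to twice the
    total within-cluster sum of squares) are comparable across
    implementations.
    """
    from scipy.spatial.distance import pdist, squareform

    d2 = squareform(pdist(np.asarray(x, dtype=float))) ** 2
    n = d2.shape[0]
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    d2_map = {
        (i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)
    }
    heights = []
    had_ties = False
    next_id = n
    while len(active) > 1:
        best = None
        for a_i in range(len(active)):
            for a_j in range(a_i + 1, len(active)):
                i, j = active[a_i], active[a_j]
                key = (min(i, j), max(i, j))
                val = d2_map[key]
                if best is None or val < best[0] - 1e-12:
                    best = (val, i, j)
                elif abs(val - best[0]) <= 1e-12 and (i, j) != best[1:]:
                    had_ties = True
        val, i, j = best
        heights.append(float(np.sqrt(val)))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2_map[(min(i, k), max(i, k))]
            djk = d2_map[(min(j, k), max(j, k))]
            dij = val
            d2_map[(min(new, k), max(new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        sizes[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
    return heights, had_ties


def ungapped_local_oracle(query: str, ref: str) -> int:
    """Best ungapped local alignment score (+1 match / -1 mismatch).

    Exhaustive per-diagonal maximum-scoring-segment search — the brute-force
    counterpart of the seeded x-drop engine.
    """
    best = 0
    nq, nr = len(query), len(ref)
    for diag in range(-(nq - 1), nr):
        q0 = max(0, -diag)
        r0 = q0 + diag
        run = 0
        while q0 < nq and r0 < nr:
            run = max(0, run) + (1 if query[q0] == ref[r0] else -1)
            best = max(best, run)
            q0 += 1
            r0 += 1
    return best
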