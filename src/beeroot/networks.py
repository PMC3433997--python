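"""Circular split networks from distance matrices (NeighborNet).

The construction has two stages: (i) an agglomerative, neighbor-joining-like
search produces a circular ordering of the taxa; (ii) the weights of all
interval splits of that ordering are estimated by least squares under
non-negativity constraints against the observed distances.  On an additive
(tree) metric the ordering embeds the tree and the constrained fit recovers
exactly the tree's splits with their branch lengths; on conflicting data,
incompatible splits can receive positive weight simultaneously, which is what
makes the splits graph a useful display of ambiguous signal.

Agglomeration follows the scheme of Bryant & Moulton (2004): taxa start as
singleton clusters; clusters are linked pairwise using the Studier-Keppler
Q criterion on cluster-averaged distances, with the nodes to link chosen by
the same criterion on a mixed node/cluster-average set; chains longer than
two nodes are immediately contracted by the 3-to-2 path reduction
(weights 2/3, 1/3), and the recorded reductions are expanded in reverse at
the end to read off the circular ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls, lsq_linear

from .distances import DistanceMatrix


class NetworkError(ValueError):
    pass


@dataclass
class SplitSystem:
    """Weighted circular split system.

    ``splits`` maps the canonical side of each split (the side not containing
    the first taxon of the circular order) to its non-negative weight.
    """

    taxa: list[str]                 # circular order
    splits: dict[frozenset[str], float]

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.taxa)}
        for side, w in self.splits.items():
            if w < 0:
                raise NetworkError("negative split weight")
            idx = sorted(pos[t] for t in side)
            if idx and idx != list(range(idx[0], idx[-1] + 1)):
                raise NetworkError("split is not an interval of the circular order")

    def nontrivial(self) -> dict[frozenset[str], float]:
        n = len(self.taxa)
        return {s: w for s, w in self.splits.items() if 1 < len(s) < n - 1}

    def to_nexus(self, path: str | Path) -> None:
        """SplitsTree-compatible Nexus SPLITS block."""
        n = len(self.taxa)
        pos = {t: i + 1 for i, t in enumerate(self.taxa)}
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN Taxa;\n")
            fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
            for i, t in enumerate(self.taxa, 1):
                fh.write(f"[{i}] '{t}'\n")
            fh.write(";\nEND;\n\nBEGIN Splits;\n")
            fh.write(f"DIMENSIONS ntax={n} nsplits={len(self.splits)};\n")
            fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
            fh.write(f"CYCLE {' '.join(str(i) for i in range(1, n + 1))};\nMATRIX\n")
            for side, w in sorted(self.splits.items(), key=lambda kv: -kv[1]):
                members = " ".join(str(pos[t]) for t in sorted(side, key=lambda t: pos[t]))
                fh.write(f"\t{w:.9g}\t {members},\n")
            fh.write(";\nEND;\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("weight\tside\n")
            for side, w in sorted(self.splits.items(), key=lambda kv: -kv[1]):
                fh.write(f"{w:.9g}\t{','.join(sorted(side))}\n")


def split_system_distance(s: SplitSystem) -> DistanceMatrix:
    """Metric induced by the split system: d(p, q) = sum of weights of splits
    separating p and q."""
    n = len(s.taxa)
    pos = {t: i for i, t in enumerate(s.taxa)}
    D = np.zeros((n, n))
    for side, w in s.splits.items():
        mask = np.zeros(n, dtype=bool)
        for t in side:
            mask[pos[t]] = True
        sep = mask[:, None] ^ mask[None, :]
        D += w * sep
    return DistanceMatrix(list(s.taxa), D, kind="split_metric")


# ---------------------------------------------------------------------------
# circular-ordering agglomeration
# ---------------------------------------------------------------------------

def _neighbor_net_ordering(D0: np.ndarray) -> list[int]:
    """Circular ordering of taxon indices via agglomerative clustering."""
    n = D0.shape[0]
    size = n + 4 * n + 8          # generous room for reduction nodes
    D = np.zeros((size, size))
    D[:n, :n] = D0
    next_node = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []  # (u, v, a, b, c)

    def dbar(ci: list[int], cj: list[int]) -> float:
        return float(np.mean(D[np.ix_(ci, cj)]))

    def reduce3(a: int, b: int, c: int, actives: list[int]) -> tuple[int, int]:
        nonlocal next_node, D
        u, v = next_node, next_node + 1
        next_node += 2
        if next_node > D.shape[0]:
            D = np.pad(D, ((0, size), (0, size)))
        for z in actives:
            D[u, z] = D[z, u] = (2 / 3) * D[a, z] + (1 / 3) * D[b, z]
            D[v, z] = D[z, v] = (1 / 3) * D[b, z] + (2 / 3) * D[c, z]
        D[u, v] = D[v, u] = (D[a, b] + D[b, c] + D[a, c]) / 3.0
        D[u, u] = D[v, v] = 0.0
        reductions.append((u, v, a, b, c))
        return u, v

    while len(clusters) > 1:
        m = len(clusters)
        if m == 2:
            bi, bj = 0, 1
        else:
            # cluster-level Studier-Keppler Q on averaged distances
            CD = np.zeros((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    CD[i, j] = CD[j, i] = dbar(clusters[i], clusters[j])
            r = CD.sum(axis=1)
            Q = (m - 2) * CD - r[:, None] - r[None, :]
            np.fill_diagonal(Q, np.inf)
            bi, bj = np.unravel_index(int(np.argmin(Q)), Q.shape)
            if bi > bj:
                bi, bj = bj, bi
        P, Qc = clusters[bi], clusters[bj]

        # node-level selection on P+Q nodes plus other-cluster averages
        others = [clusters[k] for k in range(m) if k not in (bi, bj)]
        cand_x = [P[0], P[-1]] if len(P) > 1 else [P[0]]
        cand_y = [Qc[0], Qc[-1]] if len(Qc) > 1 else [Qc[0]]
        m_hat = len(P) + len(Qc) + len(others)
        best = None
        for x in cand_x:
            for y in cand_y:
                sx = sum(D[x, z] for z in P + Qc if z != x) + sum(
                    dbar([x], c) for c in others
                )
                sy = sum(D[y, z] for z in P + Qc if z != y) + sum(
                    dbar([y], c) for c in others
                )
                q = (m_hat - 2) * D[x, y] - sx - sy
                if best is None or q < best[0] - 1e-15:
                    best = (q, x, y)
        _, x, y = best

        chain = (P if P[-1] == x else P[::-1]) + (Qc if Qc[0] == y else Qc[::-1])
        actives = [z for c in clusters for z in c if z not in chain]
        while len(chain) > 2:
            u, v = reduce3(chain[0], chain[1], chain[2], actives + chain[3:])
            chain = [u, v] + chain[3:]
        new_clusters = [clusters[k] for k in range(m) if k not in (bi, bj)]
        new_clusters.append(chain)
        clusters = new_clusters

    cycle = list(clusters[0])
    for u, v, a, b, c in reversed(reductions):
        iu = cycle.index(u)
        iv = cycle.index(v)
        if (iu + 1) % len(cycle) == iv:
            cycle[iu:iu + 1] = [a, b]
            cycle[cycle.index(v)] = c
        elif (iv + 1) % len(cycle) == iu:
            cycle[iv:iv + 1] = [c, b]
            cycle[cycle.index(u)] = a
        else:
            raise NetworkError("reduction nodes not adjacent during expansion")
    return cycle


# ---------------------------------------------------------------------------
# constrained split-weight estimation
# ---------------------------------------------------------------------------

def _interval_splits(n: int) -> list[tuple[int, int]]:
    """All (i, j) with 1 <= i <= j <= n-1: interval positions i..j of the
    circular order, never containing position 0 (one representative per
    split)."""
    return [(i, j) for i in range(1, n) for j in range(i, n)]


def _design_matrix(n: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    splits = _interval_splits(n)
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    A = np.zeros((len(pairs), len(splits)))
    for s_idx, (i, j) in enumerate(splits):
        inside = np.zeros(n, dtype=bool)
        inside[i:j + 1] = True
        for p_idx, (p, q) in enumerate(pairs):
            A[p_idx, s_idx] = inside[p] != inside[q]
    return A, splits


def neighbor_net(
    dm: DistanceMatrix, eps: float = 1e-9, method: str = "auto"
) -> SplitSystem:
    """NeighborNet: circular ordering + non-negative least-squares split
    weights.  Splits with weight below ``eps`` are discarded.

    ``method``: "nnls" (Lawson-Hanson, exact active set), "lsq" (bounded
    least squares, faster for many taxa), or "auto".
    """
    n = len(dm.labels)
    if n < 4:
        raise NetworkError("neighbor_net needs at least 4 labels")
    order_idx = _neighbor_net_ordering(dm.d)
    taxa = [dm.labels[i] for i in order_idx]
    perm = np.array(order_idx)
    Dc = dm.d[np.ix_(perm, perm)]
    A, splits = _design_matrix(n)
    dvec = Dc[np.triu_indices(n, k=1)]
    if method == "auto":
        method = "nnls" if len(splits) <= 600 else "lsq"
    if method == "nnls":
        w, _ = nnls(A, dvec)
    elif method == "lsq":
        res = lsq_linear(A, dvec, bounds=(0.0, np.inf), tol=1e-12)
        w = res.x
    else:
        raise ValueError(f"unknown method {method!r}")
    out: dict[frozenset[str], float] = {}
    for (i, j), wk in zip(splits, w):
        if wk >= eps:
            out[frozenset(taxa[i:j + 1])] = float(wk)
    return SplitSystem(taxa=taxa, splits=out)
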