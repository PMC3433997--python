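"""Unrooted trees: neighbor-joining, bootstrap, majority-rule consensus,
split-compatibility filtering, and categorical outgroup-placement
classification.

Trees are stored as undirected adjacency maps with string-labelled leaves.
Every internal edge induces a bipartition (split) of the leaf set; splits
are canonicalised as the side not containing the lexicographically smallest
leaf label, so that split sets from different trees over the same leaves are
directly comparable.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .distances import DistanceError, DistanceMatrix, allele_sharing_distance, fst_matrix
from .genotypes import OUTGROUP, GenotypeMatrix, SampleSheet


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

class UnrootedTree:
    """Leaf-labelled unrooted tree with branch lengths and optional supports.

    Nodes are integers; ``label`` maps leaf node -> string label.  Branch
    lengths live on undirected edges; supports (percent, 0-100) may be
    attached to internal edges.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.label: dict[int, str] = {}
        self.support: dict[frozenset[int], float] = {}
        self._next = 0

    # -- construction ------------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        v = self._next
        self._next += 1
        self.adj[v] = {}
        if label is not None:
            self.label[v] = label
        return v

    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    # -- basics ------------------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return sorted(
            (v for v in self.adj if v in self.label), key=lambda v: self.label[v]
        )

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.label.values())

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in self.adj:
            for v, w in self.adj[u].items():
                if u < v:
                    out.append((u, v, w))
        return out

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def validate(self) -> None:
        labs = list(self.label.values())
        if len(set(labs)) != len(labs):
            raise TreeError("duplicate leaf labels")
        n_edges = sum(len(nb) for nb in self.adj.values()) // 2
        if n_edges != len(self.adj) - 1:
            raise TreeError("tree is not acyclic/connected")
        seen = self._component(next(iter(self.adj)))
        if len(seen) != len(self.adj):
            raise TreeError("tree is not connected")

    def _component(self, start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the ``v`` side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            w = stack.pop()
            if w in self.label:
                out.append(self.label[w])
            for x in self.adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    # -- splits ------------------------------------------------------------
    def splits(self, include_trivial: bool = False) -> dict[frozenset[str], float]:
        """Canonical split -> branch length for internal (optionally all) edges."""
        ref = min(self.leaf_labels)
        out: dict[frozenset[str], float] = {}
        for u, v, w in self.edges():
            side = self.side_leaves(u, v)
            if ref in side:
                side = frozenset(self.leaf_labels) - side
            if len(side) == 0 or len(side) == len(self.leaf_labels):
                continue
            if not include_trivial and (
                len(side) == 1 or len(side) == len(self.leaf_labels) - 1
            ):
                continue
            out[side] = out.get(side, 0.0) + w
        return out

    def edge_for_split(self, split: frozenset[str]) -> tuple[int, int] | None:
        full = frozenset(self.leaf_labels)
        for u, v, _ in self.edges():
            side = self.side_leaves(u, v)
            if side == split or side == full - split:
                return (u, v)
        return None

    # -- Newick ------------------------------------------------------------
    def to_newick(self, support_as_label: bool = True, precision: int = 9) -> str:
        """Newick string rooted arbitrarily at the neighbour of the first leaf.

        Supports, where present, are written as internal-node labels rounded
        to integers (the conventional bootstrap percentage encoding).
        """
        if len(self.adj) == 1:
            (v,) = self.adj
            return f"{self.label[v]};"
        start_leaf = self.leaves[0]
        root = next(iter(self.adj[start_leaf]))

        def fmt(w: float) -> str:
            return f"{w:.{precision}g}"

        def rec(v: int, parent: int | None) -> str:
            children = [u for u in self.adj[v] if u != parent]
            if not children:
                return self.label[v]
            parts = []
            for u in children:
                sub = rec(u, v)
                sup = ""
                if support_as_label and u not in self.label:
                    s = self.support.get(frozenset((v, u)))
                    if s is not None:
                        sup = str(int(round(s)))
                parts.append(f"{sub}{sup}:{fmt(self.adj[v][u])}")
            return "(" + ",".join(parts) + ")"

        return rec(root, None) + ";"

    @classmethod
    def from_newick(cls, s: str) -> "UnrootedTree":
        """Parse a Newick string; internal-node labels are read as supports."""
        t = cls()
        s = s.strip()
        if not s.endswith(";"):
            raise TreeError("Newick string must end with ';'")
        s = s[:-1]
        pos = 0

        def parse_clade(parent: int | None) -> int:
            nonlocal pos
            if s[pos] == "(":
                v = t.add_node()
                pos += 1
                while True:
                    child = parse_clade(v)
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                # optional internal label (support) and length
                name = _scan_token(s, pos)
                if name:
                    pos += len(name)
                    try:
                        t.support[frozenset((parent, v))] = float(name)
                    except (TypeError, ValueError):
                        pass
            else:
                name = _scan_token(s, pos)
                if not name:
                    raise TreeError(f"parse error near position {pos}")
                pos += len(name)
                v = t.add_node(label=name)
            length = 0.0
            if pos < len(s) and s[pos] == ":":
                pos += 1
                tok = _scan_token(s, pos)
                pos += len(tok)
                length = float(tok)
            if parent is not None:
                t.add_edge(parent, v, length)
            return v

        root = parse_clade(None)
        if pos != len(s):
            raise TreeError(f"trailing characters at position {pos}")
        t._suppress_degree_two(root)
        t.validate()
        return t

    def _suppress_degree_two(self, root: int) -> None:
        # a rooted binary Newick has a degree-2 root; merge its two edges
        if root in self.adj and self.degree(root) == 2 and root not in self.label:
            (a, la), (b, lb) = list(self.adj[root].items())
            sup = self.support.pop(frozenset((root, a)), None)
            if sup is None:
                sup = self.support.pop(frozenset((root, b)), None)
            self.remove_edge(root, a)
            self.remove_edge(root, b)
            del self.adj[root]
            self.add_edge(a, b, la + lb)
            if sup is not None:
                self.support[frozenset((a, b))] = sup

    def copy(self) -> "UnrootedTree":
        return UnrootedTree.from_newick(self.to_newick())


def _scan_token(s: str, pos: int) -> str:
    out = []
    while pos < len(s) and s[pos] not in "(),:;":
        out.append(s[pos])
        pos += 1
    return "".join(out)


def write_newick(trees: Iterable[UnrootedTree], path: str | Path) -> None:
    """One Newick tree per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def read_newick(path: str | Path) -> list[UnrootedTree]:
    with open(path) as fh:
        return [UnrootedTree.from_newick(line) for line in fh if line.strip()]


def write_nexus_trees(trees: Sequence[UnrootedTree], path: str | Path) -> None:
    """Minimal Nexus TREES block for interoperability."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN TREES;\n")
        for k, t in enumerate(trees, 1):
            fh.write(f"  TREE tree_{k} = [&U] {t.to_newick()}\n")
        fh.write("END;\n")


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei agglomeration with the Studier-Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest pair of subtree
    representative labels (the smallest leaf label each subtree contains), so
    the result is deterministic.  Negative branch-length estimates at a join
    are clamped to zero with the deficit transferred to the sibling branch,
    preserving the joined pair's distance.
    """
    n = len(dm.labels)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 labels")
    t = UnrootedTree()
    nodes = [t.add_node(label=lab) for lab in dm.labels]
    reps = list(dm.labels)                      # tie-break representative per active node
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        # deterministic: smallest (label_i, label_j) sorted pair
        def key(ij: np.ndarray) -> tuple[str, str]:
            a, b = reps[active[ij[0]]], reps[active[ij[1]]]
            return (a, b) if a <= b else (b, a)
        ii, jj = min(map(tuple, ties), key=lambda ij: key(np.array(ij)))
        i, j = active[ii], active[jj]

        dij = D[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0

        u = t.add_node()
        t.add_edge(u, nodes[i], li)
        t.add_edge(u, nodes[j], lj)

        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(u)
        reps.append(min(reps[i], reps[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    # three-point formulas
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = t.add_node()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        t.add_edge(center, nodes[node], max(ln, 0.0))
    t.validate()
    return t


def random_binary_tree(
    n: int,
    rng: np.random.Generator,
    min_len: float = 0.1,
    max_len: float = 2.0,
    prefix: str = "t",
) -> UnrootedTree:
    """Random unrooted binary tree with uniform branch lengths, built by
    attaching each new leaf to a uniformly chosen edge."""
    if n < 3:
        raise TreeError("need at least 3 leaves")
    t = UnrootedTree()
    center = t.add_node()
    for i in range(3):
        t.add_edge(center, t.add_node(label=f"{prefix}{i:03d}"),
                   rng.uniform(min_len, max_len))
    for i in range(3, n):
        edges = t.edges()
        u, v, w = edges[rng.integers(0, len(edges))]
        t.remove_edge(u, v)
        mid = t.add_node()
        split = rng.uniform(0.25, 0.75) * w
        t.add_edge(u, mid, split)
        t.add_edge(mid, v, w - split)
        t.add_edge(mid, t.add_node(label=f"{prefix}{i:03d}"),
                   rng.uniform(min_len, max_len))
    # re-draw so every edge, interior ones included, is U(min_len, max_len)
    for u, v, _ in t.edges():
        w = float(rng.uniform(min_len, max_len))
        t.adj[u][v] = t.adj[v][u] = w
    return t


def path_length_matrix(t: UnrootedTree) -> DistanceMatrix:
    """Additive (patristic) distance matrix of a tree over its leaves."""
    labels = t.leaf_labels
    node_of = {lab: v for v, lab in t.label.items()}
    n = len(labels)
    D = np.zeros((n, n))
    for i, lab in enumerate(labels):
        dist = {node_of[lab]: 0.0}
        stack = [node_of[lab]]
        while stack:
            u = stack.pop()
            for v, w in t.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, lab2 in enumerate(labels):
            D[i, j] = dist[node_of[lab2]]
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _distance_for(
    g: GenotypeMatrix,
    sheet: SampleSheet,
    distance_kind: str,
    level: str = "subspecies",
    pool_outgroups: bool = False,
) -> DistanceMatrix:
    if distance_kind in ("allele_sharing", "allele-sharing"):
        return allele_sharing_distance(g)
    if distance_kind == "fst":
        dm, _ = fst_matrix(g, sheet, level=level, pool_outgroups=pool_outgroups)
        return dm
    raise ValueError(f"unknown distance kind {distance_kind!r}")


def bootstrap_trees(
    g: GenotypeMatrix,
    sheet: SampleSheet,
    distance_kind: str = "allele_sharing",
    R: int = 100,
    seed: int = 0,
    resample: bool = True,
    level: str = "subspecies",
    pool_outgroups: bool = False,
    max_redraws: int = 100,
) -> tuple[list[UnrootedTree], int]:
    """Locus (column) bootstrap: resample loci with replacement to the
    original locus count, recompute the requested distance, run NJ.

    Returns the replicate trees and the number of degenerate replicates that
    had to be redrawn (a replicate is degenerate when some pair has no shared
    non-missing locus or F_ST has no informative locus).  ``resample=False``
    turns each replicate into the identity panel (testing hook).
    """
    if R < 1:
        raise ValueError("R >= 1 required")
    rng = np.random.default_rng(seed)
    trees: list[UnrootedTree] = []
    redrawn = 0
    while len(trees) < R:
        if resample:
            idx = rng.integers(0, g.n_loci, size=g.n_loci)
            gb = g.resample_loci(idx)
        else:
            gb = g
        try:
            dm = _distance_for(gb, sheet, distance_kind, level, pool_outgroups)
        except DistanceError:
            redrawn += 1
            if redrawn > max_redraws:
                raise TreeError(f"more than {max_redraws} degenerate bootstrap replicates")
            continue
        trees.append(neighbor_joining(dm))
    return trees, redrawn


# ---------------------------------------------------------------------------
# consensus and compatibility
# ---------------------------------------------------------------------------

def splits_compatible(s1: frozenset[str], s2: frozenset[str], all_leaves: frozenset[str]) -> bool:
    """Two bipartitions can coexist in one tree iff one of the four pairwise
    side-intersections is empty."""
    a, na = s1, all_leaves - s1
    b, nb = s2, all_leaves - s2
    return not (a & b) or not (a & nb) or not (na & b) or not (na & nb)


def majority_rule_consensus(
    trees: Sequence[UnrootedTree], threshold: float = 0.5
) -> UnrootedTree:
    """Strict-majority consensus: splits present in > threshold of the trees.

    Edge supports are occurrence fractions x 100; consensus branch lengths
    are means over the trees containing each split; unresolved regions become
    polytomies.
    """
    if not trees:
        raise TreeError("no trees")
    leaf_sets = {frozenset(t.leaf_labels) for t in trees}
    if len(leaf_sets) != 1:
        raise TreeError("trees have differing leaf sets")
    leaves = sorted(leaf_sets.pop())
    R = len(trees)
    counts: Counter[frozenset[str]] = Counter()
    lengths: defaultdict[frozenset[str], list[float]] = defaultdict(list)
    for t in trees:
        for split, w in t.splits().items():
            counts[split] += 1
            lengths[split].append(w)
    kept = {s: c for s, c in counts.items() if c / R > threshold}
    # mean pendant lengths
    pend: defaultdict[str, list[float]] = defaultdict(list)
    for t in trees:
        for u, v, w in t.edges():
            for x in (u, v):
                if x in t.label:
                    pend[t.label[x]].append(w)

    clades = sorted(kept, key=len, reverse=True)
    t = UnrootedTree()
    root = t.add_node()
    parent_of: dict[str, int] = {lab: root for lab in leaves}
    node_clade: dict[int, frozenset[str]] = {root: frozenset(leaves)}
    for clade in clades:
        # attach under the smallest existing clade containing it
        host = root
        for v, cl in node_clade.items():
            if clade < cl and len(cl) < len(node_clade[host]):
                host = v
        u = t.add_node()
        sup = 100.0 * kept[clade] / R
        t.add_edge(host, u, float(np.mean(lengths[clade])))
        t.support[frozenset((host, u))] = sup
        node_clade[u] = clade
        for lab in clade:
            if node_clade[parent_of[lab]] > clade:
                parent_of[lab] = u
    for lab in leaves:
        v = t.add_node(label=lab)
        t.add_edge(parent_of[lab], v, float(np.mean(pend[lab])))
    t.validate()
    return t


def tree_compatible_with(t: UnrootedTree, reference: UnrootedTree) -> bool:
    """True iff every split of the reference is compatible with every split
    of the tree."""
    all_leaves = frozenset(t.leaf_labels)
    rs = list(reference.splits())
    ts = list(t.splits())
    return all(splits_compatible(r, s, all_leaves) for r in rs for s in ts)


def filter_compatible(
    trees: Sequence[UnrootedTree], reference: UnrootedTree
) -> tuple[list[UnrootedTree], list[UnrootedTree], UnrootedTree | None]:
    """Partition trees into (compatible with reference, remainder) and build
    a second majority-rule consensus from the remainder (None if empty)."""
    ref_leaves = frozenset(reference.leaf_labels)
    for t in trees:
        if frozenset(t.leaf_labels) != ref_leaves:
            raise TreeError("leaf-set mismatch between trees and reference")
    compat = [t for t in trees if tree_compatible_with(t, reference)]
    remainder = [t for t in trees if not tree_compatible_with(t, reference)]
    second = majority_rule_consensus(remainder) if remainder else None
    return compat, remainder, second


# ---------------------------------------------------------------------------
# outgroup placement
# ---------------------------------------------------------------------------

PLACEMENT_CATEGORIES = (
    "sister_to_M", "sister_to_C", "sister_to_O", "sister_to_A",
    "within_M", "within_C", "within_O", "within_A",
    "between_AM_and_CO", "other",
)


@dataclass
class PlacementTally:
    """Per-replicate outgroup-attachment categories and aggregate fractions."""

    categories: list[str]

    @property
    def n(self) -> int:
        return len(self.categories)

    @property
    def fractions(self) -> dict[str, float]:
        c = Counter(self.categories)
        return {k: c.get(k, 0) / self.n for k in PLACEMENT_CATEGORIES}

    @property
    def modal_category(self) -> str:
        c = Counter(self.categories)
        best = max(c.values())
        # deterministic tie-break by the fixed category order
        return next(k for k in PLACEMENT_CATEGORIES if c.get(k) == best)


def classify_outgroup_placement(t: UnrootedTree, sheet: SampleSheet) -> str:
    """Classify where the outgroup subtree attaches to the ingroup tree.

    The outgroup leaves must form a connected subtree (exist as one side of
    an edge); otherwise the category is "other".  Removing that subtree
    leaves an attachment node whose two remaining sides bipartition the
    ingroup leaves; the bipartition is matched against the lineage groups.
    """
    in_tree = set(t.leaf_labels)
    og = [s for s in sheet.outgroup_samples if s in in_tree]
    if not og:
        raise TreeError("tree contains no outgroup leaf")
    group_leaves: dict[str, frozenset[str]] = {}
    for gp in sheet.ingroup_groups():
        members = frozenset(s for s in sheet.samples_of_group(gp) if s in in_tree)
        if not members:
            raise TreeError(f"tree contains no leaf from group {gp}")
        group_leaves[gp] = members
    og_set = frozenset(og)

    # find the edge separating exactly the outgroup leaves
    attach_edge = None
    for u, v, _ in t.edges():
        side = t.side_leaves(u, v)
        if side == og_set:
            attach_edge = (v, u)   # u = ingroup-side endpoint... (v side == og)
            break
        if frozenset(t.leaf_labels) - side == og_set:
            attach_edge = (u, v)
            break
    if attach_edge is None:
        return "other"  # outgroup not monophyletic in this tree
    og_node, attach = attach_edge

    rest = [w for w in t.adj[attach] if w != og_node]
    if len(rest) != 2:
        return "other"  # polytomy at the attachment point
    side1 = t.side_leaves(attach, rest[0]) - og_set
    side2 = t.side_leaves(attach, rest[1]) - og_set

    for side in (side1, side2):
        for gp, members in group_leaves.items():
            if side == members:
                return f"sister_to_{gp}"
    for side in (side1, side2):
        for gp, members in group_leaves.items():
            if side and side < members:
                return f"within_{gp}"
    am = group_leaves.get("A", frozenset()) | group_leaves.get("M", frozenset())
    co = group_leaves.get("C", frozenset()) | group_leaves.get("O", frozenset())
    if {side1, side2} == {am, co}:
        return "between_AM_and_CO"
    return "other"


def placement_frequencies(
    trees: Sequence[UnrootedTree], sheet: SampleSheet
) -> PlacementTally:
    """Classify each tree's outgroup placement and tally category fractions."""
    if not trees:
        raise TreeError("no trees")
    return PlacementTally([classify_outgroup_placement(t, sheet) for t in trees])
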