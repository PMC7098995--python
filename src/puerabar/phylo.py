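"""K2P distances, barcoding-gap statistics and neighbor-joining trees.

Distances follow Kimura's two-parameter model: with P the transition and Q
the transversion fraction over comparable columns,

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).

Columns with a gap (or ambiguity) in either row of a pair are excluded
pairwise ("pairwise deletion").  Trees are built with the Saitou-Nei
neighbor-joining algorithm; bipartition support comes from resampling
alignment columns with replacement and rebuilding the tree per replicate.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = (0, 2)  # A, G

SeqSet = Mapping[str, str] | Sequence[tuple[str, str]]


def _as_pairs(seqs: SeqSet) -> list[tuple[str, str]]:
    if isinstance(seqs, Mapping):
        return list(seqs.items())
    return list(seqs)


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; gaps and ambiguity codes -> 4 (excluded pairwise)."""
    return np.frombuffer(
        seq.upper().encode().translate(_ENC_TABLE), dtype=np.uint8)


_ENC_TABLE = bytes(
    _ENCODE.get(chr(i), 4) if chr(i) in "ACGT" else 4 for i in range(256))


def k2p_distance(aligned_a: str, aligned_b: str) -> tuple[float, int]:
    """K2P distance and comparable-column count for one aligned pair."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    return _k2p_encoded(_encode(aligned_a), _encode(aligned_b))


def _k2p_encoded(ea: np.ndarray, eb: np.ndarray) -> tuple[float, int]:
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable columns after pairwise gap deletion")
    a, b = ea[valid], eb[valid]
    diff = a != b
    same_class = np.isin(a, _PURINE) == np.isin(b, _PURINE)
    transitions = int((diff & same_class).sum())
    transversions = int((diff & ~same_class).sum())
    p, q = transitions / n, transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"K2P saturation (P={p:.4f}, Q={q:.4f}): log argument <= 0")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), n


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray            # symmetric, zero diagonal, subs/site
    comparable_sites: np.ndarray  # per-pair comparable column counts

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.comparable_sites[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        """PHYLIP-style square matrix, tab separated."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(seqs: SeqSet) -> DistanceMatrix:
    """All pairwise K2P distances with per-pair (pairwise) gap deletion."""
    pairs = _as_pairs(seqs)
    labels = [l for l, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal aligned length")
    enc = np.stack([_encode(s) for _, s in pairs])
    return _distance_matrix_encoded(labels, enc)


def _distance_matrix_encoded(labels: list[str], enc: np.ndarray) -> DistanceMatrix:
    n = len(labels)
    values = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=int)
    for i in range(n):
        comparable[i, i] = int((enc[i] < 4).sum())
        for j in range(i + 1, n):
            try:
                d, m = _k2p_encoded(enc[i], enc[j])
            except ValueError as err:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {err}") from err
            values[i, j] = values[j, i] = d
            comparable[i, j] = comparable[j, i] = m
    return DistanceMatrix(labels, values, comparable)


# --------------------------------------------------------------------------
# Barcoding gap
# --------------------------------------------------------------------------

@dataclass
class GapReport:
    """max intra-group vs min inter-group distance summary.

    max_intra maps each group to its largest within-group distance, or None
    for singleton groups (within-group variation undefined).  gap_present is
    true iff the minimum between-group distance exceeds every defined
    within-group maximum.
    """
    max_intra: dict[str, float | None]
    min_inter: float
    min_inter_pair: tuple[str, str]
    gap_present: bool


def barcoding_gap(dm: DistanceMatrix, groups: Mapping[str, str],
                  exclude: tuple[str, ...] = ("outgroup", "contaminant")
                  ) -> GapReport:
    """Barcoding-gap statistics over the focal barcode groups.

    Groups named in ``exclude`` (by default the reserved outgroup and
    contaminant labels) take no part in the intra/inter statistics.
    """
    missing = [l for l in dm.labels if l not in groups]
    if missing:
        raise ValueError(f"group map missing labels: {missing}")
    keep = [l for l in dm.labels if groups[l] not in exclude]
    dm = dm.submatrix(keep)
    by_group: dict[str, list[int]] = {}
    for idx, label in enumerate(dm.labels):
        by_group.setdefault(groups[label], []).append(idx)
    if len(by_group) < 2:
        raise ValueError("barcoding gap requires at least two groups")

    max_intra: dict[str, float | None] = {}
    for g, idx in by_group.items():
        if len(idx) < 2:
            max_intra[g] = None
        else:
            sub = dm.values[np.ix_(idx, idx)]
            max_intra[g] = float(sub.max())

    min_inter = math.inf
    min_pair = ("", "")
    for i, li in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            lj = dm.labels[j]
            if groups[li] != groups[lj] and dm.values[i, j] < min_inter:
                min_inter = float(dm.values[i, j])
                min_pair = (li, lj)
    defined = [v for v in max_intra.values() if v is not None]
    gap_present = all(min_inter > v for v in defined)
    return GapReport(max_intra, min_inter, min_pair, gap_present)


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root."""
    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side that does
        not contain the lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if node.is_leaf:
                continue
            side = node.leaf_names()
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return frozenset(out)

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def to_newick(self, outgroup: str | None = None) -> str:
        tree = self if outgroup is None else root_on_outgroup(self, outgroup)
        return _newick(tree.root, top=True) + ";"


def _newick(node: TreeNode, top: bool = False) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else str(node.support)
    if top:
        return f"({inner}){label}"
    return f"({inner}){label}:{node.length:.6f}"


def root_on_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Reroot on the terminal edge of the named leaf (edge split in half)."""
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    tree = PhyloTree(copy.deepcopy(tree.root))
    parents: dict[int, TreeNode | None] = {id(tree.root): None}
    target = None
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            parents[id(c)] = node
            stack.append(c)
        if node.is_leaf and node.name == outgroup:
            target = node
    assert target is not None
    half = target.length / 2.0
    # walk from the outgroup's parent back to the old root, reversing edges
    path: list[TreeNode] = []
    node = parents[id(target)]
    while node is not None:
        path.append(node)
        node = parents[id(node)]
    new_parent_length = half
    for i, node in enumerate(path):
        node.children = [c for c in node.children
                         if c is not target and (i == 0 or c is not path[i - 1])]
        length = node.length
        node.length = new_parent_length
        new_parent_length = length
        if i + 1 < len(path):
            node.children.append(path[i + 1])
    out = TreeNode(children=[
        TreeNode(name=target.name, length=half),
        path[0],
    ])
    return PhyloTree(out)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties resolve to the lexicographically smallest pair of subtree
    labels (smallest contained leaf).  Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch so the pair's path
    length is preserved.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in dm.labels}
    d: dict[tuple[str, str], float] = {}
    for i, li in enumerate(dm.labels):
        for j in range(i + 1, n):
            lj = dm.labels[j]
            d[_key(li, lj)] = float(dm.values[i, j])
    active = sorted(nodes)          # keys are the smallest leaf in the subtree

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[_key(a, b)] for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * d[_key(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and best is not None
                                          and _key(a, b) < best):
                    best_q = q
                    best = _key(a, b)
        a, b = best
        dab = d[best]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0) + 0.0, max(lb, 0.0) + 0.0   # +0.0 kills -0.0
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = la, lb
        parent = TreeNode(children=[na, nb])
        key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[_key(key, c)] = 0.5 * (d[_key(a, c)] + d[_key(b, c)] - dab)
        active = sorted(set(active) - {a, b} | {key})
        nodes[key] = parent

    a, b, c = active
    dab, dac, dbc = d[_key(a, b)], d[_key(a, c)], d[_key(b, c)]
    nodes[a].length = max(0.0, 0.5 * (dab + dac - dbc))
    nodes[b].length = max(0.0, 0.5 * (dab + dbc - dac))
    nodes[c].length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------

def bootstrap_support(alignment: SeqSet, n_replicates: int,
                      seed: int) -> PhyloTree:
    """NJ tree with bootstrap support on the point-estimate topology.

    Alignment columns are resampled with replacement ``n_replicates`` times
    (Philox counter-based generator, so the replicate column sets are a pure
    function of the seed); each internal bipartition of the point tree is
    annotated with the integer percentage of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    pairs = _as_pairs(alignment)
    if len(pairs) < 3:
        raise ValueError("bootstrap requires an alignment with >= 3 rows")
    labels = [l for l, _ in pairs]
    enc = np.stack([_encode(s) for _, s in pairs])
    L = enc.shape[1]

    point = nj_tree(_distance_matrix_encoded(labels, enc))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in point.bipartitions()}

    rng = np.random.Generator(np.random.Philox(seed))
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(_distance_matrix_encoded(labels, enc[:, cols]))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(labels)
    ref = min(all_leaves)
    for node in point.internal_nodes():
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = round(100.0 * counts[side] / n_replicates)
    return point
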