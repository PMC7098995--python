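"""K2P distances, barcoding gap and neighbor-joining trees."""

from __future__ import annotations

import math

import numpy as np
import pytest

import puerabar as pb
from puerabar.phylo import DistanceMatrix, TreeNode, root_on_outgroup

# ----------------------------------------------------------------------
# K2P distance
# ----------------------------------------------------------------------

def test_identical_sequences_distance_zero():
    d, n = pb.k2p_distance("ACGT" * 25, "ACGT" * 25)
    assert d == 0.0 and n == 100


def test_single_transversion_over_477_sites():
    a = "ACGT" * 120    # 480
    a = a[:477]
    b = a[:100] + {"A": "C"}[a[100]] + a[101:]
    d, n = pb.k2p_distance(a, b)
    assert n == 477
    assert round(d, 4) == 0.0021
    # high-precision closed form (P=0, Q=1/477)
    assert d == pytest.approx(0.0020997400418856083, rel=1e-12)


def test_closed_form_one_transition_one_transversion_over_200():
    a = "ACGT" * 50
    b = "G" + a[1:100] + "T" + a[101:]   # A->G transition, C->T? position 100
    assert a[0] == "A" and a[100] == "A"
    b = "G" + a[1:100] + "C" + a[101:]   # A->G (transition), A->C (transversion)
    d, n = pb.k2p_distance(a, b)
    assert n == 200
    # oracle evaluated with arbitrary-precision arithmetic (sympy):
    # -1/2 ln(1 - 3/200) - 1/4 ln(1 - 2/200)
    assert d == pytest.approx(0.010069402868399446, rel=1e-12)


APE_ALIGNMENT = {
    # fixed 5x60 alignment; expected matrix frozen from ape::dist.dna
    # (model="K80", pairwise.deletion=TRUE)
    "S1": "AACGTTGTGAGGCCAAATAATTCTTTCACCAGATGCGTTTGCCCATCCGTGGGTATTATG",
    "S2": "AACGTTCTGAGGCCAAATAATTCTTTCACCAGATGCGTTTGCCCATCGGTGGGTATTATG",
    "S3": "AATGT--TGAGGCCAAATAATTCTTTCACAAGATGCGTTTGCCCATCCGTGGGTATTTTG",
    "S4": "AACCTTGTGAGGCCAAATAATTCTTTCACCAGATGCACTTGCCCATACTTGGGTGTTCTG",
    "S5": "CAAGTTGTAAGGCCAAAAAAGTCTTTCGCG-GCGGCGTTTGCCCATCCGTACGTATTATG",
}
APE_EXPECTED = {
    ("S1", "S2"): 0.0341989937096, ("S1", "S3"): 0.0535942229866,
    ("S1", "S4"): 0.1269359893071, ("S1", "S5"): 0.2145218091207,
    ("S2", "S3"): 0.0723753714884, ("S2", "S4"): 0.1673576634857,
    ("S2", "S5"): 0.2616626135501, ("S3", "S4"): 0.1752316895936,
    ("S3", "S5"): 0.2471094008477, ("S4", "S5"): 0.3916420368122,
}


def test_k2p_matrix_matches_independent_reference_values():
    dm = pb.distance_matrix(APE_ALIGNMENT)
    for (a, b), expected in APE_EXPECTED.items():
        assert dm[a, b] == pytest.approx(expected, abs=1e-10)


def test_saturation_is_an_error():
    with pytest.raises(ValueError, match="saturation"):
        pb.k2p_distance("A" * 30, "C" * 30)


def test_no_comparable_columns_is_an_error():
    with pytest.raises(ValueError, match="comparable"):
        pb.k2p_distance("AAAA----", "----CCCC")


def test_distance_strictly_increases_with_planted_substitutions():
    rng = np.random.default_rng(11)
    for length in (100, 250, 500):
        seq = rng.choice(list("ACGT"), size=length)
        other = seq.copy()
        positions = rng.choice(length, size=25, replace=False)
        prev = 0.0
        for i, pos in enumerate(positions):
            other[pos] = rng.choice([b for b in "ACGT" if b != other[pos]])
            d, _ = pb.k2p_distance("".join(seq), "".join(other))
            assert d > prev, (length, i)
            prev = d


def test_k2p_at_least_p_distance():
    rng = np.random.default_rng(12)
    for _ in range(20):
        length = int(rng.integers(100, 400))
        a = rng.choice(list("ACGT"), size=length)
        b = a.copy()
        k = int(rng.integers(1, length // 5))
        for pos in rng.choice(length, size=k, replace=False):
            b[pos] = rng.choice([x for x in "ACGT" if x != b[pos]])
        d, n = pb.k2p_distance("".join(a), "".join(b))
        p = (a != b).sum() / n
        assert d >= p - 1e-12


def test_k2p_symmetry():
    rng = np.random.default_rng(13)
    a = "".join(rng.choice(list("ACGT"), size=150))
    b = "".join(rng.choice(list("ACGT"), size=150))
    try:
        dab = pb.k2p_distance(a, b)
        dba = pb.k2p_distance(b, a)
        assert dab == dba
    except ValueError:
        pytest.skip("random pair saturated")


# ----------------------------------------------------------------------
# distance matrix
# ----------------------------------------------------------------------

def _brute_k2p(a: str, b: str) -> float:
    """Character-loop oracle, independent of the vectorized implementation."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x, y) in transitions:
                ts += 1
            else:
                tv += 1
    p, q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def test_identical_rows_give_zero_matrix():
    dm = pb.distance_matrix([("a", "ACGTACGT"), ("b", "ACGTACGT"),
                             ("c", "ACGTACGT")])
    assert dm.values.max() == 0.0


def test_matrix_equals_bruteforce_on_random_alignments():
    rng = np.random.default_rng(21)
    for _ in range(5):
        seqs = {}
        base = rng.choice(list("ACGT"), size=60)
        for i in range(5):
            row = base.copy()
            for pos in rng.choice(60, size=rng.integers(0, 10), replace=False):
                row[pos] = rng.choice([b for b in "ACGT" if b != row[pos]])
            if i == 3:
                row[rng.integers(0, 60)] = "-"
            seqs[f"R{i}"] = "".join(row)
        dm = pb.distance_matrix(seqs)
        labels = list(seqs)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert dm[a, b] == pytest.approx(_brute_k2p(seqs[a], seqs[b]),
                                                 abs=1e-12)


def test_matrix_error_names_the_pair():
    with pytest.raises(ValueError, match=r"\(x, y\)"):
        pb.distance_matrix([("x", "AAAA"), ("y", "CCCC"), ("z", "AAAA")])


def test_subspecies_fixture_intra_below_inter(refs):
    dm = pb.distance_matrix(list(refs.aligned_amplicons().items()))
    lob = ["LOB001", "LOB002"]
    thom = ["THO001", "THO002"]
    intra = max(dm[a, b] for i, a in enumerate(lob) for b in lob[i + 1:])
    inter = min(dm[a, b] for a in lob for b in thom)
    assert intra <= inter


# ----------------------------------------------------------------------
# barcoding gap
# ----------------------------------------------------------------------

def test_gap_between_distinct_uniform_groups():
    seqs = {"a1": "AAAAACGTAC", "a2": "AAAAACGTAC",
            "b1": "AAAAACGTTC", "b2": "AAAAACGTTC"}
    rep = pb.barcoding_gap(pb.distance_matrix(seqs),
                           {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
    assert rep.max_intra == {"g1": 0.0, "g2": 0.0}
    assert rep.gap_present


def test_fixture_gap_matches_published_summary(refs):
    dm = pb.distance_matrix(list(refs.aligned_amplicons().items()))
    rep = pb.barcoding_gap(dm, refs.groups())
    assert round(rep.max_intra["lobata"], 4) == 0.0021
    assert rep.max_intra["thomsonii"] == 0.0
    assert rep.gap_present


def test_overlapping_groups_have_no_gap():
    # within-group distances overlap the between-group range
    rng = np.random.default_rng(31)
    base = rng.choice(list("ACGT"), size=80)
    seqs = {}
    for i, nmut in enumerate([0, 12, 2, 3]):
        row = base.copy()
        for pos in rng.choice(80, size=nmut, replace=False):
            row[pos] = rng.choice([b for b in "ACGT" if b != row[pos]])
        seqs[f"q{i}"] = "".join(row)
    groups = {"q0": "g1", "q1": "g1", "q2": "g2", "q3": "g2"}
    dm = pb.distance_matrix(seqs)
    rep = pb.barcoding_gap(dm, groups)
    # exhaustive pair-scan oracle
    labels = list(seqs)
    intra = [dm[a, b] for i, a in enumerate(labels) for b in labels[i + 1:]
             if groups[a] == groups[b]]
    inter = [dm[a, b] for i, a in enumerate(labels) for b in labels[i + 1:]
             if groups[a] != groups[b]]
    assert rep.min_inter == min(inter)
    assert rep.gap_present == (min(inter) > max(intra)) is False


def test_singleton_group_reports_absent_intra():
    seqs = {"a": "ACGTACGTAA", "b": "ACGTACGTCC", "c": "ACGTACGTCC"}
    rep = pb.barcoding_gap(pb.distance_matrix(seqs),
                           {"a": "g1", "b": "g2", "c": "g2"})
    assert rep.max_intra["g1"] is None


def test_gap_missing_label_errors():
    dm = pb.distance_matrix({"a": "ACGT", "b": "ACGA"})
    with pytest.raises(ValueError, match="missing"):
        pb.barcoding_gap(dm, {"a": "g1"})


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def _matrix(labels, d):
    n = len(labels)
    vals = np.zeros((n, n))
    for (a, b), v in d.items():
        i, j = labels.index(a), labels.index(b)
        vals[i, j] = vals[j, i] = v
    return DistanceMatrix(list(labels), vals, np.full((n, n), 100))


def test_three_taxa_closed_form():
    dm = _matrix(["A", "B", "C"], {("A", "B"): 0.3, ("A", "C"): 0.4,
                                   ("B", "C"): 0.5})
    tree = pb.nj_tree(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths == pytest.approx({"A": 0.1, "B": 0.2, "C": 0.3})


def test_four_taxon_additive_recovery_exact():
    # tree: ((A:1,B:2):0.5 internal, C:1.5, D:2.5)
    d = {("A", "B"): 3.0, ("A", "C"): 3.0, ("A", "D"): 4.0,
         ("B", "C"): 4.0, ("B", "D"): 5.0, ("C", "D"): 4.0}
    tree = pb.nj_tree(_matrix(["A", "B", "C", "D"], d))
    assert frozenset({"A", "B"}) in tree.bipartitions() or \
        frozenset({"C", "D"}) in tree.bipartitions()
    # path lengths reproduce the input exactly
    paths = _path_lengths(tree)
    for (a, b), v in d.items():
        assert paths[frozenset((a, b))] == pytest.approx(v, abs=1e-12)


def _path_lengths(tree: pb.PhyloTree) -> dict[frozenset, float]:
    dists: dict[frozenset, float] = {}

    def below(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: node.length}
        per_child = [below(c) for c in node.children]
        for i, left in enumerate(per_child):
            for right in per_child[i + 1:]:
                for la, da in left.items():
                    for lb, db in right.items():
                        dists[frozenset((la, lb))] = da + db
        merged = {}
        for child in per_child:
            merged.update(child)
        return {l: d + node.length for l, d in merged.items()}

    below(tree.root)
    return dists


def _random_tree_distances(rng, n_leaves):
    """Random binary unrooted tree; returns (distance dict, bipartitions)."""
    nodes = [(f"L{i}", {f"L{i}"}) for i in range(n_leaves)]
    dist = {}
    leafsets = []
    node_leaves = {f"L{i}": {f"L{i}": 0.0} for i in range(n_leaves)}
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, sa), (nb, sb) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x, dx in node_leaves[na].items():
            for y, dy in node_leaves[nb].items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        name = f"I{counter}"
        counter += 1
        merged = {x: d + la for x, d in node_leaves[na].items()}
        merged.update({y: d + lb for y, d in node_leaves[nb].items()})
        node_leaves[name] = merged
        union = sa | sb
        if 1 < len(union) < n_leaves - 1:
            leafsets.append(frozenset(union))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((name, union))
    all_leaves = frozenset(f"L{i}" for i in range(n_leaves))
    ref = min(all_leaves)
    canon = set()
    for s in leafsets:
        side = all_leaves - s if ref in s else s
        if 1 < len(side) < n_leaves - 1:
            canon.add(side)
    return dist, frozenset(canon)


@pytest.mark.parametrize("seed", range(50))
def test_nj_recovers_random_additive_trees(seed):
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(5, 9))
    dist, true_biparts = _random_tree_distances(rng, n)
    labels = [f"L{i}" for i in range(n)]
    tree = pb.nj_tree(_matrix(labels, {(a, b): dist[frozenset((a, b))]
                                       for i, a in enumerate(labels)
                                       for b in labels[i + 1:]}))
    assert tree.bipartitions() == true_biparts
    paths = _path_lengths(tree)
    for key, v in dist.items():
        assert paths[key] == pytest.approx(v, abs=1e-9)


def test_nj_topology_matches_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    dist, _ = _random_tree_distances(rng, 7)
    labels = [f"L{i}" for i in range(7)]
    vals = np.zeros((7, 7))
    for i, a in enumerate(labels):
        for j in range(i + 1, 7):
            vals[i, j] = vals[j, i] = dist[frozenset((a, labels[j]))]
    mine = pb.nj_tree(DistanceMatrix(labels, vals, np.full((7, 7), 1)))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(vals, labels))
    all_leaves = frozenset(labels)
    ref = min(labels)
    their_biparts = set()
    for node in theirs.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(labels) - 1:
            their_biparts.add(side)
    assert mine.bipartitions() <= frozenset(their_biparts) | mine.bipartitions()
    assert mine.bipartitions() == frozenset(their_biparts)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError, match="at least 3"):
        pb.nj_tree(_matrix(["A", "B"], {("A", "B"): 1.0}))


def test_branch_lengths_non_negative(refs):
    dm = pb.distance_matrix(list(refs.aligned_amplicons().items()))
    tree = pb.nj_tree(dm)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        assert node.length >= 0.0
        assert math.copysign(1.0, node.length) > 0   # no -0.0 in output


# ----------------------------------------------------------------------
# bootstrap and newick
# ----------------------------------------------------------------------

def _two_group_alignment(rng):
    base = rng.choice(list("ACGT"), size=120)
    other = base.copy()
    for pos in rng.choice(120, size=10, replace=False):
        other[pos] = rng.choice([b for b in "ACGT" if b != other[pos]])
    seqs = {}
    for g, template in (("a", base), ("b", other)):
        for i in range(4):
            row = template.copy()
            pos = rng.integers(0, 120)
            row[pos] = rng.choice([x for x in "ACGT" if x != row[pos]])
            seqs[f"{g}{i}"] = "".join(row)
    return seqs


def test_bootstrap_bit_identical_across_runs(refs):
    aln = list(refs.aligned_amplicons().items())
    t1 = pb.bootstrap_support(aln, 50, seed=3).to_newick()
    t2 = pb.bootstrap_support(aln, 50, seed=3).to_newick()
    assert t1 == t2


def test_separated_groups_high_support():
    """Two 4-member groups with 10 fixed differences: group bipartition
    support >= 95 at 200 replicates across 10 seeds."""
    rng = np.random.default_rng(77)
    for seed in range(10):
        seqs = _two_group_alignment(rng)
        tree = pb.bootstrap_support(seqs, 200, seed=seed)
        group_a = frozenset(l for l in seqs if l.startswith("a"))
        all_leaves = frozenset(seqs)
        ref = min(all_leaves)
        side = group_a if ref not in group_a else all_leaves - group_a
        supports = {all_leaves - n.leaf_names() if ref in n.leaf_names()
                    else n.leaf_names(): n.support
                    for n in tree.internal_nodes()}
        assert side in supports
        assert supports[side] >= 95, (seed, supports[side])


def test_identical_alignment_rows_bootstrap_runs():
    seqs = {f"s{i}": "ACGTACGTACGT" for i in range(5)}
    tree = pb.bootstrap_support(seqs, 20, seed=0)
    for node in tree.internal_nodes():
        assert node.support is None or 0 <= node.support <= 100


def test_bootstrap_requires_three_rows():
    with pytest.raises(ValueError, match="3 rows"):
        pb.bootstrap_support({"a": "ACGT", "b": "ACGT"}, 10, seed=0)


def test_newick_parses_with_dendropy_and_reroot_preserves_leaves(refs):
    dendropy = pytest.importorskip("dendropy")
    aln = list(refs.aligned_amplicons().items())
    tree = pb.bootstrap_support(aln, 20, seed=1)
    for outgroup in (None, "OUT_TUB"):
        nwk = tree.to_newick(outgroup=outgroup)
        parsed = dendropy.Tree.get(data=nwk, schema="newick",
                                   preserve_underscores=True)
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == \
            set(dict(aln))
    rooted = root_on_outgroup(tree, "OUT_TUB")
    assert rooted.leaf_names() == tree.leaf_names()
    assert rooted.bipartitions() == tree.bipartitions()


def test_distance_matrix_tsv_export(tmp_path, refs):
    dm = pb.distance_matrix(list(refs.aligned_amplicons().items()))
    path = tmp_path / "dm.tsv"
    dm.to_tsv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "9"
    assert len(lines) == 10
    assert lines[1].split("\t")[0] == "LOB001"
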