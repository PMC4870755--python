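"""K2P distances, neighbor joining (with an exhaustive additive-matrix
oracle), bootstrap, cluster assignment, distinguishing sites."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mthap
from mthap import DistanceMatrix, MthapError, SaturationError
from mthap.haplotyping import tree_splits

DNA = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestK2P:
    def test_identical_is_zero(self):
        assert mthap.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_example(self):
        # 100 sites, 10 transitions, 5 transversions
        s1 = "A" * 85 + "A" * 10 + "A" * 5
        s2 = "A" * 85 + "G" * 10 + "C" * 5
        d = mthap.k2p_distance(s1, s2)
        assert d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.90)),
                                  abs=1e-12)
        assert d == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_error(self):
        s1 = "A" * 10
        s2 = "G" * 5 + "A" * 5  # P = 0.5, Q = 0
        with pytest.raises(SaturationError):
            mthap.k2p_distance(s1, s2)

    def test_gap_and_n_sites_excluded(self):
        c = mthap.site_pair_counts("ACGT-N", "ACGTAC")
        assert c.n == 4 and c.ts == 0 and c.tv == 0

    def test_all_gap_errors(self):
        with pytest.raises(MthapError):
            mthap.k2p_distance("---", "AAA")

    def test_jukes_cantor_limit(self):
        # with ts:tv = 1:2 the K2P form reduces to -(3/4) ln(1 - 4p/3)
        for p in (0.03, 0.12, 0.30):
            n = 3000
            ts, tv = int(n * p / 3), int(n * 2 * p / 3)
            s1 = "A" * n
            s2 = "G" * ts + "C" * tv + "A" * (n - ts - tv)
            d = mthap.k2p_distance(s1, s2)
            peff = (ts + tv) / n
            assert d == pytest.approx(-0.75 * math.log(1 - 4 * peff / 3),
                                      rel=1e-9)

    @given(DNA)
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_zero_property(self, s):
        other = s[::-1]
        try:
            d_ab = mthap.k2p_distance(s, other)
            d_ba = mthap.k2p_distance(other, s)
        except SaturationError:
            return
        assert d_ab == d_ba
        assert (d_ab == 0) == (s == other)


class TestPairwiseDistances:
    def test_identical_sequences_zero_matrix(self):
        dm = mthap.pairwise_distances(["ACGT"] * 3)
        assert np.all(dm.d == 0)

    def test_five_consensus_dloops_strictly_positive(self, dloop_alignment):
        seqs, labels = dloop_alignment
        one_each = {l[0]: s for s, l in zip(seqs, labels)}
        dm = mthap.pairwise_distances(list(one_each.values()),
                                      list(one_each.keys()))
        off = dm.d[~np.eye(5, dtype=bool)]
        assert (off > 0).all()

    def test_single_sequence(self):
        dm = mthap.pairwise_distances(["ACGT"])
        assert dm.d.shape == (1, 1) and dm.d[0, 0] == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(MthapError):
            mthap.pairwise_distances(["ACGT", "ACG"])


# ---------------------------------------------------------------------------
# exhaustive NJ oracle: all unrooted 4- and 5-taxon topologies
# ---------------------------------------------------------------------------

def _enumerate_topologies(n_taxa):
    """All unrooted binary topologies as edge lists; leaves are 0..n-1."""
    base = [(-1, 0), (-1, 1), (-1, 2)]
    trees = [base]
    next_internal = [-2]
    for leaf in range(3, n_taxa):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal[0]
                new = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, leaf)]
                new_trees.append(new)
        trees = new_trees
        next_internal[0] -= 1
    return trees


def _path_matrix(edges, lengths, n_taxa):
    nodes = {x for e in edges for x in e}
    adj = {x: [] for x in nodes}
    for (u, v), l in zip(edges, lengths):
        adj[u].append((v, l))
        adj[v].append((u, l))
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, l in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + l
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    return d


def _true_splits(edges, n_taxa):
    splits = set()
    for i, (u, v) in enumerate(edges):
        if u >= 0 or v >= 0:
            continue  # leaf edge
        adj = {}
        for j, (a, b) in enumerate(edges):
            if j == i:
                continue
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            x = stack.pop()
            if 0 <= x < n_taxa:
                side.add(x)
            for y in adj.get(x, []):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(side) < n_taxa - 1:
            names = frozenset(str(x) for x in side)
            anchor = "0"
            allv = frozenset(str(x) for x in range(n_taxa))
            splits.add(names if anchor not in names else allv - names)
    return splits


def _tree_path_matrix(root, labels):
    adj = {}

    def walk(node):
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length, c))
            adj.setdefault(id(c), []).append((id(node), c.length, node))
            walk(c)

    walk(root)
    leaf_ids = {l.name: id(l) for l in root.leaves()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {leaf_ids[a]: 0.0}
        stack = [leaf_ids[a]]
        while stack:
            x = stack.pop()
            for y, l, _ in adj.get(x, []):
                if y not in dist:
                    dist[y] = dist[x] + l
                    stack.append(y)
        for j, b in enumerate(labels):
            d[i, j] = dist[leaf_ids[b]]
    return d


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_recovers_all_additive_topologies(self, n_taxa):
        """Exhaustive oracle: NJ must recover topology and branch lengths
        for additive matrices from every unrooted 4- and 5-taxon tree."""
        topos = _enumerate_topologies(n_taxa)
        assert len(topos) == {4: 3, 5: 15}[n_taxa]
        rng = np.random.default_rng(42)
        labels = [str(i) for i in range(n_taxa)]
        for edges in topos:
            for _ in range(3):  # several random length assignments each
                lengths = rng.uniform(0.05, 1.0, size=len(edges))
                dm = DistanceMatrix(labels,
                                    _path_matrix(edges, lengths, n_taxa))
                tree = mthap.nj_tree(dm)
                assert tree_splits(tree) == _true_splits(edges, n_taxa)
                recovered = _tree_path_matrix(tree, labels)
                assert np.allclose(recovered, dm.d, atol=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = mthap.nj_tree(DistanceMatrix(["1", "2", "3"], d))
        lens = {l.name: l.length for l in tree.leaves()}
        assert lens["1"] == pytest.approx((3 + 4 - 5) / 2)
        assert lens["2"] == pytest.approx((3 + 5 - 4) / 2)
        assert lens["3"] == pytest.approx((4 + 5 - 3) / 2)

    def test_equal_distance_ties_first_index(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = mthap.nj_tree(DistanceMatrix(list("wxyz"), d))
        # first-index pair (w, x) joined first
        splits = tree_splits(tree)
        assert splits <= {frozenset({"y", "z"})}  # {wx|yz} or a star

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(MthapError):
            mthap.nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestBootstrap:
    def test_single_replicate_supports_binary(self, dloop_alignment):
        seqs, labels = dloop_alignment
        tree, _ = mthap.bootstrap_support(seqs[:20], labels[:20],
                                          n_replicates=1, seed=0)
        sups = [n.support for n in _internal_nodes(tree)
                if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_identical_seeds_identical_supports(self, dloop_alignment):
        seqs, labels = dloop_alignment
        t1, _ = mthap.bootstrap_support(seqs, labels, 25, seed=7)
        t2, _ = mthap.bootstrap_support(seqs, labels, 25, seed=7)
        s1 = sorted(n.support for n in _internal_nodes(t1)
                    if n.support is not None)
        s2 = sorted(n.support for n in _internal_nodes(t2)
                    if n.support is not None)
        assert s1 == s2


def _internal_nodes(root):
    out = []

    def walk(n):
        for c in n.children:
            if c.children:
                out.append(c)
                walk(c)

    walk(root)
    return out


class TestAssignHaplotypes:
    def test_zero_threshold_all_singletons(self):
        dm = mthap.pairwise_distances(["AAAAAAAA", "AAAAAAAG", "AAAAAAGG"])
        asg = mthap.assign_haplotypes(dm, 0.0)
        assert asg.n_clusters == 3

    def test_boundary_tie_unassigned(self):
        t = 0.1
        d = np.array([[0, 3 * t, t], [3 * t, 0, t], [t, t, 0]])
        asg = mthap.assign_haplotypes(
            DistanceMatrix(["x", "y", "z"], d), t)
        assert asg.assignments["z"] == "unassigned"
        assert asg.assignments["x"] != "unassigned"

    def test_labels_by_size_then_first_seen(self):
        # 3 identical + 2 identical + 1 singleton
        base = "A" * 40
        seqs = (["GG" + base[2:]] * 2 + [base] * 3
                + [base[:-2] + "GG"])
        labels = [f"s{i}" for i in range(6)]
        dm = mthap.pairwise_distances(seqs, labels)
        asg = mthap.assign_haplotypes(dm, 1e-6)
        assert asg.assignments["s2"] == "A"   # largest cluster
        assert asg.assignments["s0"] == "B"
        assert asg.assignments["s5"] == "C"

    def test_full_recovery_from_profiles(self, dloop_alignment):
        seqs, labels = dloop_alignment
        dm = mthap.pairwise_distances(seqs, labels)
        asg = mthap.assign_haplotypes(dm, 4e-4)
        assert asg.n_clusters == 5
        # zero within-haplotype divergence -> exact recovery of the grouping
        for lab in labels:
            assert asg.assignments[lab] == asg.assignments[f"{lab[0]}0"]


class TestDistinguishingSites:
    def test_reference_only_is_empty(self, reference):
        cons = {h: mthap.apply_profile(reference,
                                       mthap.HaplotypeProfile(h, []))
                for h in "AB"}
        sites, shared = mthap.find_distinguishing_sites(cons, reference)
        assert sites == [] and shared == []

    def test_shared_sites_not_distinguishing(self, reference, consensuses):
        sites, shared = mthap.find_distinguishing_sites(consensuses,
                                                        reference)
        assert len(shared) == 30
        assert all(s.unique_to is None for s in shared)
        assert not {s.position for s in sites} & {s.position for s in shared}

    def test_plain_string_input(self, reference):
        seq = list(reference.sequence)
        seq[99] = "A" if seq[99] != "A" else "C"
        sites, _ = mthap.find_distinguishing_sites(
            {"X": "".join(seq), "Y": reference.sequence}, reference)
        assert len(sites) == 1 and sites[0].position == 100
        assert sites[0].unique_to == "X"

    def test_unaligned_input_rejected(self, reference):
        with pytest.raises(MthapError):
            mthap.find_distinguishing_sites(
                {"X": reference.sequence[:-5]}, reference)
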