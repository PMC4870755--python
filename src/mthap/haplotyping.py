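"""Haplotype assignment from aligned mtDNA sequences.

Kimura two-parameter distances, Saitou-Nei neighbor joining with bootstrap
support, single-linkage cluster assignment, and detection of the polymorphic
sites that distinguish haplotype consensuses from a reference backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .genome import AnnotatedGenome, MthapError
from .simulate import HaplotypeConsensus, Polymorphism, diff_against_reference


class SaturationError(MthapError):
    """Distances are saturated: the K2P log argument is non-positive."""


# ---------------------------------------------------------------------------
# Kimura 2P distance
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class SitePairCounts:
    n: int    # compared sites (both defined, no gaps/N)
    ts: int   # transitions
    tv: int   # transversions

    @property
    def P(self) -> float:
        return self.ts / self.n

    @property
    def Q(self) -> float:
        return self.tv / self.n


def site_pair_counts(seq1: str, seq2: str) -> SitePairCounts:
    """Transition/transversion counts under pairwise deletion of gaps and N."""
    if len(seq1) != len(seq2):
        raise MthapError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return SitePairCounts(n, ts, tv)


def k2p_from_counts(counts: SitePairCounts) -> float:
    if counts.n == 0:
        raise MthapError("no comparable sites (all gaps/N)")
    P, Q = counts.P, counts.Q
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise SaturationError(
            f"K2P distance saturated (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(a * math.sqrt(b))


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2P distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    return k2p_from_counts(site_pair_counts(seq1, seq2))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Alignment -> uint8 codes: A=0 G=1 C=2 T=3, anything else 255."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("AGCT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


def _k2p_matrix(enc: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    n = enc.shape[0]
    d = np.zeros((n, n))
    valid = enc != 255
    purine = enc < 2  # A,G
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise MthapError(
                    f"no comparable sites between {labels[i]} and {labels[j]}")
            diff = both & (enc[i] != enc[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / m, tv / m
            a, b = 1 - 2 * P - Q, 1 - 2 * Q
            if a <= 0 or b <= 0:
                raise SaturationError(
                    f"pair ({labels[i]}, {labels[j]}) is saturated")
            d[i, j] = d[j, i] = -0.5 * math.log(a * math.sqrt(b))
    return d


def pairwise_distances(sequences: Sequence[str],
                       labels: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """K2P distance matrix over an equal-length alignment."""
    if labels is None:
        labels = [f"seq{i}" for i in range(len(sequences))]
    if len(set(len(s) for s in sequences)) > 1:
        raise MthapError("all sequences must have the same aligned length")
    if len(sequences) == 0:
        raise MthapError("no sequences given")
    enc = _encode(sequences)
    return DistanceMatrix(list(labels), _k2p_matrix(enc, list(labels)))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def tree_splits(root: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as the
    side not containing the alphabetically first leaf."""
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not root and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    walk(root)
    return splits


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root).

    Taxa at distance zero from each other are agglomerated first into a
    zero-length multifurcation (their relative arrangement carries no
    signal), which canonicalizes the otherwise arbitrary tie order among
    identical sequences. Remaining ties in the Q-criterion are broken by
    first (row-major) index order. Negative branch lengths are clamped to
    zero with the deficit transferred to the sibling edge.
    """
    n = len(matrix.labels)
    if n < 3:
        raise MthapError("neighbor joining needs at least 3 taxa")

    # collapse zero-distance groups
    parent_uf = list(range(n))

    def find(x):
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.d[i, j] == 0.0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent_uf[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    if len(groups) < n:
        reps = sorted(groups)
        rep_nodes = []
        for r in reps:
            members = groups[r]
            if len(members) == 1:
                rep_nodes.append(TreeNode(name=matrix.labels[members[0]]))
            else:
                rep_nodes.append(TreeNode(children=[
                    TreeNode(name=matrix.labels[m], length=0.0)
                    for m in members]))
        if len(reps) == 1:
            return rep_nodes[0]
        if len(reps) == 2:
            half = matrix.d[reps[0], reps[1]] / 2
            for node in rep_nodes:
                node.length = half
            return TreeNode(children=rep_nodes)
        sub = DistanceMatrix([f"g{k}" for k in range(len(reps))],
                             matrix.d[np.ix_(reps, reps)])
        skeleton = nj_tree(sub)
        lookup = dict(zip(sub.labels, rep_nodes))

        def graft(node: TreeNode) -> TreeNode:
            if not node.children:
                real = lookup[node.name]
                real.length = node.length
                real.support = node.support
                return real
            node.children = [graft(c) for c in node.children]
            return node

        return graft(skeleton)

    d = matrix.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in matrix.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))          # first-index tie-break (row-major)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ai, aj = active[i], active[j]
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = max(0.0, (dab + dac - dbc) / 2)
    lb = max(0.0, (dab + dbc - dac) / 2)
    lc = max(0.0, (dac + dbc - dab) / 2)
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = ln
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def bootstrap_support(sequences: Sequence[str],
                      labels: Sequence[str],
                      n_replicates: int = 100,
                      seed: int = 0) -> tuple[TreeNode, int]:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; support is
    the percentage of replicate trees containing each original internal split.
    Replicates with a saturated pair are skipped (count returned).
    """
    if n_replicates < 1:
        raise MthapError("need at least one bootstrap replicate")
    labels = list(labels)
    enc = _encode(sequences)
    tree = nj_tree(DistanceMatrix(labels, _k2p_matrix(enc, labels)))
    original = tree_splits(tree)
    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    n_cols = enc.shape[1]
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_d = _k2p_matrix(enc[:, cols], labels)
            rep = nj_tree(DistanceMatrix(labels, rep_d))
        except SaturationError:
            skipped += 1
            continue
        rep_splits = tree_splits(rep)
        for s in original:
            if s in rep_splits:
                counts[s] += 1
    done = n_replicates - skipped
    supports = {s: (100.0 * c / done if done else 0.0)
                for s, c in counts.items()}

    all_leaves = frozenset(labels)
    anchor = min(all_leaves)

    def annotate(node: TreeNode, root: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, root) for c in node.children))
        if node is not root and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = supports[side]
        return below

    annotate(tree, tree)
    if skipped:
        import logging
        logging.getLogger(__name__).info(
            "bootstrap: %d of %d replicates skipped (saturation)",
            skipped, n_replicates)
    return tree, skipped


# ---------------------------------------------------------------------------
# cluster assignment
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssignment:
    assignments: dict[str, str]   # individual -> label or "unassigned"
    threshold: float
    n_clusters: int
    metadata: dict = field(default_factory=dict)


def assign_haplotypes(matrix: DistanceMatrix, threshold: float,
                      labels_pool: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
                      ) -> HaplotypeAssignment:
    """Single-linkage clusters at a distance threshold, labelled A, B, ...

    Clusters are connected components of the graph d < threshold, labelled by
    descending size then first-seen order. An individual whose own cluster is
    a singleton sitting at exactly the threshold distance from two or more
    clusters is reported "unassigned" (tie rule).
    """
    if threshold < 0:
        raise MthapError("threshold must be >= 0")
    n = len(matrix.labels)
    d = matrix.d
    # union-find over strict-inequality edges
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    clusters = sorted(comp.values(), key=lambda ms: (-len(ms), ms[0]))

    assignments: dict[str, str] = {}
    cluster_of = {}
    for ci, members in enumerate(clusters):
        for m in members:
            cluster_of[m] = ci
    for ci, members in enumerate(clusters):
        label = labels_pool[ci] if ci < len(labels_pool) else f"H{ci + 1}"
        for m in members:
            assignments[matrix.labels[m]] = label
    # boundary tie rule
    for ci, members in enumerate(clusters):
        if len(members) != 1:
            continue
        m = members[0]
        at_threshold = set()
        for j in range(n):
            if j != m and d[m, j] == threshold:
                at_threshold.add(cluster_of[j])
        if len(at_threshold) >= 2:
            assignments[matrix.labels[m]] = "unassigned"

    return HaplotypeAssignment(
        assignments=assignments,
        threshold=threshold,
        n_clusters=len(clusters),
        metadata={"linkage": "single"},
    )


# ---------------------------------------------------------------------------
# distinguishing sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistinguishingSite:
    position: int
    alleles: tuple[tuple[str, str], ...]  # (haplotype, allele-name) pairs
    unique_to: Optional[str]              # None for shared sites
    kind: str


def find_distinguishing_sites(
    consensuses: Union[dict[str, HaplotypeConsensus], dict[str, str]],
    reference: AnnotatedGenome,
) -> tuple[list[DistinguishingSite], list[DistinguishingSite]]:
    """Sites where haplotype consensuses differ from the reference backbone.

    A site is *distinguishing* iff exactly one haplotype differs from the
    reference there (``unique_to`` names it); sites where two or more
    haplotypes differ are returned separately as *shared*.

    Consensuses may be HaplotypeConsensus objects (indels projected through
    their coordinate maps) or plain strings of the reference's length.
    """
    diffs: dict[str, list[Polymorphism]] = {}
    for hap, cons in consensuses.items():
        if isinstance(cons, HaplotypeConsensus):
            diffs[hap] = diff_against_reference(cons, reference)
        else:
            seq = str(cons).upper()
            if len(seq) != reference.length:
                raise MthapError(
                    f"consensus {hap} is not aligned to reference coordinates "
                    f"({len(seq)} vs {reference.length} bp); supply a "
                    "HaplotypeConsensus with its projection instead")
            diffs[hap] = [
                Polymorphism(i + 1, reference.base(i + 1), b, "SNV")
                for i, b in enumerate(seq) if b != reference.base(i + 1)
            ]

    by_position: dict[int, dict[str, Polymorphism]] = {}
    for hap, changes in diffs.items():
        for ch in changes:
            by_position.setdefault(ch.position, {})[hap] = ch

    distinguishing, shared = [], []
    for pos in sorted(by_position):
        carriers = by_position[pos]
        alleles = tuple(sorted((h, c.name) for h, c in carriers.items()))
        kinds = {c.kind for c in carriers.values()}
        kind = kinds.pop() if len(kinds) == 1 else "mixed"
        if len(carriers) == 1:
            (hap,) = carriers
            distinguishing.append(
                DistinguishingSite(pos, alleles, hap, kind))
        else:
            shared.append(DistinguishingSite(pos, alleles, None, kind))
    return distinguishing, shared
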