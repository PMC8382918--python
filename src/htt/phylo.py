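"""Distances, NJ trees, the donor/recipient nesting test, and UPGMA
activity histories.

Trees are :class:`dendropy.Tree` objects throughout.  The NJ construction
follows Saitou & Nei's Q-criterion with deterministic label-order
tie-breaking and negative branch lengths clamped to zero.  The UPGMA
activity history treats identity distances (``d = 100 - %identity``) as a
relative molecular clock: every internal node of the average-linkage
dendrogram marks a branching (amplification) event, and the node heights
binned at 1% intervals sketch when a TE family was transpositionally
active.  Node height is merge distance / 2 (the ultrametric convention, so
heights read as per-lineage divergence); the raw merge distances are kept
alongside since either convention can be plotted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "ActivityHistory",
    "p_distance",
    "p_distance_matrix",
    "nj_tree",
    "nesting_test",
    "upgma_history",
    "leaf_taxon",
    "taxa_form_clade",
]


def leaf_taxon(label: str) -> str:
    """Taxon part of a leaf label; copies of one taxon are ``taxon|copy``."""
    return label.split("|")[0]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    metric: str = "p_distance"  # or "identity_distance"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


def p_distance(seq_a: str, seq_b: str, pairwise_deletion: bool = True) -> float:
    """Proportion of differing sites between two aligned sequences.

    With pairwise deletion (the default) every column where either sequence
    has a gap or N is excluded; otherwise such columns count as differences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = seq_a.upper(), seq_b.upper()
    skip = {"-", "N"}
    mism = 0
    kept = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            if not pairwise_deletion:
                kept += 1
                mism += 1
            continue
        kept += 1
        if x != y:
            mism += 1
    if kept == 0:
        raise ValueError("no retained columns after pairwise deletion")
    return mism / kept


def p_distance_matrix(
    labels: list[str], aligned_seqs: list[str], pairwise_deletion: bool = True
) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = p_distance(
            aligned_seqs[i], aligned_seqs[j], pairwise_deletion
        )
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# Neighbor joining


def _clamp(length: float) -> float:
    if length < 0:
        warnings.warn("negative branch length clamped to 0", stacklevel=3)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Q-criterion agglomeration with deterministic tie-breaking by the
    smallest leaf label contained in each active node; negative branch
    lengths are clamped to 0 with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    # active nodes: key -> (newick fragment, smallest contained leaf label)
    nodes: dict[int, tuple[str, str]] = {
        i: (lab, lab) for i, lab in enumerate(dm.labels)
    }
    dist: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = float(dm.d[i, j])
    next_id = n

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(nodes) > 3:
        keys = sorted(nodes)
        r = len(keys)
        rowsum = {i: sum(d(i, k) for k in keys if k != i) for i in keys}
        best = None
        for i, j in itertools.combinations(keys, 2):
            q = (r - 2) * d(i, j) - rowsum[i] - rowsum[j]
            tie = tuple(sorted((nodes[i][1], nodes[j][1])))
            cand = (q, tie, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        li = 0.5 * d(i, j) + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        li, lj = _clamp(li), _clamp(lj)
        new_key = next_id
        next_id += 1
        for k in keys:
            if k in (i, j):
                continue
            dist[(min(k, new_key), max(k, new_key))] = max(
                0.0, 0.5 * (d(i, k) + d(j, k) - d(i, j))
            )
        frag = f"({nodes[i][0]}:{li:.17g},{nodes[j][0]}:{lj:.17g})"
        nodes[new_key] = (frag, min(nodes[i][1], nodes[j][1]))
        del nodes[i], nodes[j]
        dist = {
            (a, b): v for (a, b), v in dist.items() if a in nodes and b in nodes
        }

    (i, j, k) = sorted(nodes)
    dij, dik, djk = d(i, j), d(i, k), d(j, k)
    li = _clamp(0.5 * (dij + dik - djk))
    lj = _clamp(0.5 * (dij + djk - dik))
    lk = _clamp(0.5 * (dik + djk - dij))
    newick = (
        f"({nodes[i][0]}:{li:.17g},{nodes[j][0]}:{lj:.17g},"
        f"{nodes[k][0]}:{lk:.17g});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Nesting test


def _tree_adjacency(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Undirected adjacency of the tree with degree-2 nodes suppressed.

    Returns (adjacency: node -> set(node), leaf_label: node -> label).
    """
    adj: dict = {}
    leaf_label: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or edge.head_node is None:
            continue
        a, b = edge.tail_node, edge.head_node
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    for leaf in tree.leaf_node_iter():
        leaf_label[leaf] = leaf.taxon.label if leaf.taxon else ""
    # suppress internal degree-2 nodes (e.g. an artificial root)
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node in leaf_label:
                continue
            if len(adj[node]) == 2:
                u, v = adj[node]
                adj[u].discard(node)
                adj[v].discard(node)
                adj[u].add(v)
                adj[v].add(u)
                del adj[node]
                changed = True
    return adj, leaf_label


def _component_leaves(adj, leaf_label, start, blocked_edge) -> set[str]:
    """Leaf labels reachable from ``start`` without crossing blocked_edge."""
    seen = {start}
    stack = [start]
    labels = set()
    while stack:
        node = stack.pop()
        if node in leaf_label:
            labels.add(leaf_label[node])
        for nxt in adj[node]:
            if {node, nxt} == set(blocked_edge) or nxt in seen:
                continue
            seen.add(nxt)
            stack.append(nxt)
    return labels


def _edges(adj) -> list[tuple]:
    out = []
    seen = set()
    for a in adj:
        for b in adj[a]:
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                out.append((a, b))
    return out


def _component_nodes(adj, start, blocked_edge) -> set:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in adj[node]:
            if {node, nxt} == set(blocked_edge) or nxt in seen:
                continue
            seen.add(nxt)
            stack.append(nxt)
    return seen


def _nested(adj, leaf_label, inner: set[str], outer: set[str]) -> bool:
    """True iff ``inner`` leaves form one side of an edge and the other
    side's subtree has an internal edge with ``outer`` leaves on both sides
    (i.e. the outer set's diversity straddles the attachment point).

    Requiring an *internal* edge of the complement means a balanced split,
    or a single stray leaf, never qualifies as nesting.
    """

    def side_leaves(start, blocked) -> set[str]:
        seen = {start}
        stack = [start]
        labels: set[str] = set()
        while stack:
            node = stack.pop()
            if node in leaf_label:
                labels.add(leaf_label[node])
            for nxt in adj[node]:
                if any({node, nxt} == set(e) for e in blocked) or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
        return labels

    for a, b in _edges(adj):
        side_a = _component_leaves(adj, leaf_label, a, (a, b))
        if side_a == inner:
            attach = b
        elif _component_leaves(adj, leaf_label, b, (a, b)) == inner:
            attach = a
        else:
            continue
        clade_edge = (a, b)
        comp_nodes = _component_nodes(adj, attach, clade_edge)
        for u, v in _edges(adj):
            if u not in comp_nodes or v not in comp_nodes:
                continue
            if u in leaf_label or v in leaf_label:
                continue  # pendant edge, not internal
            left = side_leaves(u, [(u, v), clade_edge])
            right = side_leaves(v, [(u, v), clade_edge])
            if (left & outer) and (right & outer):
                return True
    return False


def _max_within_distance(tree: dendropy.Tree, labels: set[str]) -> float:
    """Largest patristic distance within a label set (missing lengths = 1)."""
    if len(labels) < 2:
        return 0.0
    work = tree.clone(depth=1)
    for edge in work.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    pdm = work.phylogenetic_distance_matrix()
    taxa = [t for t in work.taxon_namespace if t.label in labels]
    best = 0.0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            best = max(best, pdm.distance(taxa[i], taxa[j]))
    return best


def nesting_test(
    tree: dendropy.Tree,
    donor_labels: set[str],
    recipient_labels: set[str],
    depth_ratio: float = 1.5,
) -> str:
    """Infer transfer direction from how one label set nests in the other.

    ``recipient_nested_in_donor`` means the recipient leaves form a clade
    (root-agnostically: one side of some edge) while donor diversity
    straddles its attachment point — the pattern left by a transfer out of
    an already diversified donor lineage.  A balanced split, where neither
    set's diversity surrounds the other's attachment, is ``not_nested``.
    When the structural reading holds in both directions the deeper
    lineage is taken as the surrounding one: the verdict follows the set
    whose internal patristic depth exceeds the other's by ``depth_ratio``
    (a relative molecular clock; a recent transfer leaves the recipient
    family shallow), and stays ``not_nested`` if depths are comparable.
    """
    donor_labels = set(donor_labels)
    recipient_labels = set(recipient_labels)
    if donor_labels & recipient_labels:
        raise ValueError("donor and recipient label sets must be disjoint")
    adj, leaf_label = _tree_adjacency(tree)
    present = set(leaf_label.values())
    missing = (donor_labels | recipient_labels) - present
    if missing:
        raise ValueError(f"labels missing from tree: {sorted(missing)}")
    r_in_d = len(donor_labels) >= 2 and _nested(
        adj, leaf_label, recipient_labels, donor_labels
    )
    d_in_r = len(recipient_labels) >= 2 and _nested(
        adj, leaf_label, donor_labels, recipient_labels
    )
    if r_in_d and d_in_r:
        donor_depth = _max_within_distance(tree, donor_labels)
        recip_depth = _max_within_distance(tree, recipient_labels)
        if donor_depth > depth_ratio * recip_depth:
            return "recipient_nested_in_donor"
        if recip_depth > depth_ratio * donor_depth:
            return "donor_nested_in_recipient"
        return "not_nested"
    if r_in_d:
        return "recipient_nested_in_donor"
    if d_in_r:
        return "donor_nested_in_recipient"
    return "not_nested"


def taxa_form_clade(
    tree: dendropy.Tree,
    focal_taxa: set[str],
    allowed_extra: set[str] = frozenset(),
) -> bool:
    """True iff some edge side holds leaves of every focal taxon and of no
    taxon outside ``focal_taxa | allowed_extra``.

    Leaf labels are ``taxon|copy``; the check is at the taxon level, so a
    tree may carry several copies per taxon.
    """
    focal_taxa = set(focal_taxa)
    adj, leaf_label = _tree_adjacency(tree)
    for a, b in _edges(adj):
        for start in (a, b):
            side = _component_leaves(adj, leaf_label, start, (a, b))
            taxa = {leaf_taxon(lab) for lab in side}
            if focal_taxa <= taxa and taxa <= focal_taxa | set(allowed_extra):
                return True
    return False


# ---------------------------------------------------------------------------
# UPGMA activity history


@dataclass
class ActivityHistory:
    """Branching-point heights of one TE cluster under UPGMA."""

    cluster_id: str
    node_heights: list[float]       # merge distance / 2, sorted ascending
    merge_distances: list[float]    # raw merge distances, same order
    histogram: dict[int, int]       # 1%-wide bins of node heights
    tree: dendropy.Tree = field(repr=False)


def upgma_history(
    dm_identity: DistanceMatrix, cluster_id: str = ""
) -> ActivityHistory:
    """UPGMA over an identity-distance matrix (``d = 100 - %identity``).

    Average-linkage agglomeration (group averages weighted by cluster
    size); node height = merge distance / 2; the histogram counts node
    heights in 1% bins and always sums to ``n_leaves - 1``.
    """
    n = len(dm_identity.labels)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    # active clusters: key -> (size, newick fragment, height, min label)
    active: dict[int, tuple[int, str, float, str]] = {
        i: (1, lab, 0.0, lab) for i, lab in enumerate(dm_identity.labels)
    }
    dist: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = float(dm_identity.d[i, j])
    next_id = n
    heights: list[float] = []
    merges: list[float] = []

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        keys = sorted(active)
        best = None
        for i, j in itertools.combinations(keys, 2):
            tie = tuple(sorted((active[i][3], active[j][3])))
            cand = (d(i, j), tie, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        dij, _, i, j = best
        height = dij / 2.0
        heights.append(height)
        merges.append(dij)
        size_i, frag_i, h_i, min_i = active[i]
        size_j, frag_j, h_j, min_j = active[j]
        frag = (
            f"({frag_i}:{max(0.0, height - h_i):.17g},"
            f"{frag_j}:{max(0.0, height - h_j):.17g})"
        )
        new_key = next_id
        next_id += 1
        for k in keys:
            if k in (i, j):
                continue
            merged = (size_i * d(i, k) + size_j * d(j, k)) / (size_i + size_j)
            dist[(min(k, new_key), max(k, new_key))] = merged
        active[new_key] = (size_i + size_j, frag, height, min(min_i, min_j))
        del active[i], active[j]
        dist = {
            (a, b): v for (a, b), v in dist.items() if a in active and b in active
        }

    newick = next(iter(active.values()))[1] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    histogram: dict[int, int] = {}
    for h in heights:
        b = int(h)  # 1% bins
        histogram[b] = histogram.get(b, 0) + 1
    return ActivityHistory(
        cluster_id=cluster_id,
        node_heights=sorted(heights),
        merge_distances=[m for _, m in sorted(zip(heights, merges))],
        histogram=histogram,
        tree=tree,
    )
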