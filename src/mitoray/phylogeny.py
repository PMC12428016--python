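"""Distance-based phylogeny: p/K2P distances, neighbor joining, bootstrap
support, and monophyly testing.

Neighbor joining is the standard Q-criterion agglomeration (Saitou & Nei),
which is exact on additive distance matrices. Ties in the Q matrix break
deterministically by taxon label order; negative branch-length estimates
are clamped to zero with the deficit moved to the sibling branch. Support
values are bootstrap proportions from column resampling — they occupy the
usual support slot in Newick output but are *not* posterior probabilities.
Trees are carried as DendroPy objects; only outgroup rooting is offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class PhylogenyError(ValueError):
    pass


_GAPLIKE = set("-.NX?")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a model tag.

    Saturated K2P pairs (logarithm undefined) are stored as NaN and listed
    in ``undefined_pairs``; neighbor joining refuses incomplete matrices.
    """

    labels: list[str]
    matrix: np.ndarray
    model: str
    undefined_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhylogenyError("matrix shape does not match label count")

    @property
    def complete(self) -> bool:
        return not np.isnan(self.matrix).any()

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.matrix):
            lines.append(label.ljust(12) + " ".join(f"{d:.6f}" for d in row))
        return "\n".join(lines) + "\n"


def _as_items(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, dict):
        return [(k, v.upper()) for k, v in alignment.items()]
    return [(k, v.upper()) for k, v in alignment]


def pairwise_distances(alignment, model: str = "p") -> DistanceMatrix:
    """p-distances or Kimura 2-parameter distances from an alignment.

    ``alignment``: mapping or list of (label, sequence); equal-length
    aligned sequences. Columns with a gap or ambiguous base in either
    sequence of a pair are excluded pairwise. K2P uses the closed form
    d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with transition proportion P and
    transversion proportion Q.
    """
    items = _as_items(alignment)
    if len(items) < 2:
        raise PhylogenyError("need at least two taxa")
    if model not in ("p", "k2p"):
        raise PhylogenyError(f"unknown distance model {model!r}")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise PhylogenyError("sequences are not aligned (unequal lengths)")
    labels = [k for k, _ in items]
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for _, s in items]
    good = [~np.isin(a, np.frombuffer("".join(_GAPLIKE).encode(), dtype=np.uint8)) for a in arrs]
    purine = [np.isin(a, np.frombuffer(b"AG", dtype=np.uint8)) for a in arrs]

    n = len(items)
    mat = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = good[i] & good[j]
            m = int(ok.sum())
            if m == 0:
                raise PhylogenyError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            diff = (arrs[i] != arrs[j]) & ok
            if model == "p":
                d = diff.sum() / m
            else:
                transitions = diff & (purine[i] == purine[j])
                P = transitions.sum() / m
                Q = (diff.sum() - transitions.sum()) / m
                w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
                if w1 <= 0 or w2 <= 0:
                    d = np.nan
                    undefined.append((labels[i], labels[j]))
                else:
                    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, matrix=mat, model=model, undefined_pairs=undefined)


@dataclass
class PhyloTree:
    """A phylogenetic tree wrapping a DendroPy tree.

    Internal-node support values, when present, are bootstrap proportions
    in [0, 1].
    """

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each canonicalized as the
        leaf set on the side *not* containing the alphabetically first
        taxon."""
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(all_leaves - side)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def rooted_on(self, outgroup: str) -> "PhyloTree":
        """A copy rooted on the edge leading to the outgroup leaf."""
        clone = self.tree.clone(depth=1)
        node = None
        for lf in clone.leaf_node_iter():
            if lf.taxon.label == outgroup:
                node = lf
                break
        if node is None:
            raise PhylogenyError(f"unknown outgroup label {outgroup!r}")
        length = node.edge.length or 0.0
        clone.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                             update_bipartitions=False)
        return PhyloTree(clone)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a complete distance matrix.

    Returns an unrooted tree (trifurcation at the final join for >3 taxa).
    """
    if len(dm.labels) < 3:
        raise PhylogenyError("need at least three taxa")
    if not dm.complete:
        raise PhylogenyError(
            f"incomplete distance matrix (undefined pairs: {dm.undefined_pairs})"
        )
    taxon_ns = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    # sort key per cluster for deterministic tie-breaking
    keys = list(dm.labels)
    d = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None  # (q, key_i, key_j, i, j)
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                cand_keys = tuple(sorted((keys[i], keys[j])))
                cand = (q, cand_keys[0], cand_keys[1], i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([np.column_stack([d[np.ix_(keep, keep)], new_d[keep]]),
                       np.append(new_d[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    if len(nodes) == 3:
        l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
        l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
        for node, length in zip(nodes, (l0, l1, l2)):
            node.edge.length = max(length, 0.0)
            tree.seed_node.add_child(node)
    else:  # exactly 2 left (only when starting from 3 taxa handled above)
        for node in nodes:
            tree.seed_node.add_child(node)
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(
    alignment,
    model: str = "p",
    replicates: int = 100,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """Attach bootstrap proportions to the NJ tree of an alignment.

    Columns are resampled with replacement ``replicates`` times; each
    internal edge's support is the fraction of replicate NJ trees
    containing the same bipartition. Reproducible under a fixed seed.
    """
    if replicates < 1:
        raise PhylogenyError("replicates must be >= 1")
    items = _as_items(alignment)
    if tree is None:
        tree = neighbor_joining(pairwise_distances(items, model))
    rng = np.random.default_rng(seed)
    L = len(items[0][1])
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        resampled = [(k, "".join(s[c] for c in cols)) for k, s in items]
        try:
            rep = neighbor_joining(pairwise_distances(resampled, model))
        except PhylogenyError:
            continue  # saturated replicate: counts as absent support
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = tree.leaf_labels
    ref = min(all_leaves)
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(all_leaves - side)
        if side in counts:
            node.label = f"{counts[side] / replicates:.3f}"
    return tree


def is_monophyletic(
    tree: PhyloTree, taxa: set[str], outgroup: str
) -> tuple[bool, frozenset]:
    """Whether ``taxa`` form a clade after rooting the tree on ``outgroup``.

    Returns the verdict and the supporting leaf set (the smallest clade
    containing all of ``taxa`` in the rooted tree).
    """
    taxa = set(taxa)
    leaves = tree.leaf_labels
    unknown = (taxa | {outgroup}) - leaves
    if unknown:
        raise PhylogenyError(f"unknown taxon labels: {sorted(unknown)}")
    if outgroup in taxa:
        raise PhylogenyError("outgroup cannot be part of the tested taxon set")
    if len(taxa) <= 1 or taxa == leaves - {outgroup}:
        return True, frozenset(taxa)
    rooted = tree.rooted_on(outgroup)
    node_taxa = [lf for lf in rooted.tree.leaf_node_iter() if lf.taxon.label in taxa]
    mrca = rooted.tree.mrca(taxa=[lf.taxon for lf in node_taxa])
    clade = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
    return clade == taxa, clade
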