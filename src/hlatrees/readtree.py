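"""Per-read alignment trees: probability propagation and weight distribution.

Every read (pair) that aligns ambiguously gets a tree over the hierarchical
names of the alleles it aligns to: root -> gene -> allele group -> peptide
-> nucleotide -> intron, with each alignment a leaf.  Three rules define
the weighting:

* a leaf's local probability is ``10^(-SMMQ/10)`` (product of the error
  probabilities of its mismatched bases);
* an internal node's probability is the maximum of its children's;
* weight flows down from the root (weight 1 per read by default): a node
  receives ``parent.w * p / sum(p over the parent's children)``, so all of
  a node's weight is distributed among its children.

Probabilities are held in log10 internally; all public contracts are on
the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .alignment_io import ReadAlignmentSet
from .reference import HaplotypeName

PathKey = tuple[str, tuple[str, ...]]  # (gene, fields-prefix)

LOG10_ZERO = -1e9  # sentinel for p == 0 in log10 space


def leaf_probability(mismatch_qualities: Iterable[int]) -> float:
    """Local alignment probability ``10^(-sum(q)/10)``.

    1.0 for a perfect alignment; strictly decreasing in every quality.
    """
    return 10.0 ** leaf_log10_probability(mismatch_qualities)


def leaf_log10_probability(mismatch_qualities: Iterable[int]) -> float:
    total = 0
    for q in mismatch_qualities:
        if q < 0:
            raise ValueError(f"negative phred quality {q}")
        total += q
    return -total / 10.0


class TreeNode:
    """Node of a read tree.

    ``logp`` is the propagated probability (log10); ``w`` the distributed
    weight.  A node may simultaneously be a leaf (an allele typed only to
    this depth) and carry children (deeper-typed alleles sharing the
    prefix); its own leaf mass then stays at this depth and is not passed
    further down.
    """

    __slots__ = ("label", "level", "children", "logp", "w",
                 "leaf_allele", "leaf_logp")

    def __init__(self, label: str, level: int):
        self.label = label
        self.level = level
        self.children: dict[str, TreeNode] = {}
        self.logp: float = LOG10_ZERO
        self.w: float = 0.0
        self.leaf_allele: HaplotypeName | None = None
        self.leaf_logp: float | None = None

    @property
    def p(self) -> float:
        return 10.0 ** self.logp if self.logp > LOG10_ZERO / 2 else 0.0

    @property
    def is_leaf(self) -> bool:
        return self.leaf_allele is not None and not self.children

    def __repr__(self) -> str:
        return (f"TreeNode({self.label!r}, level={self.level}, "
                f"p={self.p:.4g}, w={self.w:.4g})")


@dataclass
class ReadTree:
    read_id: str
    root: TreeNode
    root_weight: float = 1.0

    def leaves(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.leaf_allele is not None:
                yield node
            stack.extend(node.children.values())

    def node_at(self, path: PathKey) -> TreeNode | None:
        gene, fields = path
        node = self.root.children.get(gene)
        for f in fields:
            if node is None:
                return None
            node = node.children.get(f)
        return node

    def supports(self, path: PathKey) -> bool:
        return self.node_at(path) is not None

    def gene_weights(self) -> dict[str, float]:
        return {g: n.w for g, n in self.root.children.items()}


def _propagate_probabilities(node: TreeNode) -> float:
    """Bottom-up: node probability = max over children (and own leaf mass)."""
    best = node.leaf_logp if node.leaf_logp is not None else LOG10_ZERO
    for child in node.children.values():
        best = max(best, _propagate_probabilities(child))
    node.logp = best
    return best


def _distribute_weights(node: TreeNode) -> None:
    """Top-down: split ``node.w`` among children proportionally to their
    probabilities (the node's own leaf mass, if any, competes as a virtual
    sibling and its share stays at this depth)."""
    if not node.children:
        return
    entries = [(c, c.logp) for c in node.children.values()]
    terms = list(entries)
    if node.leaf_logp is not None:
        terms.append((None, node.leaf_logp))
    m = max(lp for _, lp in terms)
    if m <= LOG10_ZERO / 2:
        # all-zero corner (unreachable with finite phred sums): uniform split
        share = node.w / len(terms)
        for child, _ in entries:
            child.w = share
            _distribute_weights(child)
        return
    denom = sum(10.0 ** (lp - m) for _, lp in terms)
    for child, lp in entries:
        child.w = node.w * (10.0 ** (lp - m)) / denom
        _distribute_weights(child)


def build_read_tree(aset: ReadAlignmentSet, root_weight: float = 1.0) -> ReadTree:
    """Build and weight the tree for one read (pair).

    One leaf per allele in the alignment set, at the depth the allele is
    typed to; internal nodes along each name path; probabilities propagated
    upward (max), weights distributed downward from ``root_weight``.
    """
    if not aset.alignments:
        raise ValueError(f"{aset.read_id}: empty alignment set")
    return _tree_from_leaves(
        aset.read_id,
        [(rec.allele_name, leaf_log10_probability(rec.mismatch_qualities))
         for rec in aset.alignments.values()],
        root_weight,
    )


def _tree_from_leaves(
    read_id: str,
    leaves: Iterable[tuple[HaplotypeName, float]],
    root_weight: float,
) -> ReadTree:
    root = TreeNode("", 0)
    for name, logp in leaves:
        node = root
        for label in (name.gene, *name.fields):
            nxt = node.children.get(label)
            if nxt is None:
                nxt = TreeNode(label, node.level + 1)
                node.children[label] = nxt
            node = nxt
        node.leaf_allele = name
        # duplicate leaf (same allele twice) keeps the better probability
        node.leaf_logp = logp if node.leaf_logp is None else max(node.leaf_logp, logp)
    _propagate_probabilities(root)
    root.w = root_weight
    _distribute_weights(root)
    return ReadTree(read_id=read_id, root=root, root_weight=root_weight)


def _covered_by(name: HaplotypeName, allowed: Iterable[PathKey]) -> bool:
    """True iff some allowed prefix is an ancestor-or-self of ``name``."""
    for gene, fields in allowed:
        if name.gene == gene and len(fields) <= len(name.fields) \
                and name.fields[: len(fields)] == fields:
            return True
    return False


def prune_tree(tree: ReadTree, allowed: set[PathKey]) -> ReadTree:
    """Keep only leaves covered by an allowed prefix, then reweight.

    Reweighting rebuilds the topology from the surviving leaves' stored
    local probabilities and redistributes ``root_weight`` from scratch, so
    a surviving tree keeps its full weight.  A tree with no surviving leaf
    is returned unchanged: only trees containing evidence for the selected
    haplotypes are pruned.
    """
    survivors = [
        (leaf.leaf_allele, leaf.leaf_logp)
        for leaf in tree.leaves()
        if _covered_by(leaf.leaf_allele, allowed)
    ]
    if not survivors:
        return tree
    return _tree_from_leaves(tree.read_id, survivors, tree.root_weight)


def node_evidence(tree: ReadTree, level: int, path: PathKey) -> float:
    """Weight of the node at ``path`` (which must sit at ``level``); 0 if
    absent.  A leaf shallower than ``level`` on the path's ancestry carries
    no evidence below its own depth."""
    gene, fields = path
    if level != 1 + len(fields):
        raise ValueError(f"path {path} does not sit at level {level}")
    node = tree.node_at(path)
    return node.w if node is not None else 0.0


def iter_paths_at_level(tree: ReadTree, level: int) -> Iterator[tuple[PathKey, float]]:
    """All (path, weight) pairs at ``level`` present in the tree."""
    stack: list[tuple[TreeNode, PathKey]] = [
        (n, (g, ())) for g, n in tree.root.children.items()
    ]
    while stack:
        node, (gene, fields) = stack.pop()
        if node.level == level:
            yield (gene, fields), node.w
            continue
        for label, child in node.children.items():
            stack.append((child, (gene, fields + (label,))))


# ---------------------------------------------------------------------------
# Debug dumps (not a stable interface)


def tree_to_text(tree: ReadTree) -> str:
    lines: list[str] = [f"read {tree.read_id} (root weight {tree.root_weight:g})"]

    def walk(node: TreeNode, indent: int) -> None:
        mark = f" [{node.leaf_allele}]" if node.leaf_allele is not None else ""
        lines.append(f"{'  ' * indent}{node.label or '<root>'} "
                     f"p={node.p:.4g} w={node.w:.4g}{mark}")
        for label in sorted(node.children):
            walk(node.children[label], indent + 1)

    walk(tree.root, 0)
    return "\n".join(lines)


def tree_to_dot(tree: ReadTree) -> str:
    lines = ["digraph readtree {"]
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        lines.append(
            f'  n{nid} [label="{node.label or "root"}\\np={node.p:.3g}'
            f'\\nw={node.w:.3g}"];'
        )
        for label in sorted(node.children):
            cid = walk(node.children[label])
            lines.append(f"  n{nid} -> n{cid};")
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)
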