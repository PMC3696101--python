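import pytest
from hypothesis import HealthCheck, settings

from hlatrees.reference import (
    HaplotypeName,
    SyntheticReferenceConfig,
    generate_synthetic_reference,
    standard_synthetic_reference,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synthetic_reference():
    """Standard bench reference: 10 genes x 4 x 3 x 2, 1 kb alleles."""
    return standard_synthetic_reference(1)


@pytest.fixture(scope="session")
def tiny_reference():
    """Small reference for fast end-to-end tests."""
    ref, _ = generate_synthetic_reference(
        SyntheticReferenceConfig(
            n_genes=2, groups_per_gene=2, peptides_per_group=2,
            nucleotide_variants_per_peptide=1, base_length=400, seed=3,
        )
    )
    return ref


# ---------------------------------------------------------------------------
# Independent recursive evaluator for read-tree probabilities and weights.
# Deliberately shares no code with hlatrees.readtree: a plain nested-dict
# tree, linear-scale probabilities, and direct evaluation of the three
# rules (leaf probability, max-propagation, proportional weight split with
# the node's own leaf mass competing as a virtual sibling).


class OracleNode:
    def __init__(self):
        self.children = {}
        self.leaf_p = None
        self.p = 0.0
        self.w = 0.0


def oracle_tree(leaves, root_weight=1.0):
    """leaves: [(labels tuple incl. gene, linear leaf probability)]."""
    root = OracleNode()
    for labels, p in leaves:
        node = root
        for lab in labels:
            node = node.children.setdefault(lab, OracleNode())
        node.leaf_p = p if node.leaf_p is None else max(node.leaf_p, p)

    def prop(node):
        best = node.leaf_p if node.leaf_p is not None else 0.0
        for c in node.children.values():
            best = max(best, prop(c))
        node.p = best
        return best

    prop(root)
    root.w = root_weight

    def dist(node):
        if not node.children:
            return
        denom = sum(c.p for c in node.children.values())
        if node.leaf_p is not None:
            denom += node.leaf_p
        for c in node.children.values():
            c.w = node.w * c.p / denom if denom > 0 else node.w / (
                len(node.children) + (node.leaf_p is not None)
            )
            dist(c)

    dist(root)
    return root


def oracle_lookup(root, labels):
    node = root
    for lab in labels:
        node = node.children.get(lab)
        if node is None:
            return None
    return node


def random_alignment_sets(rng, n_sets, max_alleles=8):
    """Random per-read alignment sets over a small varied-depth name pool."""
    from hlatrees.alignment_io import AlignmentRecord, ReadAlignmentSet

    pool = [
        HaplotypeName("A", ("01", "01", "01")),
        HaplotypeName("A", ("01", "01", "02")),
        HaplotypeName("A", ("01", "02")),
        HaplotypeName("A", ("02", "01", "01", "01")),
        HaplotypeName("A", ("02", "90")),
        HaplotypeName("B", ("07", "02", "01")),
        HaplotypeName("B", ("07",)),
        HaplotypeName("B", ("44", "02")),
        HaplotypeName("DRB1", ("03", "01", "01")),
        HaplotypeName("DRB1", ("15", "01")),
    ]
    sets = []
    for i in range(n_sets):
        k = int(rng.integers(1, max_alleles + 1))
        idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        alignments = {}
        for j in idx:
            name = pool[j]
            n_mm = int(rng.integers(0, 4))
            quals = tuple(int(q) for q in rng.integers(2, 41, size=n_mm))
            alignments[str(name)] = AlignmentRecord(
                read_id=f"r{i}", mate=0, allele_name=name,
                mismatch_qualities=quals,
            )
        sets.append(ReadAlignmentSet(read_id=f"r{i}", alignments=alignments))
    return sets
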