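"""Greedy, top-down, iterative pruning haplotype caller.

Per gene, the two alleles of a diploid sample are called one hierarchy
level at a time.  At the allele-group level the group with the highest
summed tree evidence becomes the primary; the forest is then temporarily
pruned to the primaries and the second-highest scoring group becomes the
secondary.  Trees supporting both calls are assigned to the one they
support with greater weight (seeded coin flip on exact ties), the forest
is repruned and reweighted, and the procedure descends: at each deeper
level the best-scoring extension of each chain is selected from the trees
assigned to that chain.  When primary and secondary still coincide, a
divergent deeper variant is accepted as secondary only if its evidence
exceeds ``secondary_min_fraction`` (default 5%) of the primary's.

The final pruned forest doubles as an expression estimate: the summed
gene-node weight is the number of (fractional) reads assigned to each
gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .readtree import PathKey, ReadTree, iter_paths_at_level, prune_tree
from .reference import HaplotypeName

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    secondary_min_fraction: float = 0.05
    max_level: int = 5
    gene_coverage_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.secondary_min_fraction < 1.0:
            raise ValueError("secondary_min_fraction must be in [0, 1)")
        if not 2 <= self.max_level <= 5:
            raise ValueError("max_level must be in [2, 5]")


@dataclass
class EvidenceTable:
    """Summed node weights per (gene, fields-prefix) path at one level."""

    level: int
    scores: dict[PathKey, float] = field(default_factory=dict)

    def gene_paths(self, gene: str) -> list[tuple[PathKey, float]]:
        """Paths of one gene, best score first (ties: lexicographic name)."""
        items = [(p, s) for p, s in self.scores.items() if p[0] == gene]
        return sorted(items, key=lambda kv: (-kv[1], kv[0]))

    def genes(self) -> list[str]:
        return sorted({p[0] for p in self.scores})


@dataclass
class HaplotypeCall:
    gene: str
    primary: HaplotypeName
    secondary: HaplotypeName
    per_level_scores: dict[int, tuple[float, float]]
    homozygous: bool
    rng_seed: int


@dataclass
class CallResult:
    """Calls plus the final pruned forest (kept for expression estimation)."""

    calls: list[HaplotypeCall]
    forest: list[ReadTree]

    def by_gene(self) -> dict[str, HaplotypeCall]:
        return {c.gene: c for c in self.calls}


def sum_evidence(
    trees: Iterable[ReadTree],
    level: int,
    constraint: Mapping[str, tuple[str, ...]] | None = None,
) -> EvidenceTable:
    """Sum node weights across all trees at one level.

    With ``constraint`` (gene -> fields-prefix), only paths of the listed
    genes that extend the constrained prefix are scored.
    """
    if level < 2:
        raise ValueError("evidence is defined for levels >= 2")
    table = EvidenceTable(level=level)
    for tree in trees:
        for (gene, fields), w in iter_paths_at_level(tree, level):
            if constraint is not None:
                pref = constraint.get(gene)
                if pref is None or fields[: len(pref)] != pref:
                    continue
            key = (gene, fields)
            table.scores[key] = table.scores.get(key, 0.0) + w
    return table


def select_primary(evidence: EvidenceTable) -> dict[str, PathKey]:
    """Per gene, the highest-scoring path (argmax; ties to the
    lexicographically smallest name, logged)."""
    if not evidence.scores:
        raise ValueError("empty evidence table")
    out: dict[str, PathKey] = {}
    for gene in evidence.genes():
        ranked = evidence.gene_paths(gene)
        best, best_score = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == best_score:
            logger.info("gene %s: argmax tie at %.6g, keeping %s",
                        gene, best_score, _fmt(best))
        out[gene] = best
    return out


def _secondary_selection_forest(
    trees: Sequence[ReadTree], primaries: Mapping[str, PathKey]
) -> list[ReadTree]:
    """Temporary forest for secondary selection.

    A tree is pruned to a primary path when that path is the tree's
    best-supported path of its gene at the primary's level — equal-weight
    ties resolve toward the primary, so fully ambiguous trees surrender
    their split weight to it.  Trees whose dominant support lies elsewhere
    pass through unchanged and keep their evidence for the runner-up.
    (Counting ANY nonzero primary probability as support would instead
    swallow every weak cross-alignment and hide genuine second alleles.)
    """
    out: list[ReadTree] = []
    for tree in trees:
        allowed: set[PathKey] = set()
        for gene, path in primaries.items():
            w_p = _path_weight(tree, path)
            if w_p <= 0.0:
                continue
            level = len(path[1]) + 1
            w_other = max(
                (w for (g, f), w in iter_paths_at_level(tree, level)
                 if g == gene and (g, f) != path),
                default=0.0,
            )
            if w_p >= w_other - 1e-12:
                allowed.add(path)
        out.append(prune_tree(tree, allowed) if allowed else tree)
    return out


def select_secondary(
    trees: Sequence[ReadTree],
    primaries: Mapping[str, PathKey],
    level: int,
    config: CallerConfig = CallerConfig(),
) -> tuple[dict[str, PathKey], dict[str, tuple[float, float]]]:
    """Second haplotype per gene from a temporarily pruned forest.

    Trees dominantly supporting a primary are pruned to it and reweighted;
    evidence is re-summed, and per gene the best path distinct from the
    primary is taken.  A candidate sharing the primary's parent path at
    levels >= 3 must additionally reach ``secondary_min_fraction`` of the
    primary's score; with no acceptable candidate the gene is homozygous
    (secondary == primary).

    Returns (secondaries, per-gene (primary score, secondary score)).
    """
    temp = _secondary_selection_forest(trees, primaries)
    ev = sum_evidence(temp, level)
    secondaries: dict[str, PathKey] = {}
    scores: dict[str, tuple[float, float]] = {}
    for gene, primary in primaries.items():
        p_score = ev.scores.get(primary, 0.0)
        chosen = primary
        s_score = 0.0
        for path, score in ev.gene_paths(gene):
            if path == primary or score <= 0.0:
                continue
            shared_parent = level >= 3 and path[1][:-1] == primary[1][:-1]
            if shared_parent and score < config.secondary_min_fraction * p_score:
                continue
            chosen, s_score = path, score
            break
        secondaries[gene] = chosen
        scores[gene] = (p_score, s_score)
    return secondaries, scores


def _path_weight(tree: ReadTree, path: PathKey) -> float:
    node = tree.node_at(path)
    return node.w if node is not None else 0.0


def assign_ambiguous_trees(
    trees: Sequence[ReadTree],
    primaries: Mapping[str, PathKey],
    secondaries: Mapping[str, PathKey],
    rng: np.random.Generator,
) -> list[ReadTree]:
    """Reprune the forest so only edges supporting a called haplotype remain.

    A tree supporting both the primary and the secondary of one gene is
    assigned to the side it supports with greater weight; on an exact tie
    the assignment is a seeded coin flip.  Trees supporting neither pass
    through unchanged; the tree count is conserved.
    """
    out: list[ReadTree] = []
    genes = sorted(set(primaries) | set(secondaries))
    for tree in trees:
        allowed: set[PathKey] = set()
        for gene in genes:
            p = primaries.get(gene)
            s = secondaries.get(gene, p)
            if p is None:
                p = s
            wp = _path_weight(tree, p)
            if s == p:
                if wp > 0:
                    allowed.add(p)
                continue
            ws = _path_weight(tree, s)
            if wp > 0 and ws > 0:
                if wp > ws:
                    allowed.add(p)
                elif ws > wp:
                    allowed.add(s)
                else:
                    allowed.add(p if rng.random() < 0.5 else s)
            elif wp > 0:
                allowed.add(p)
            elif ws > 0:
                allowed.add(s)
        out.append(prune_tree(tree, allowed) if allowed else tree)
    return out


def _extension_scores(
    forest: Sequence[ReadTree], path: PathKey
) -> dict[str, float]:
    """Summed child weights one level below ``path`` across the forest.

    Leaf mass held at ``path``'s own depth contributes nothing deeper.
    """
    acc: dict[str, float] = {}
    for tree in forest:
        node = tree.node_at(path)
        if node is None:
            continue
        for label, child in node.children.items():
            acc[label] = acc.get(label, 0.0) + child.w
    return acc


def _best_extension(scores: Mapping[str, float],
                    exclude: str | None = None) -> tuple[str, float] | None:
    items = [(lbl, s) for lbl, s in scores.items()
             if s > 0.0 and lbl != exclude]
    if not items:
        return None
    return min(items, key=lambda kv: (-kv[1], kv[0]))


def call_haplotypes(
    trees: Sequence[ReadTree], config: CallerConfig = CallerConfig()
) -> CallResult:
    """Run the full greedy top-down pruning iteration over a read forest.

    Level 2: primary and secondary allele groups per gene, ambiguous trees
    assigned, forest repruned.  Levels 3..``max_level``: each chain is
    extended by the argmax of the evidence of the trees assigned to it;
    while primary and secondary chains still coincide, the 5% rule decides
    whether a divergent deeper variant is accepted as secondary.  A chain
    stops extending when no tree carries evidence below its current depth
    (alleles typed to different resolutions).  Deterministic under
    ``config.seed``.
    """
    forest = list(trees)
    if not forest:
        raise ValueError("empty read forest")
    if sum(t.root_weight for t in forest) <= 0.0:
        raise ValueError("read forest has zero total weight")

    rng = np.random.default_rng(config.seed)
    ev2 = sum_evidence(forest, 2)
    if not ev2.scores:
        raise ValueError("no evidence at the allele-group level")
    primaries = select_primary(ev2)
    secondaries, sec_scores = select_secondary(forest, primaries, 2, config)

    pchain: dict[str, PathKey] = dict(primaries)
    schain: dict[str, PathKey] = dict(secondaries)
    diverged = {g: pchain[g] != schain[g] for g in pchain}
    per_level: dict[str, dict[int, tuple[float, float]]] = {
        g: {2: (ev2.scores[pchain[g]], sec_scores[g][1] if diverged[g] else
                ev2.scores[pchain[g]])}
        for g in pchain
    }
    forest = assign_ambiguous_trees(forest, pchain, schain, rng)

    p_stop = {g: False for g in pchain}
    s_stop = {g: False for g in pchain}
    for level in range(3, config.max_level + 1):
        newly_diverged = False
        for gene in pchain:
            if p_stop[gene] and s_stop[gene]:
                continue
            if not diverged[gene]:
                scores = _extension_scores(forest, pchain[gene])
                best = _best_extension(scores)
                if best is None:
                    p_stop[gene] = s_stop[gene] = True
                    continue
                label, _ = best
                new_p = (gene, pchain[gene][1] + (label,))
                # candidate divergent secondary: re-score on the temporary
                # secondary-selection forest so ambiguous trees surrender
                # their split weight to the primary first
                temp = _secondary_selection_forest(forest, {gene: new_p})
                temp_scores = _extension_scores(temp, pchain[gene])
                p_score = temp_scores.get(label, 0.0)
                runner = _best_extension(temp_scores, exclude=label)
                if (runner is not None
                        and runner[1] >= config.secondary_min_fraction * p_score):
                    s_label, s_score = runner
                    schain[gene] = (gene, pchain[gene][1] + (s_label,))
                    diverged[gene] = True
                    newly_diverged = True
                else:
                    s_score = p_score
                    schain[gene] = new_p
                pchain[gene] = new_p
                per_level[gene][level] = (p_score, s_score)
            else:
                p_score = s_score = 0.0
                if not p_stop[gene]:
                    best = _best_extension(_extension_scores(forest, pchain[gene]))
                    if best is None:
                        p_stop[gene] = True
                    else:
                        pchain[gene] = (gene, pchain[gene][1] + (best[0],))
                        p_score = best[1]
                if not s_stop[gene]:
                    best = _best_extension(_extension_scores(forest, schain[gene]))
                    if best is None:
                        s_stop[gene] = True
                    else:
                        schain[gene] = (gene, schain[gene][1] + (best[0],))
                        s_score = best[1]
                if not (p_stop[gene] and s_stop[gene]):
                    per_level[gene][level] = (p_score, s_score)
        forest = assign_ambiguous_trees(forest, pchain, schain, rng)
        if newly_diverged:
            logger.debug("level %d: new primary/secondary divergence", level)

    calls = [
        HaplotypeCall(
            gene=gene,
            primary=HaplotypeName(gene, pchain[gene][1]),
            secondary=HaplotypeName(gene, schain[gene][1]),
            per_level_scores=per_level[gene],
            homozygous=pchain[gene] == schain[gene],
            rng_seed=config.seed,
        )
        for gene in sorted(pchain)
    ]
    return CallResult(calls=calls, forest=forest)


def estimate_expression(forest: Iterable[ReadTree]) -> dict[str, float]:
    """Summed gene-node weight over the final pruned forest.

    Unassigned trees keep their weight split across the genes they align
    to, so the total over genes never exceeds the number of trees times
    the root weight.
    """
    out: dict[str, float] = {}
    for tree in forest:
        for gene, w in tree.gene_weights().items():
            out[gene] = out.get(gene, 0.0) + w
    return out


def filter_genes_by_coverage(
    expression: Mapping[str, float],
    mapped_read_count: int,
    fraction: float = 0.01,
) -> set[str]:
    """Genes whose assigned weight reaches ``fraction`` of all mapped reads
    (boundary kept: >=)."""
    threshold = fraction * mapped_read_count
    return {g for g, w in expression.items() if w >= threshold}


def _fmt(path: PathKey) -> str:
    gene, fields = path
    return f"{gene}*{':'.join(fields)}" if fields else gene
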