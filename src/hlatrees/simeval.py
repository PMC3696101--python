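"""Diploid RNA-seq read simulation and depth-aware accuracy scoring.

The simulator emulates paired-end sequencing of spliced cDNA: two truth
alleles per gene, fragments drawn from a truncated normal, each base
substituted independently at a configurable rate (no indels), qualities
from a flat / linear-decay / rate-matched model.  Pairs per allele follow
the coverage formula ``round(coverage * allele_length / (2 * read_length))``.

Because simulated alleles share one coordinate system (no indels), the
package can compute an all-alignments SAM internally by gapless
re-alignment of every mate at its known fragment offset against every
candidate allele ("direct-truth" mode) — no external aligner needed.

Accuracy is scored per hierarchy level and only where the truth allele is
typed to that level: a truth allele known only to the peptide level is
never assessed at the nucleotide or intron level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord, filter_exact, group_alignments
from .caller import CallerConfig, CallResult, HaplotypeCall, call_haplotypes
from .readtree import build_read_tree
from .reference import HaplotypeName, Reference, ReferenceAllele

logger = logging.getLogger(__name__)

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class QualityModel:
    """Per-base phred qualities of simulated reads.

    kind "flat": constant ``q``; "linear": decay from ``q_start`` at the
    5' end to ``q_end`` at the 3' end; "matched": flat at
    ``round(-10*log10(substitution_rate))`` so emitted qualities are
    consistent in expectation with the substitution process (capped at 41,
    the common sequencer maximum).
    """

    kind: str = "matched"
    q: int = 30
    q_start: int = 38
    q_end: int = 20

    def qualities(self, read_length: int, substitution_rate: float) -> np.ndarray:
        if self.kind == "flat":
            return np.full(read_length, self.q, dtype=np.int64)
        if self.kind == "linear":
            return np.round(
                np.linspace(self.q_start, self.q_end, read_length)
            ).astype(np.int64)
        if self.kind == "matched":
            if substitution_rate <= 0:
                q = 41
            else:
                q = int(round(-10.0 * math.log10(substitution_rate)))
            return np.full(read_length, int(np.clip(q, 2, 41)), dtype=np.int64)
        raise ValueError(f"unknown quality model {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    read_length: int = 100
    coverage_per_haplotype: float = 50.0
    substitution_rate: float = 0.0
    fragment_mean: int = 300
    fragment_sd: float = 30.0
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0.0 <= self.substitution_rate < 0.25:
            raise ValueError("substitution_rate must be in [0, 0.25)")


@dataclass(frozen=True)
class TruthEntry:
    gene: str
    haplotype_1: HaplotypeName
    haplotype_2: HaplotypeName


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def by_gene(self) -> dict[str, TruthEntry]:
        return {e.gene: e for e in self.entries}


@dataclass(frozen=True)
class SimulatedPair:
    """One simulated read pair, truth-tagged with its source fragment."""

    read_id: str
    source_allele: HaplotypeName
    fragment_start: int
    fragment_length: int
    seq1: str
    qual1: np.ndarray  # phred ints, in emitted (5'->3') orientation
    seq2: str  # reverse-complement of the fragment end
    qual2: np.ndarray


def sample_truth_haplotypes(
    reference: Reference, genes: Sequence[str], rng: np.random.Generator
) -> TruthTable:
    """Two alleles per gene, uniform with replacement (homozygous truths
    possible); deterministic under the generator's state."""
    entries = []
    for gene in genes:
        alleles = reference.by_gene(gene)
        if not alleles:
            raise ValueError(f"gene {gene!r} absent from reference")
        i, j = rng.integers(0, len(alleles), size=2)
        entries.append(TruthEntry(gene, alleles[i].name, alleles[j].name))
    return TruthTable(entries)


def pairs_per_allele(coverage: float, allele_length: int, read_length: int) -> int:
    return int(round(coverage * allele_length / (2 * read_length)))


def simulate_reads(
    reference: Reference, truth: TruthTable, config: SimConfig
) -> list[SimulatedPair]:
    """Simulate paired reads for every truth allele.

    Fragment lengths are drawn from a normal clamped to
    ``[read_length, allele_length]`` (mates may overlap on short
    fragments); fragment starts are uniform; each base is substituted to a
    uniformly chosen different base with probability
    ``substitution_rate``.  Read names encode the source allele and
    fragment for truth tracking.  Alleles shorter than the read length are
    skipped with a warning.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    pairs: list[SimulatedPair] = []
    serial = 0
    for entry in truth.entries:
        for hap in (entry.haplotype_1, entry.haplotype_2):
            allele = reference.get(str(hap))
            if allele is None:
                raise ValueError(f"truth allele {hap} absent from reference")
            L = len(allele)
            if L < rl:
                logger.warning("allele %s shorter than read length; skipped", hap)
                continue
            n_pairs = pairs_per_allele(config.coverage_per_haplotype, L, rl)
            base_q = config.quality_model.qualities(rl, config.substitution_rate)
            seq_arr = np.frombuffer(allele.sequence.encode(), dtype=np.uint8)
            for _ in range(n_pairs):
                flen = int(round(rng.normal(config.fragment_mean,
                                            config.fragment_sd)))
                flen = int(np.clip(flen, rl, L))
                start = int(rng.integers(0, L - flen + 1))
                frag = seq_arr[start : start + flen]
                r1 = _mutate_read(frag[:rl].copy(), config.substitution_rate, rng)
                r2t = _mutate_read(frag[flen - rl :].copy(),
                                   config.substitution_rate, rng)
                read_id = f"sim|{hap}|{start}|{flen}|{serial}"
                serial += 1
                pairs.append(
                    SimulatedPair(
                        read_id=read_id,
                        source_allele=allele.name,
                        fragment_start=start,
                        fragment_length=flen,
                        seq1=r1.tobytes().decode(),
                        qual1=base_q.copy(),
                        seq2=revcomp(r2t.tobytes().decode()),
                        qual2=base_q[::-1].copy(),
                    )
                )
    return pairs


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate_read(seq: np.ndarray, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, seq[hits])
        seq[hits] = _BASES[(idx + shift) % 4]
    return seq


def write_fastq_pair(pairs: Sequence[SimulatedPair], path1: str | Path,
                     path2: str | Path) -> None:
    """Phred+33 FASTQ output, one file per mate."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{_qual_str(p.qual1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{_qual_str(p.qual2)}\n")


def _qual_str(q: np.ndarray) -> str:
    return "".join(chr(int(v) + 33) for v in q)


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\thaplotype_1\thaplotype_2\n")
        for e in truth.entries:
            fh.write(f"{e.gene}\t{e.haplotype_1}\t{e.haplotype_2}\n")


def read_truth_tsv(path: str | Path) -> TruthTable:
    from .reference import parse_allele_name

    entries = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, h1, h2 = line.rstrip("\n").split("\t")
            entries.append(TruthEntry(gene, parse_allele_name(h1),
                                      parse_allele_name(h2)))
    return TruthTable(entries)


# ---------------------------------------------------------------------------
# Direct-truth alignment (internal all-alignments computation)


class DirectAligner:
    """Gapless all-alignments computation against a co-linear reference.

    Each mate is compared, at its known fragment offset, against every
    reference allele long enough to hold it; alignments with at most
    ``max_mismatches`` substitutions are reported.  Valid whenever the
    reference alleles share one coordinate system (true for the synthetic
    references here, which contain substitutions only).
    """

    def __init__(self, reference: Reference, max_mismatches: int | None = None):
        self.reference = reference
        self.max_mismatches = max_mismatches
        self._alleles: list[ReferenceAllele] = list(reference)
        by_len: dict[int, list[int]] = {}
        for i, a in enumerate(self._alleles):
            by_len.setdefault(len(a), []).append(i)
        self._groups = [
            (
                np.asarray(idx),
                np.vstack([
                    np.frombuffer(self._alleles[i].sequence.encode(), dtype=np.uint8)
                    for i in idx
                ]),
            )
            for length, idx in sorted(by_len.items())
        ]

    def _ceiling(self, read_length: int, substitution_rate: float) -> int:
        if self.max_mismatches is not None:
            return self.max_mismatches
        # generous enough to keep the true allele at high error rates while
        # excluding unrelated genes (~75% mismatch)
        return math.ceil(read_length * (0.08 + 2.0 * substitution_rate))

    def align_mate(
        self, read_id: str, mate: int, template_seq: str,
        template_qual: np.ndarray, offset: int, *, ceiling: int,
    ) -> Iterator[AlignmentRecord]:
        read = np.frombuffer(template_seq.encode(), dtype=np.uint8)
        rl = read.size
        for idx, mat in self._groups:
            if mat.shape[1] < offset + rl:
                continue
            diff = mat[:, offset : offset + rl] != read
            counts = diff.sum(axis=1)
            for row in np.nonzero(counts <= ceiling)[0]:
                positions = np.nonzero(diff[row])[0]
                yield AlignmentRecord(
                    read_id=read_id,
                    mate=mate,
                    allele_name=self._alleles[idx[row]].name,
                    mismatch_qualities=tuple(
                        int(template_qual[p]) for p in positions
                    ),
                )

    def align_pairs(
        self, pairs: Sequence[SimulatedPair], substitution_rate: float = 0.0
    ) -> Iterator[AlignmentRecord]:
        """Stream alignment records pair by pair (read ids contiguous)."""
        for p in pairs:
            rl = len(p.seq1)
            ceiling = self._ceiling(rl, substitution_rate)
            yield from self.align_mate(
                p.read_id, 1, p.seq1, p.qual1, p.fragment_start, ceiling=ceiling
            )
            # mate 2 compared in template-forward orientation
            off2 = p.fragment_start + p.fragment_length - rl
            yield from self.align_mate(
                p.read_id, 2, revcomp(p.seq2), p.qual2[::-1], off2,
                ceiling=ceiling,
            )


def write_direct_sam(
    reference: Reference,
    pairs: Sequence[SimulatedPair],
    aligner: DirectAligner,
    path: str | Path,
    substitution_rate: float = 0.0,
) -> None:
    """All-alignments SAM (text) from direct-truth alignment, with MD/NM
    tags so any SAM consumer can recover mismatch positions."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for a in reference:
            fh.write(f"@SQ\tSN:{a.record_id or a.name}\tLN:{len(a)}\n")
        for p in pairs:
            rl = len(p.seq1)
            ceiling = aligner._ceiling(rl, substitution_rate)
            mates = [
                (1, 0x40, p.seq1, p.qual1, p.fragment_start),
                (2, 0x80 | 0x10, revcomp(p.seq2), p.qual2[::-1],
                 p.fragment_start + p.fragment_length - rl),
            ]
            for mate, mate_flag, seq, qual, offset in mates:
                for rec in aligner.align_mate(p.read_id, mate, seq, qual,
                                              offset, ceiling=ceiling):
                    allele = reference.get(str(rec.allele_name))
                    ref_slice = allele.sequence[offset : offset + rl]
                    md = _md_string(seq, ref_slice)
                    flag = 0x1 | 0x2 | mate_flag
                    fh.write(
                        "\t".join([
                            p.read_id, str(flag),
                            allele.record_id or str(allele.name),
                            str(offset + 1), "255", f"{rl}M", "*", "0", "0",
                            seq, _qual_str(qual),
                            f"NM:i:{len(rec.mismatch_qualities)}", f"MD:Z:{md}",
                        ]) + "\n"
                    )


def _md_string(read: str, ref: str) -> str:
    out: list[str] = []
    run = 0
    for rb, fb in zip(read, ref):
        if rb == fb:
            run += 1
        else:
            out.append(str(run))
            out.append(fb)
            run = 0
    out.append(str(run))
    return "".join(out)


def type_sample(
    records: Iterable[AlignmentRecord],
    caller_config: CallerConfig = CallerConfig(),
    *,
    exact: bool = False,
    root_weight: float = 1.0,
) -> CallResult:
    """Alignment-record stream -> grouped pairs -> read forest -> calls."""
    sets = group_alignments(records)
    if exact:
        sets = filter_exact(sets)
    forest = [build_read_tree(s, root_weight) for s in sets]
    if not forest:
        raise ValueError("no read trees (empty or fully filtered input)")
    return call_haplotypes(forest, caller_config)


# ---------------------------------------------------------------------------
# Accuracy rules


ACCURACY_LEVELS = {2: "allele_group", 3: "peptide", 4: "nucleotide", 5: "intron"}


@dataclass
class AccuracyReport:
    """Per-level assessed/correct counts, depth-truncation aware."""

    assessed: dict[str, int] = field(
        default_factory=lambda: {n: 0 for n in ACCURACY_LEVELS.values()}
    )
    correct: dict[str, int] = field(
        default_factory=lambda: {n: 0 for n in ACCURACY_LEVELS.values()}
    )

    def accuracy(self, level_name: str) -> float:
        a = self.assessed[level_name]
        return self.correct[level_name] / a if a else float("nan")

    def merge(self, other: "AccuracyReport") -> None:
        for name in self.assessed:
            self.assessed[name] += other.assessed[name]
            self.correct[name] += other.correct[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": list(self.assessed),
                "assessed": [self.assessed[n] for n in self.assessed],
                "correct": [self.correct[n] for n in self.assessed],
                "accuracy": [self.accuracy(n) for n in self.assessed],
            }
        )


def _matched_depth(call: HaplotypeName, truth: HaplotypeName) -> int:
    n = 0
    for cf, tf in zip(call.fields, truth.fields):
        if cf != tf:
            break
        n += 1
    return n


def evaluate_accuracy(
    calls: Sequence[HaplotypeCall] | Mapping[str, tuple[HaplotypeName, HaplotypeName]],
    truth: TruthTable,
) -> AccuracyReport:
    """Score called allele pairs against truth, per hierarchy level.

    Within each gene the two calls are matched to the two truth alleles by
    the pairing that maximises total matched depth (so a swapped
    primary/secondary order costs nothing).  A truth allele typed to depth
    d is assessed at levels 2..d only; its matched call is correct at a
    level iff all fields through that level agree.
    """
    if isinstance(calls, Mapping):
        pair_by_gene = dict(calls)
    else:
        pair_by_gene = {c.gene: (c.primary, c.secondary) for c in calls}
    report = AccuracyReport()
    scored = 0
    for entry in truth.entries:
        got = pair_by_gene.get(entry.gene)
        if got is None:
            # an uncalled gene is wrong at every assessable level
            got = (None, None)
        else:
            scored += 1
        truths = (entry.haplotype_1, entry.haplotype_2)
        if got[0] is not None:
            straight = (_matched_depth(got[0], truths[0])
                        + _matched_depth(got[1], truths[1]))
            crossed = (_matched_depth(got[0], truths[1])
                       + _matched_depth(got[1], truths[0]))
            matched = (got[0], got[1]) if straight >= crossed else (got[1], got[0])
        else:
            matched = (None, None)
        for call, t in zip(matched, truths):
            for level, name in ACCURACY_LEVELS.items():
                if t.depth < level:
                    continue
                report.assessed[name] += 1
                if call is not None and len(call.fields) >= level - 1 \
                        and call.fields[: level - 1] == t.fields[: level - 1]:
                    report.correct[name] += 1
    if scored == 0:
        raise ValueError("no overlap between called and truth genes")
    return report


# ---------------------------------------------------------------------------
# End-to-end simulation studies


def run_replicate(
    reference: Reference,
    genes: Sequence[str],
    sim_config: SimConfig,
    caller_config: CallerConfig,
    aligner: DirectAligner | None = None,
    *,
    exact: bool = False,
) -> tuple[CallResult, TruthTable]:
    """One full cycle: sample truth -> simulate -> direct-align -> call."""
    rng = np.random.default_rng(sim_config.seed)
    truth = sample_truth_haplotypes(reference, genes, rng)
    pairs = simulate_reads(reference, truth, sim_config)
    if aligner is None:
        aligner = DirectAligner(reference)
    records = aligner.align_pairs(pairs, sim_config.substitution_rate)
    result = type_sample(records, caller_config, exact=exact)
    return result, truth


def run_simulation_study(
    reference: Reference,
    grid: Sequence[SimConfig],
    genes: Sequence[str],
    replicates: int,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Accuracy table over a grid of simulation conditions.

    For every condition, ``replicates`` independent cycles are run and
    per-level assessed/correct counts pooled over genes and replicates
    (each assessed truth allele weighs equally, which is how multi-gene
    averages are formed).  Returns one row per condition x level.
    """
    rows = []
    cond_streams = np.random.SeedSequence(seed).spawn(len(grid))
    for cond_idx, cond in enumerate(grid):
        report = AccuracyReport()
        child_seeds = cond_streams[cond_idx].generate_state(2 * replicates) % (2**31)
        for r in range(replicates):
            rep_cfg = replace(cond, seed=int(child_seeds[2 * r]))
            caller = caller_config or CallerConfig()
            caller = CallerConfig(
                secondary_min_fraction=caller.secondary_min_fraction,
                max_level=caller.max_level,
                gene_coverage_fraction=caller.gene_coverage_fraction,
                seed=int(child_seeds[2 * r + 1]),
            )
            result, truth = run_replicate(reference, genes, rep_cfg, caller)
            report.merge(evaluate_accuracy(result.calls, truth))
        for name in report.assessed:
            rows.append(
                {
                    "condition": cond_idx,
                    "read_length": cond.read_length,
                    "coverage": cond.coverage_per_haplotype,
                    "substitution_rate": cond.substitution_rate,
                    "level": name,
                    "assessed": report.assessed[name],
                    "correct": report.correct[name],
                    "accuracy": report.accuracy(name),
                }
            )
    return pd.DataFrame(rows)


def recovery_fraction(
    reference: Reference,
    genes: Sequence[str],
    sim_config: SimConfig,
    replicates: int,
    seed: int = 0,
    caller_config: CallerConfig | None = None,
) -> float:
    """Fraction of replicates whose called pair equals the truth pair
    exactly at full depth for every simulated gene."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * replicates) % (2**31)
    hits = 0
    aligner = DirectAligner(reference)
    base_caller = caller_config or CallerConfig()
    for r in range(replicates):
        cfg = replace(sim_config, seed=int(seeds[2 * r]))
        caller = CallerConfig(
            secondary_min_fraction=base_caller.secondary_min_fraction,
            max_level=base_caller.max_level,
            gene_coverage_fraction=base_caller.gene_coverage_fraction,
            seed=int(seeds[2 * r + 1]),
        )
        result, truth = run_replicate(reference, genes, cfg, caller, aligner)
        if all(
            _pair_recovered(result.by_gene().get(e.gene), e)
            for e in truth.entries
        ):
            hits += 1
    return hits / replicates


def _pair_recovered(call: HaplotypeCall | None, entry: TruthEntry) -> bool:
    if call is None:
        return False
    return {str(call.primary), str(call.secondary)} == {
        str(entry.haplotype_1), str(entry.haplotype_2)
    }
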