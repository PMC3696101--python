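"""SAM ingestion: mismatch qualities, pairing, grouping, exact-match filter.

The quantity extracted from every alignment is its SMMQ — the sum of the
phred qualities of the read bases sitting at substituted positions.  A
perfect alignment has SMMQ 0; the tree layer converts SMMQ to an alignment
probability 10^(-SMMQ/10).  Mates of a pair aligned to the same allele are
combined by summing their SMMQs, which is what lets paired-end phasing
information flow into a single per-pair tree.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .reference import HaplotypeName, Reference

logger = logging.getLogger(__name__)

MAX_PHRED = 93
DEFAULT_INDEL_QUALITY = 30


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of one mate (or an unpaired read) to one allele."""

    read_id: str
    mate: int  # 1, 2, or 0 for unpaired/combined
    allele_name: HaplotypeName
    mismatch_qualities: tuple[int, ...] = ()
    has_indel: bool = False

    def __post_init__(self) -> None:
        for q in self.mismatch_qualities:
            if not (0 <= q <= MAX_PHRED):
                raise ValueError(f"phred quality {q} outside [0, {MAX_PHRED}]")

    @property
    def smmq(self) -> int:
        return sum(self.mismatch_qualities)


@dataclass
class ReadAlignmentSet:
    """All alignments of a read (pair), one combined record per allele."""

    read_id: str
    alignments: dict[str, AlignmentRecord] = field(default_factory=dict)
    paired: bool = False

    def __len__(self) -> int:
        return len(self.alignments)


class SamFormatError(ValueError):
    pass


def mismatch_qualities_from_record(
    aln: pysam.AlignedSegment,
    *,
    indel_quality: int = DEFAULT_INDEL_QUALITY,
    reference_seq: str | None = None,
) -> tuple[list[int], bool]:
    """Phred qualities of the read bases at substituted positions.

    Mismatch positions come from the MD tag (via pysam's aligned pairs) or,
    if MD is absent, from direct comparison against ``reference_seq``.
    Each inserted or deleted base contributes ``indel_quality`` (simulations
    here contain no indels; real data may).  Soft-clipped bases are ignored.
    """
    if aln.query_qualities is None:
        raise SamFormatError(f"{aln.query_name}: QUAL is '*'")
    quals = aln.query_qualities
    out: list[int] = []
    has_indel = False

    if aln.has_tag("MD"):
        for qpos, rpos, ref_base in aln.get_aligned_pairs(with_seq=True):
            if qpos is not None and rpos is not None:
                if ref_base is not None and ref_base.islower():
                    out.append(quals[qpos])
    elif reference_seq is not None:
        qseq = aln.query_sequence
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            if qseq[qpos].upper() != reference_seq[rpos].upper():
                out.append(quals[qpos])
    else:
        raise SamFormatError(
            f"{aln.query_name}: no MD tag and no reference sequence supplied"
        )

    for op, length in aln.cigartuples or ():
        if op == 1 or op == 2:  # I / D
            has_indel = True
            out.extend([indel_quality] * length)
    return out, has_indel


def parse_sam_alignments(
    sam_path: str | Path,
    reference: Reference,
    *,
    indel_quality: int = DEFAULT_INDEL_QUALITY,
    stats: dict | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped SAM/BAM records as :class:`AlignmentRecord`.

    Unmapped records are skipped; records whose target resolves to no
    reference allele (e.g. a null allele excluded at load time) are skipped
    and counted in ``stats``.
    """
    counters = stats if stats is not None else {}
    counters.setdefault("yielded", 0)
    counters.setdefault("skipped_unmapped", 0)
    counters.setdefault("skipped_unknown_target", 0)

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                counters["skipped_unmapped"] += 1
                continue
            target = aln.reference_name
            allele = reference.resolve(target) if target else None
            if allele is None:
                counters["skipped_unknown_target"] += 1
                continue
            mq, has_indel = mismatch_qualities_from_record(
                aln,
                indel_quality=indel_quality,
                reference_seq=allele.sequence if not aln.has_tag("MD") else None,
            )
            mate = 1 if aln.is_read1 else 2 if aln.is_read2 else 0
            counters["yielded"] += 1
            yield AlignmentRecord(
                read_id=aln.query_name,
                mate=mate,
                allele_name=allele.name,
                mismatch_qualities=tuple(mq),
                has_indel=has_indel,
            )
    if counters["yielded"] == 0:
        logger.warning("%s: no usable alignment records", sam_path)


def _combine(read_id: str, per_allele: dict[str, dict[int, AlignmentRecord]],
             paired: bool) -> ReadAlignmentSet:
    combined: dict[str, AlignmentRecord] = {}
    for allele_key, by_mate in per_allele.items():
        recs = list(by_mate.values())
        quals: tuple[int, ...] = ()
        indel = False
        for r in recs:
            quals = quals + r.mismatch_qualities
            indel = indel or r.has_indel
        combined[allele_key] = AlignmentRecord(
            read_id=read_id,
            mate=0,
            allele_name=recs[0].allele_name,
            mismatch_qualities=quals,
            has_indel=indel,
        )
    return ReadAlignmentSet(read_id=read_id, alignments=combined, paired=paired)


def group_alignments(
    records: Iterable[AlignmentRecord],
) -> Iterator[ReadAlignmentSet]:
    """Group a record stream by read id into per-pair alignment sets.

    Records of one read id must be contiguous (aligners emit them that
    way); memory is bounded by the largest per-read set.  Per allele, the
    two mates' SMMQs are summed; if only one mate aligns there, its record
    stands alone; duplicate alignments of the same mate to the same allele
    keep the one with minimum SMMQ.
    """
    current: str | None = None
    buf: dict[str, dict[int, AlignmentRecord]] = {}
    saw_mate2 = False
    for rec in records:
        if rec.read_id != current:
            if current is not None and buf:
                yield _combine(current, buf, saw_mate2)
            current, buf, saw_mate2 = rec.read_id, {}, False
        mate = rec.mate if rec.mate in (1, 2) else 1
        saw_mate2 = saw_mate2 or rec.mate == 2
        by_mate = buf.setdefault(str(rec.allele_name), {})
        prev = by_mate.get(mate)
        if prev is None or rec.smmq < prev.smmq:
            by_mate[mate] = rec
    if current is not None and buf:
        yield _combine(current, buf, saw_mate2)


def filter_exact(
    sets: Iterable[ReadAlignmentSet],
) -> Iterator[ReadAlignmentSet]:
    """Keep only perfect alignments (SMMQ 0, no indel); drop emptied sets.

    Idempotent by construction.
    """
    for s in sets:
        kept = {
            k: r for k, r in s.alignments.items()
            if r.smmq == 0 and not r.has_indel
        }
        if kept:
            yield ReadAlignmentSet(read_id=s.read_id, alignments=kept,
                                   paired=s.paired)


# ---------------------------------------------------------------------------
# Optional external-aligner shell-out


class AlignerError(RuntimeError):
    pass


def compute_max_insert(read_length: int, fragment_mean: float,
                       fragment_sd: float, default: int = 250) -> int:
    """Maximum insert size passed to the aligner: for reads longer than
    100 bp, fragment mean plus three standard deviations."""
    if read_length > 100:
        return int(round(fragment_mean + 3 * fragment_sd))
    return default


def run_external_aligner(
    fastq1: str | Path,
    fastq2: str | Path | None,
    reference_fasta: str | Path,
    out_sam: str | Path,
    *,
    command_template: list[str],
) -> Path:
    """Run a configured aligner command; returns the all-alignments SAM path.

    ``command_template`` entries may contain the placeholders ``{fastq1}``,
    ``{fastq2}``, ``{reference}`` and ``{out_sam}``.  This is optional
    plumbing: every pipeline entry point also accepts SAM directly.
    """
    subst = {
        "fastq1": str(fastq1),
        "fastq2": str(fastq2) if fastq2 else "",
        "reference": str(reference_fasta),
        "out_sam": str(out_sam),
    }
    cmd = [part.format(**subst) for part in command_template]
    cmd = [c for c in cmd if c]
    if shutil.which(cmd[0]) is None:
        raise AlignerError(
            f"aligner executable {cmd[0]!r} not found on PATH; supply SAM "
            "input directly or install/configure the aligner"
        )
    logger.info("running aligner: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerError(
            f"aligner exited with {proc.returncode}: {proc.stderr.strip()}"
        )
    return Path(out_sam)
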