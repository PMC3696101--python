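"""Hierarchical HLA nomenclature and reference-allele handling.

HLA alleles are named hierarchically: a gene symbol followed by up to four
colon-separated fields (allele group, peptide, nucleotide, intron), e.g.
``HLA-A*01:02:03:04``.  The depth of a name — how many fields it carries —
is the typing resolution.  This module parses and formats such names, loads
cDNA references from FASTA (excluding unexpressed "null" alleles, whose
suffix is ``N``), and generates synthetic references whose sequence
divergence mirrors the nested structure of the real database: alleles in
the same peptide group are more similar than alleles in the same allele
group, which are more similar than alleles of the same gene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Level indices used throughout: 0 = tree root, 1 = gene, 2 = allele group,
#: 3 = peptide, 4 = nucleotide, 5 = intron.
LEVEL_NAMES: dict[int, str] = {
    1: "gene",
    2: "allele_group",
    3: "peptide",
    4: "nucleotide",
    5: "intron",
}

MAX_FIELDS = 4

_NAME_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Za-z][A-Za-z0-9]*)\*"
    r"(?P<fields>[0-9]+(?::[0-9]+)*)"
    r"(?P<suffix>[A-Z]?)$"
)


class AlleleNameError(ValueError):
    """Raised when an allele-name string does not match the grammar."""


class ReferenceError(ValueError):
    """Raised for unloadable or inconsistent references."""


@dataclass(frozen=True, order=True)
class HaplotypeName:
    """A hierarchical allele identifier: gene plus 1–4 name fields.

    Fields are compared verbatim as strings (``"01" != "1"``), matching
    IMGT convention; no numeric normalisation is applied.
    """

    gene: str
    fields: tuple[str, ...]
    expression_suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.fields or len(self.fields) > MAX_FIELDS:
            raise AlleleNameError(
                f"{self.gene}*{':'.join(self.fields)}: need 1-{MAX_FIELDS} fields"
            )

    @property
    def depth(self) -> int:
        """Typing depth: 1 (gene) + number of fields; in {2,3,4,5}."""
        return 1 + len(self.fields)

    @property
    def path(self) -> tuple[str, tuple[str, ...]]:
        """(gene, fields) pair used as a tree-path key."""
        return (self.gene, self.fields)

    def truncate(self, depth: int) -> "HaplotypeName":
        """Name restricted to ``depth`` levels (suffix dropped)."""
        if depth < 2 or depth > self.depth:
            raise ValueError(f"cannot truncate depth-{self.depth} name to {depth}")
        return HaplotypeName(self.gene, self.fields[: depth - 1])

    def is_ancestor_of(self, other: "HaplotypeName") -> bool:
        """Proper-prefix relation on (gene, fields)."""
        return (
            self.gene == other.gene
            and len(self.fields) < len(other.fields)
            and other.fields[: len(self.fields)] == self.fields
        )

    def __str__(self) -> str:
        s = f"{self.gene}*{':'.join(self.fields)}"
        return s + self.expression_suffix if self.expression_suffix else s


def parse_allele_name(raw: str) -> HaplotypeName:
    """Parse ``[HLA-]GENE*F1[:F2[:F3[:F4]]][X]`` into a :class:`HaplotypeName`.

    A leading ``HLA-`` is stripped; a single trailing capital letter is the
    expression suffix (``N`` marks null alleles).  Field strings are kept
    verbatim.

    >>> str(parse_allele_name("HLA-A*01:02:03:04"))
    'A*01:02:03:04'
    """
    m = _NAME_RE.match(raw.strip())
    if m is None:
        if "*" not in raw:
            raise AlleleNameError(f"{raw!r}: missing '*' separator")
        raise AlleleNameError(f"{raw!r}: does not match GENE*F1[:F2[:F3[:F4]]][X]")
    fields = tuple(m.group("fields").split(":"))
    if len(fields) > MAX_FIELDS:
        raise AlleleNameError(f"{raw!r}: more than {MAX_FIELDS} fields")
    suffix = m.group("suffix") or None
    return HaplotypeName(m.group("gene"), fields, suffix)


DEFAULT_NULL_SUFFIXES = frozenset({"N"})


def is_null_allele(
    name: HaplotypeName, null_suffixes: frozenset[str] = DEFAULT_NULL_SUFFIXES
) -> bool:
    """True iff the name carries a suffix marking an unexpressed allele.

    Only ``N`` by default; other expression suffixes (L/S/Q/C/A) denote
    altered but nonzero expression and are retained unless configured.
    """
    return name.expression_suffix in null_suffixes


@dataclass(frozen=True)
class ReferenceAllele:
    name: HaplotypeName
    sequence: str
    record_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"{self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class Reference:
    """Collection of reference alleles keyed by canonical name string."""

    def __init__(self, alleles: Iterable[ReferenceAllele], metadata: str = ""):
        self.alleles: dict[str, ReferenceAllele] = {}
        self._by_record_id: dict[str, str] = {}
        self.metadata = metadata
        for a in alleles:
            key = str(a.name)
            if key in self.alleles:
                raise ReferenceError(f"duplicate allele name {key}")
            self.alleles[key] = a
            if a.record_id:
                self._by_record_id.setdefault(a.record_id, key)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __iter__(self) -> Iterator[ReferenceAllele]:
        return iter(self.alleles.values())

    def get(self, name: str) -> ReferenceAllele | None:
        return self.alleles.get(name)

    def resolve(self, target: str) -> ReferenceAllele | None:
        """Resolve a SAM target name: canonical allele name or FASTA record id."""
        hit = self.alleles.get(target)
        if hit is not None:
            return hit
        key = self._by_record_id.get(target)
        return self.alleles[key] if key is not None else None

    def genes(self) -> list[str]:
        return sorted({a.name.gene for a in self})

    def by_gene(self, gene: str) -> list[ReferenceAllele]:
        return [a for a in self if a.name.gene == gene]


def _default_header_parser(description: str) -> HaplotypeName:
    """IMGT dialect: ``>ID NAME LENGTH bp`` — name is the second token.

    Falls back to treating the whole first token as the name.
    """
    tokens = description.split()
    candidates = [tokens[1]] if len(tokens) > 1 else []
    candidates.append(tokens[0])
    last_err: Exception | None = None
    for tok in candidates:
        try:
            return parse_allele_name(tok)
        except AlleleNameError as e:  # try the fallback token
            last_err = e
    raise AlleleNameError(str(last_err))


def load_reference(
    fasta_path: str | Path,
    header_parser: Callable[[str], HaplotypeName] | None = None,
    *,
    null_suffixes: frozenset[str] = DEFAULT_NULL_SUFFIXES,
    exclude_null: bool = True,
) -> Reference:
    """Load a cDNA allele reference from FASTA.

    Null alleles (suffix in ``null_suffixes``) are excluded by default: they
    are unexpressed, so intronic reads would artificially inflate their
    scores.  Headers that do not parse are skipped with a warning.
    """
    parse = header_parser or _default_header_parser
    alleles: list[ReferenceAllele] = []
    n_null = n_unparseable = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            name = parse(rec.description)
        except AlleleNameError:
            n_unparseable += 1
            logger.warning("skipping unparseable header: %s", rec.description)
            continue
        if exclude_null and is_null_allele(name, null_suffixes):
            n_null += 1
            continue
        alleles.append(
            ReferenceAllele(name=name, sequence=str(rec.seq).upper(), record_id=rec.id)
        )
    if not alleles:
        raise ReferenceError(f"{fasta_path}: no parseable non-null records")
    logger.info(
        "loaded %d alleles from %s (%d null excluded, %d unparseable)",
        len(alleles), fasta_path, n_null, n_unparseable,
    )
    return Reference(alleles, metadata=str(fasta_path))


# ---------------------------------------------------------------------------
# Synthetic reference generation


@dataclass(frozen=True)
class SyntheticReferenceConfig:
    """Parameters of the nested-divergence synthetic reference.

    Sequences are generated by descent: one random ancestor per gene, allele
    groups mutated from it at ``divergence_group`` per base, peptides from
    their group at ``divergence_peptide``, nucleotide variants from their
    peptide at ``divergence_nucleotide``.  The ordering
    group > peptide > nucleotide > 0 is required so that hierarchical
    similarity mirrors the real database.
    """

    n_genes: int = 10
    groups_per_gene: int = 4
    peptides_per_group: int = 3
    nucleotide_variants_per_peptide: int = 2
    base_length: int = 1000
    divergence_group: float = 0.05
    divergence_peptide: float = 0.01
    divergence_nucleotide: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.divergence_group > self.divergence_peptide
                > self.divergence_nucleotide > 0):
            raise ValueError(
                "divergences must satisfy group > peptide > nucleotide > 0"
            )
        for fld in ("n_genes", "groups_per_gene", "peptides_per_group",
                    "nucleotide_variants_per_peptide", "base_length"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be >= 1")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``,
    always to a different base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        # shift by 1..3 in base space guarantees a different base
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def generate_synthetic_reference(
    config: SyntheticReferenceConfig,
) -> tuple[Reference, dict[str, str]]:
    """Generate a nested-divergence reference; deterministic under seed.

    Returns the reference and an ancestry map ``allele name -> parent name``
    (parents are the unobserved group/peptide ancestors, recorded as
    truncated names).  Allele names are ``SYN<g>*<i>:<j>:<k>`` (depth 4;
    no intron level).
    """
    rng = np.random.default_rng(config.seed)
    alleles: list[ReferenceAllele] = []
    ancestry: dict[str, str] = {}
    for g in range(1, config.n_genes + 1):
        gene = f"SYN{g:02d}"
        ancestor = _BASES[rng.integers(0, 4, size=config.base_length)]
        for i in range(1, config.groups_per_gene + 1):
            group_seq = _mutate(ancestor, config.divergence_group, rng)
            for j in range(1, config.peptides_per_group + 1):
                pep_seq = _mutate(group_seq, config.divergence_peptide, rng)
                for k in range(1, config.nucleotide_variants_per_peptide + 1):
                    seq = _mutate(pep_seq, config.divergence_nucleotide, rng)
                    name = HaplotypeName(gene, (f"{i:02d}", f"{j:02d}", f"{k:02d}"))
                    alleles.append(
                        ReferenceAllele(
                            name=name,
                            sequence=seq.tobytes().decode("ascii"),
                            record_id=f"SYNREF:{len(alleles):05d}",
                        )
                    )
                    ancestry[str(name)] = f"{gene}*{i:02d}:{j:02d}"
    ref = Reference(alleles, metadata=f"synthetic(seed={config.seed})")
    return ref, ancestry


def standard_synthetic_reference(seed: int = 0) -> Reference:
    """The default test-bench reference: 10 genes x 4 groups x 3 peptides
    x 2 nucleotide variants, 1 kb alleles, divergences 5% / 1% / 0.2%."""
    ref, _ = generate_synthetic_reference(SyntheticReferenceConfig(seed=seed))
    return ref


def write_reference_fasta(reference: Reference, fasta_path: str | Path) -> None:
    """Write the reference in the IMGT-style header dialect
    (``>ID NAME LENGTH bp``), 60 columns per sequence line."""
    with open(fasta_path, "w") as fh:
        for a in reference:
            rid = a.record_id or str(a.name)
            fh.write(f">{rid} {a.name} {len(a)} bp\n")
            for i in range(0, len(a.sequence), 60):
                fh.write(a.sequence[i : i + 60] + "\n")


def write_ancestry_tsv(ancestry: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, parent in ancestry.items():
            fh.write(f"{name}\t{parent}\n")
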