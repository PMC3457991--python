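"""Core domain types and the indel classifier.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open (``[start, end)``), like BED.
VCF positions are 1-based anchor-base style and are converted exactly once,
at the I/O boundary.  miRNA mature sequences are stored as RNA (ACGU) and
converted to DNA only where genome comparisons happen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

DNA_ALPHABET = set("ACGT")
DNA_ALPHABET_N = set("ACGTN")

#: the three indel classes of the size/repeat taxonomy
SINGLE_BASE_PAIR = "single_base_pair"
REPEAT_EXPANSION = "repeat_expansion"
OTHER = "other"
INDEL_CLASSES = (SINGLE_BASE_PAIR, REPEAT_EXPANSION, OTHER)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic span; the universal coordinate currency."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _validate_allele(allele: str, what: str) -> str:
    allele = allele.upper()
    if not allele:
        raise ValueError(f"empty {what} allele")
    bad = set(allele) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} allele {allele!r} contains {sorted(bad)}")
    return allele


def _derive_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "complex"


@dataclass(frozen=True)
class Variant:
    """One VCF-style record (anchor-base alleles); multi-allelic rows are
    split upstream so each Variant carries exactly one alt."""

    chrom: str
    pos1: int  # 1-based VCF position of the anchor base
    rsid: str
    ref: str
    alt: str
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos1 < 1:
            raise ValueError(f"non-positive VCF position {self.pos1}")
        object.__setattr__(self, "ref", _validate_allele(self.ref, "REF"))
        object.__setattr__(self, "alt", _validate_allele(self.alt, "ALT"))
        object.__setattr__(self, "kind", _derive_kind(self.ref, self.alt))

    @property
    def anchor0(self) -> int:
        """0-based position of the anchor base."""
        return self.pos1 - 1

    @property
    def net_change(self) -> int:
        """len(alt) - len(ref); positive for insertions."""
        return len(self.alt) - len(self.ref)

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def indel_seq(self) -> str:
        """The inserted/deleted bases (non-anchor suffix of the longer allele)."""
        if self.kind == "insertion":
            return self.alt[len(self.ref):]
        if self.kind == "deletion":
            return self.ref[len(self.alt):]
        raise ValueError(f"{self.rsid or self.chrom}: not an indel ({self.kind})")


@dataclass(frozen=True)
class MirnaAnnotation:
    """A precursor hairpin with its mature products.

    ``sequences`` maps a mature name to its RNA sequence (ACGU); it may be
    empty if only coordinates are known (sequences can then be derived from
    a genome).
    """

    name: str
    pre_interval: GenomicInterval
    mature_intervals: tuple = ()  # tuple[(name, GenomicInterval), ...]
    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mat_name, iv in self.mature_intervals:
            if not self.pre_interval.contains(iv):
                raise ValueError(
                    f"mature {mat_name} {iv.chrom}:{iv.start}-{iv.end} not "
                    f"inside precursor {self.name}"
                )
            if not (18 <= iv.length() <= 26):
                warnings.warn(
                    f"mature {mat_name} has unusual length {iv.length()}",
                    stacklevel=2,
                )
        for mat_name, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGU")
            if bad:
                raise ValueError(f"mature sequence {mat_name} contains {sorted(bad)}")


@dataclass(frozen=True)
class TargetPair:
    """An experimentally supported mRNA:miRNA pair."""

    gene_id: str
    mirna_name: str
    evidence_source: str = ""


CANONICAL_FOOTPRINT_LENGTH = 41


@dataclass(frozen=True)
class FootprintRecord:
    """An Argonaute crosslinking footprint (canonically 41 nt)."""

    footprint_id: str
    interval: GenomicInterval
    bound_mirnas: tuple = ()

    def __post_init__(self) -> None:
        if self.interval.length() != CANONICAL_FOOTPRINT_LENGTH:
            warnings.warn(
                f"footprint {self.footprint_id} length "
                f"{self.interval.length()} != {CANONICAL_FOOTPRINT_LENGTH}",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Indel classification
# ---------------------------------------------------------------------------

def _unit_decompositions(s: str):
    """Yield every unit u such that s is a whole number >= 1 of copies of u."""
    n = len(s)
    for lu in range(1, n + 1):
        if n % lu:
            continue
        u = s[:lu]
        if u * (n // lu) == s:
            yield u


def classify_indel(variant: Variant, genome: Mapping[str, str]) -> str:
    """Assign an indel to one of three classes.

    Classes follow the size-first taxonomy: (i) a net 1-bp indel is
    ``single_base_pair`` regardless of repeat context; (ii) a longer indel
    whose inserted/deleted sequence is a whole number of copies of some unit
    ``u`` with at least one further copy of ``u`` immediately adjacent in
    the reference is a ``repeat_expansion``; (iii) everything else is
    ``other``.

    ``genome`` must cover the variant's reference span plus the adjacent
    context needed for the repeat check (the inserted/deleted length on
    either side is sufficient).
    """
    if not variant.is_indel:
        raise ValueError(f"classify_indel needs an indel, got kind={variant.kind}")
    s = variant.indel_seq
    if len(s) == 1:
        return SINGLE_BASE_PAIR

    seq = genome[variant.chrom]
    a = variant.anchor0
    ref_seen = seq[a: a + len(variant.ref)].upper()
    if ref_seen != variant.ref:
        raise ValueError(
            f"{variant.rsid or variant.chrom}:{variant.pos1} REF "
            f"{variant.ref!r} does not match genome {ref_seen!r}"
        )

    if variant.kind == "insertion":
        # insertion point sits right after the ref span
        right_start = a + len(variant.ref)
        left_end = a + len(variant.ref)
    else:  # deletion: deleted bases occupy [a+len(alt), a+len(ref))
        right_start = a + len(variant.ref)
        left_end = a + len(variant.alt)

    for u in _unit_decompositions(s):
        lu = len(u)
        right = seq[right_start: right_start + lu].upper()
        if right == u:
            return REPEAT_EXPANSION
        if left_end - lu >= 0 and seq[left_end - lu: left_end].upper() == u:
            return REPEAT_EXPANSION
    return OTHER
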