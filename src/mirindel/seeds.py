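"""Seed-site motif generation and reference-vs-mutant window diffing.

The core operation of the package: for each variant, extract a window of
reference sequence around it, build the corresponding mutant window by
substituting the alternate allele, scan both for exact seed-site motifs of
each miRNA, and compare the two match sets.  A site present in the
reference but not (after offset normalisation) in the mutant is called
*disrupted*; the converse is *created*.

Seed-site types follow the canonical catalogue: a site of type spanning
miRNA positions ``i..j`` is the reverse complement (in DNA space) of those
mature positions, with an extra ``A`` appended at the 3' end of the site
for the A1-anchored types (8mer, 7mer-A1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .model import Variant

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedType:
    """A target-site category defined by which mature miRNA positions pair.

    ``mirna_span`` is 1-based inclusive on the mature miRNA; ``requires_A1``
    adds an adenine opposite miRNA position 1 at the 3' end of the site.
    """

    name: str
    mirna_span: Tuple[int, int]
    requires_A1: bool = False

    @property
    def motif_length(self) -> int:
        i, j = self.mirna_span
        return j - i + 1 + (1 if self.requires_A1 else 0)


#: default six seed-site types (user-overridable via configuration)
DEFAULT_SEED_TYPES: Tuple[SeedType, ...] = (
    SeedType("8mer", (2, 8), requires_A1=True),
    SeedType("7mer-m8", (2, 8)),
    SeedType("7mer-A1", (2, 7), requires_A1=True),
    SeedType("6mer", (2, 7)),
    SeedType("offset-6mer", (3, 8)),
    SeedType("offset-7mer", (3, 9)),
)


def seed_motifs(mature_rna: str,
                seed_types: Sequence[SeedType] = DEFAULT_SEED_TYPES
                ) -> Dict[str, str]:
    """Map seed-type name -> DNA site motif for one mature miRNA.

    The motif is the reverse complement of the spanned mature positions
    (RNA converted to DNA), plus a 3' ``A`` for A1-anchored types.  Types
    whose span exceeds the mature length are dropped with a warning.
    """
    dna = mature_rna.upper().replace("U", "T")
    out: Dict[str, str] = {}
    for st in seed_types:
        i, j = st.mirna_span
        if j > len(dna):
            warnings.warn(
                f"mature of length {len(dna)} too short for {st.name} "
                f"(needs position {j}); type dropped",
                stacklevel=2,
            )
            continue
        motif = revcomp(dna[i - 1: j])
        if st.requires_A1:
            motif = motif + "A"
        out[st.name] = motif
    return out


@dataclass(frozen=True)
class Motif:
    """A scannable motif tagged with its miRNA and seed type."""

    mirna_name: str
    seed_type: str
    motif: str


def catalog_motifs(catalog: Mapping[str, str],
                   seed_types: Sequence[SeedType] = DEFAULT_SEED_TYPES
                   ) -> List[Motif]:
    """Flatten {mirna_name: mature RNA} into a motif list."""
    out: List[Motif] = []
    for name in sorted(catalog):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for st_name, motif in seed_motifs(catalog[name], seed_types).items():
                out.append(Motif(name, st_name, motif))
    return out


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowPair:
    """Reference and mutant windows around one variant."""

    ref: str
    mut: str
    origin: int       # 0-based genomic coordinate of the left window edge
    anchor_offset: int  # offset of the variant anchor base within ref window
    truncated: bool = False


def extract_windows(genome: Mapping[str, str], v: Variant,
                    half_width: int = 50) -> WindowPair:
    """Extract ``half_width`` nt of flank either side of the variant's
    reference span; the mutant window carries the alt allele instead.

    Windows crossing a chromosome edge are truncated and flagged.
    """
    seq = genome[v.chrom]
    a = v.anchor0
    if not (0 <= a < len(seq)):
        raise ValueError(f"variant {v.rsid} at {v.pos1} outside chromosome")
    ref_seen = seq[a: a + len(v.ref)].upper()
    if ref_seen != v.ref:
        raise ValueError(
            f"{v.rsid or v.chrom}:{v.pos1} REF {v.ref!r} != genome {ref_seen!r}"
        )
    left = max(0, a - half_width)
    right = min(len(seq), a + len(v.ref) + half_width)
    truncated = left != a - half_width or right != a + len(v.ref) + half_width
    ref_w = seq[left: right]
    mut_w = seq[left: a] + v.alt + seq[a + len(v.ref): right]
    return WindowPair(ref_w, mut_w, left, a - left, truncated)


# ---------------------------------------------------------------------------
# Scanning and diffing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteMatch:
    """One exact motif occurrence in a scanned window."""

    mirna_name: str
    seed_type: str
    offset: int  # 0-based start within the window
    motif: str


def scan(window: str, motifs: Iterable[Motif]) -> List[SiteMatch]:
    """All exact occurrences of every motif (overlaps included).

    Windows may contain N; N never matches any motif base.
    """
    window = window.upper()
    out: List[SiteMatch] = []
    for m in motifs:
        start = 0
        while True:
            idx = window.find(m.motif, start)
            if idx < 0:
                break
            out.append(SiteMatch(m.mirna_name, m.seed_type, idx, m.motif))
            start = idx + 1
    return out


@dataclass(frozen=True)
class ImpactCall:
    """A seed site disrupted or created by one variant."""

    rsid: str
    mirna_name: str
    seed_type: str
    status: str                 # "disrupted" | "created"
    ref_offset: int | None      # window offset in the reference frame
    mut_offset: int | None      # window offset in the mutant frame
    genomic_site_start: int     # reference-frame genomic start of the site


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def diff_sites(ref_matches: Sequence[SiteMatch], mut_matches: Sequence[SiteMatch],
               v: Variant, anchor_offset: int, origin: int = 0
               ) -> List[ImpactCall]:
    """Compare match sets between reference and mutant windows.

    Mutant offsets strictly right of the variant's left edge are shifted
    back by the net length change before comparison, so unchanged
    downstream sites cancel.  Per (miRNA, seed type), reference matches
    with no equivalent mutant match are *disrupted*; the converse are
    *created*.
    """
    delta = v.net_change
    edge = anchor_offset + _common_prefix_len(v.ref, v.alt) - 1

    def map_mut(off: int) -> int:
        return off - delta if off > edge else off

    keys = {(m.mirna_name, m.seed_type) for m in ref_matches}
    keys |= {(m.mirna_name, m.seed_type) for m in mut_matches}
    calls: List[ImpactCall] = []
    for key in sorted(keys):
        r_offs = {m.offset for m in ref_matches
                  if (m.mirna_name, m.seed_type) == key}
        m_pairs = [(m.offset, map_mut(m.offset)) for m in mut_matches
                   if (m.mirna_name, m.seed_type) == key]
        m_mapped = {mapped for _, mapped in m_pairs}
        for off in sorted(r_offs - m_mapped):
            calls.append(ImpactCall(v.rsid, key[0], key[1], "disrupted",
                                    off, None, origin + off))
        for raw, mapped in sorted(m_pairs):
            if mapped not in r_offs:
                calls.append(ImpactCall(v.rsid, key[0], key[1], "created",
                                        None, raw, origin + mapped))
    return calls


def call_impacts(genome: Mapping[str, str], v: Variant,
                 motifs: Sequence[Motif], half_width: int = 50,
                 strand: str = "+") -> List[ImpactCall]:
    """Extract windows, scan and diff for one variant.

    ``strand`` is the transcript strand of the scanned region.  Sites live
    on the mRNA sense strand, so for a '-' transcript the motifs are
    reverse-complemented and scanned against the genome-plus windows; the
    reported matches keep their miRNA/seed-type identity.
    """
    wp = extract_windows(genome, v, half_width)
    if strand == "-":
        motifs = [Motif(m.mirna_name, m.seed_type, revcomp(m.motif)) for m in motifs]
    ref_matches = scan(wp.ref, motifs)
    mut_matches = scan(wp.mut, motifs)
    return diff_sites(ref_matches, mut_matches, v, wp.anchor_offset, wp.origin)
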