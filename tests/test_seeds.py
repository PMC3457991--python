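"""Seed motif construction, window extraction, scanning and diffing.

The diff engine is checked exactly against an independent oracle that
re-scans both windows by naive substring enumeration and set-subtracts
after offset normalisation.
"""

import re

import numpy as np
import pytest

from mirindel.model import Variant
from mirindel.seeds import (DEFAULT_SEED_TYPES, Motif, call_impacts,
                            diff_sites, extract_windows, revcomp, scan,
                            seed_motifs)

MATURE = "UAGCAGCACGUAAAUAUUGGCG"  # a canonical 22-nt mature sequence


@pytest.mark.parametrize("seq,expected", [
    ("ACGT", "ACGT"),
    ("AAAC", "GTTT"),
    ("ACGN", "NCGT"),
])
def test_revcomp(seq, expected):
    assert revcomp(seq) == expected


def test_revcomp_rejects_non_dna():
    with pytest.raises(ValueError):
        revcomp("ACGU")


def test_seed_motifs_hand_enumerated():
    # positions 2-8 of the mature are AGCAGCA; complements enumerated by hand
    m = seed_motifs(MATURE)
    assert m["7mer-m8"] == "TGCTGCT"
    assert m["8mer"] == "TGCTGCTA"
    assert m["6mer"] == "GCTGCT"
    assert m["7mer-A1"] == "GCTGCTA"
    assert m["offset-6mer"] == revcomp("GCAGCA")
    assert m["offset-7mer"] == revcomp("GCAGCAC")


def test_short_mature_drops_offset_types_with_warning():
    with pytest.warns(UserWarning, match="offset-7mer"):
        m = seed_motifs("UAGCAGCA")  # 8 nt
    assert "offset-7mer" not in m
    assert "7mer-m8" in m


def _motifs(mature=MATURE, name="m1"):
    return [Motif(name, st, mo) for st, mo in seed_motifs(mature).items()]


def test_extract_windows_length_bookkeeping():
    genome = {"c": "AAAACCCCGGGGTTTT"}
    # deletion of one G at the C/G junction
    v = Variant("c", 8, ".", "CG", "C")
    wp = extract_windows(genome, v, half_width=3)
    assert len(wp.mut) == len(wp.ref) - 1
    assert wp.ref == "CCCCGGGG"[0:8]  # [4,12) around span [7,9)
    # insertion adds two bases
    vi = Variant("c", 8, ".", "C", "CTT")
    wpi = extract_windows(genome, vi, half_width=3)
    assert len(wpi.mut) == len(wpi.ref) + 2
    # SNV windows differ at exactly one position
    vs = Variant("c", 8, ".", "C", "A")
    wps = extract_windows(genome, vs, half_width=3)
    assert sum(x != y for x, y in zip(wps.ref, wps.mut)) == 1


def test_extract_windows_truncates_at_chromosome_edge():
    genome = {"c": "ACGTACGTAC"}
    wp = extract_windows(genome, Variant("c", 2, ".", "C", "A"), half_width=5)
    assert wp.truncated
    assert wp.origin == 0


def test_scan_exhaustive_example():
    window = "AATGCTGCTAAA"
    hits = {(h.seed_type, h.offset) for h in scan(window, _motifs())}
    assert ("8mer", 2) in hits
    assert ("7mer-m8", 2) in hits
    assert ("7mer-A1", 3) in hits
    assert ("6mer", 3) in hits
    # no hit may disagree with the window content
    for h in scan(window, _motifs()):
        assert window[h.offset: h.offset + len(h.motif)] == h.motif


def test_scan_no_complementarity_and_overlaps():
    assert scan("AAAAAAAA", _motifs()) == []
    motif = [Motif("m", "t", "AA")]
    assert [h.offset for h in scan("AAA", motif)] == [0, 1]
    # N never matches
    assert scan("TGCTGNT", [Motif("m", "t", "TGCTGCT")]) == []


def test_snv_outside_any_motif_yields_no_calls():
    genome = {"c": "T" * 30 + "TGCTGCTA" + "T" * 30}
    v = Variant("c", 5, ".", "T", "A")  # far left of the site
    calls = call_impacts(genome, v, _motifs(), half_width=20)
    assert calls == []


def test_deletion_inside_8mer_disrupts_nested_types_too():
    genome = {"c": "T" * 30 + "TGCTGCTA" + "T" * 30}
    # delete the first C of the motif (genome offset 33, anchor at 32)
    v = Variant("c", 33, ".", "CT", "C")
    assert genome["c"][32:34] == "CT"
    calls = call_impacts(genome, v, _motifs(), half_width=25)
    disrupted = {c.seed_type for c in calls if c.status == "disrupted"}
    assert {"8mer", "7mer-m8", "7mer-A1", "6mer"} <= disrupted
    assert all(c.status == "disrupted" for c in calls)


def test_insertion_completing_motif_is_created():
    # reference lacks the 6mer GCTGCT by one base; inserting C completes it
    genome = {"c": "T" * 30 + "GTGCT" + "T" * 30}
    v = Variant("c", 31, ".", "G", "GC")  # GTGCT -> GCTGCT
    assert genome["c"][30] == "G"
    calls = call_impacts(genome, v, [Motif("m1", "6mer", "GCTGCT")],
                         half_width=20)
    assert [c.status for c in calls] == ["created"]


def test_flank_sites_are_never_called():
    """Motif occurrences entirely left or right of the indel cancel."""
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    motif = "TGCTGCTA"
    for _ in range(200):
        left = "".join(rng.choice(bases, 40))
        right = "".join(rng.choice(bases, 40))
        mid = "".join(rng.choice(bases, 10))
        seq = left[:10] + motif + left[18:] + mid + right[:20] + motif + right[28:]
        a = 45 + int(rng.integers(0, 8))  # inside mid region
        if rng.random() < 0.5:
            v = Variant("c", a + 1, ".", seq[a], seq[a] + "".join(
                rng.choice(bases, int(rng.integers(1, 4)))))
        else:
            L = int(rng.integers(1, 4))
            v = Variant("c", a + 1, ".", seq[a: a + 1 + L], seq[a])
        calls = call_impacts({"c": seq}, v, [Motif("m", "8mer", motif)],
                             half_width=50)
        for c in calls:
            # a genuine call must not point at the planted flank copies
            if c.status == "disrupted":
                assert c.ref_offset not in (10, None)


def _oracle_diff(ref_w, mut_w, motifs, v, anchor_offset):
    """Independent scan-and-subtract oracle using regex enumeration."""
    delta = len(v.alt) - len(v.ref)
    cp = 0
    for x, y in zip(v.ref, v.alt):
        if x != y:
            break
        cp += 1
    edge = anchor_offset + cp - 1
    out = set()
    for m in motifs:
        pat = re.compile(f"(?={re.escape(m.motif)})")
        r_offs = {mm.start() for mm in pat.finditer(ref_w)}
        raw = {mm.start() for mm in pat.finditer(mut_w)}
        mapped = {o - delta if o > edge else o for o in raw}
        for o in sorted(r_offs - mapped):
            out.add((m.mirna_name, m.seed_type, "disrupted", o))
        for o in sorted(raw):
            om = o - delta if o > edge else o
            if om not in r_offs:
                out.add((m.mirna_name, m.seed_type, "created", om))
    return out


def test_diff_equals_bruteforce_oracle_on_random_fixtures():
    """Random windows x random matures x random indels: exact agreement
    with the independent scan-and-subtract oracle."""
    rng = np.random.default_rng(202)
    bases = np.array(list("ACGT"))
    rna = np.array(list("ACGU"))
    for _ in range(400):
        seq = "".join(rng.choice(bases, 160))
        mature = "".join(rng.choice(rna, 22))
        motifs = [Motif("m1", st, mo) for st, mo in seed_motifs(mature).items()]
        a = int(rng.integers(40, 110))
        r = rng.random()
        if r < 0.4:
            v = Variant("c", a + 1, ".", seq[a], seq[a] + "".join(
                rng.choice(bases, int(rng.integers(1, 5)))))
        elif r < 0.8:
            L = int(rng.integers(1, 5))
            v = Variant("c", a + 1, ".", seq[a: a + 1 + L], seq[a])
        else:
            alt = "ACGT"[int(rng.integers(4))]
            if alt == seq[a]:
                continue
            v = Variant("c", a + 1, ".", seq[a], alt)
        wp = extract_windows({"c": seq}, v, half_width=50)
        got = {(c.mirna_name, c.seed_type, c.status,
                c.ref_offset if c.status == "disrupted"
                else c.genomic_site_start - wp.origin)
               for c in call_impacts({"c": seq}, v, motifs, half_width=50)}
        want = _oracle_diff(wp.ref, wp.mut, motifs, v, wp.anchor_offset)
        assert got == want


def test_minus_strand_scanning_finds_transcript_sense_motif():
    motif = seed_motifs(MATURE)["7mer-m8"]       # TGCTGCT on the transcript
    genome = {"c": "T" * 100 + revcomp(motif) + "T" * 93}
    v = Variant("c", 103, ".", "CA", "C")        # delete one motif base
    assert genome["c"][102:104] == "CA"
    calls = call_impacts(genome, v, _motifs(), half_width=50, strand="-")
    disrupted = {c.seed_type for c in calls if c.status == "disrupted"}
    assert "7mer-m8" in disrupted
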