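"""Domain types, format readers/writers and their round trips."""

import pytest

from mirindel import io as mio
from mirindel.model import (FootprintRecord, GenomicInterval,
                            MirnaAnnotation, Variant)


# ---------------------------------------------------------------------------
# GenomicInterval / Variant invariants
# ---------------------------------------------------------------------------

def test_interval_rejects_empty_and_negative():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


@pytest.mark.parametrize("ref,alt,kind", [
    ("A", "C", "snv"),
    ("A", "AC", "insertion"),
    ("AT", "A", "deletion"),
    ("A", "ACACA", "insertion"),
    ("AC", "GT", "complex"),
])
def test_variant_kind_derivation(ref, alt, kind):
    assert Variant("chr1", 10, ".", ref, alt).kind == kind


def test_variant_rejects_bad_alleles():
    with pytest.raises(ValueError):
        Variant("chr1", 10, ".", "", "A")
    with pytest.raises(ValueError):
        Variant("chr1", 10, ".", "AX", "A")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_read_fasta_single_and_folded(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1\nACGT\n")
    assert mio.read_fasta(p) == {"chr1": "ACGT"}
    p.write_text(">a\nAC\nGT\n>b\nTT\n")
    assert mio.read_fasta(p) == {"a": "ACGT", "b": "TT"}


def test_read_fasta_alphabet_error_names_offset(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text(">a\nACXT\n")
    with pytest.raises(ValueError, match="offset 2"):
        mio.read_fasta(p)


def test_read_fasta_duplicate_names(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">a\nAC\n>a\nGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        mio.read_fasta(p)


def test_fasta_round_trip(tmp_path):
    seqs = {"chr1": "ACGTACGT" * 20, "chr2": "TTTT"}
    p = tmp_path / "rt.fa"
    mio.write_fasta(p, seqs, width=13)
    assert mio.read_fasta(p) == seqs


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

def test_read_vcf_insertion_of_c(tmp_path):
    # the canonical single-base insertion shape: anchor A gains a C
    p = tmp_path / "v.vcf"
    p.write_text("#CHROM\tPOS\tID\tREF\tALT\n"
                 "chr2\t25166699\trs34922018\tA\tAC\n")
    (v,) = mio.read_vcf_min(p)
    assert v.kind == "insertion"
    assert v.indel_seq == "C"
    assert v.pos1 == 25166699 and v.rsid == "rs34922018"


def test_read_vcf_anchor_deletion_and_multiallelic(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text("chr1\t10\t.\tAT\tA\nchr1\t10\t.\tA\tC,G\n")
    vs = mio.read_vcf_min(p)
    assert [v.kind for v in vs] == ["deletion", "snv", "snv"]
    assert vs[0].indel_seq == "T"
    assert (vs[1].alt, vs[2].alt) == ("C", "G")


def test_read_vcf_bad_pos(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text("chr1\tten\t.\tA\tC\n")
    with pytest.raises(ValueError, match="non-integer POS"):
        mio.read_vcf_min(p)


def test_vcf_round_trip(tmp_path):
    vs = [Variant("chr1", 5, "rs1", "A", "AC"),
          Variant("chr2", 9, "rs2", "GT", "G"),
          Variant("chr2", 12, "rs3", "T", "A")]
    p = tmp_path / "rt.vcf"
    mio.write_vcf_min(p, vs)
    assert mio.read_vcf_min(p) == vs


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def test_read_bed_footprint_canonical_length(tmp_path):
    p = tmp_path / "fp.bed"
    p.write_text("chr1\t100\t141\tfp1\n")
    (fp,) = mio.read_footprints(p)
    assert fp.interval.length() == 41
    assert fp.footprint_id == "fp1"


def test_read_bed_noncanonical_footprint_warns(tmp_path):
    p = tmp_path / "fp.bed"
    p.write_text("chr1\t100\t130\tfp1\n")
    with pytest.warns(UserWarning, match="length 30"):
        mio.read_footprints(p)


def test_read_bed_empty_interval_rejected(tmp_path):
    p = tmp_path / "b.bed"
    p.write_text("chr1\t5\t5\tx\n")
    with pytest.raises(ValueError, match="empty interval"):
        mio.read_bed(p)


def test_gwas_marker_row(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("chrom\tpos\trsid\tp\ttrait\n"
                 "chr2\t25158008\trs713586\t6e-22\tBody Mass Index\n")
    df = mio.read_gwas_markers(p)
    row = df.iloc[0]
    assert row["rsid"] == "rs713586"
    assert row["pos"] == 25158008
    assert row["p"] == pytest.approx(6e-22)
    assert row["trait"] == "Body Mass Index"


def test_read_tsv_missing_schema_column(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("a\tb\n1\t2\n")
    with pytest.raises(ValueError, match="missing required columns"):
        mio.read_tsv_table(p, {"a": int, "c": str})


def test_tsv_round_trip_with_comment_header(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"gene_id": ["g1", "g2"], "mirna": ["m1", "m2"],
                       "source": ["s", "s"]})
    p = tmp_path / "pairs.tsv"
    mio.write_tsv(p, df, ["pairs table", "units: none"])
    back = mio.read_tsv_table(p, {"gene_id": str, "mirna": str})
    assert back.equals(df)


# ---------------------------------------------------------------------------
# miRNA GFF3
# ---------------------------------------------------------------------------

def test_mirna_gff_round_trip(tmp_path):
    pre = GenomicInterval("chr1", 1000, 1100, "-")
    mat = GenomicInterval("chr1", 1010, 1032, "-")
    m = MirnaAnnotation("syn-mir-001", pre, (("syn-miR-001", mat),))
    p = tmp_path / "m.gff3"
    mio.write_mirna_gff(p, [m])
    (back,) = mio.read_mirna_gff(p)
    assert back.name == m.name
    assert back.pre_interval == pre
    assert back.mature_intervals == (("syn-miR-001", mat),)


def test_mature_outside_precursor_rejected():
    pre = GenomicInterval("chr1", 1000, 1100)
    mat = GenomicInterval("chr1", 1090, 1112)
    with pytest.raises(ValueError, match="not inside precursor"):
        MirnaAnnotation("x", pre, (("x-mat", mat),))
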