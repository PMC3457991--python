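"""Readers and writers for every on-disk format the pipeline touches.

All conversions between external coordinate conventions (1-based VCF/GFF,
0-based BED) and the internal 0-based half-open convention happen here and
nowhere else.  Writers emit tab-separated files with a ``#``-prefixed
comment preamble describing the columns; readers skip such comments.
"""

from __future__ import annotations

import io as _io
import re
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    FootprintRecord,
    GenomicInterval,
    MirnaAnnotation,
    TargetPair,
    Variant,
)

_NON_DNA = re.compile(r"[^ACGTN]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    The name is the first whitespace token of the header.  Duplicate names
    and characters outside ACGTN raise ``ValueError`` (with the 0-based
    offset of the first offending character).
    """
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in out:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seq = str(rec.seq).upper()
        m = _NON_DNA.search(seq)
        if m:
            raise ValueError(
                f"record {name!r}: invalid character {m.group()!r} at offset {m.start()}"
            )
        out[name] = seq
    return out


def read_rna_fasta(path) -> Dict[str, str]:
    """Read a FASTA of RNA sequences (ACGU; T tolerated and mapped to U)."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - set("ACGUN")
        if bad:
            raise ValueError(f"record {rec.id!r}: invalid characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

def read_vcf_min(path) -> List[Variant]:
    """Read a minimal VCF (CHROM POS ID REF ALT; extra columns ignored).

    Multi-allelic rows are split into one Variant per alt allele, preserving
    file order.
    """
    variants: List[Variant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            chrom, pos_s, rsid, ref, alts = fields[:5]
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS {pos_s!r}") from exc
            for alt in alts.split(","):
                try:
                    variants.append(Variant(chrom, pos1, rsid, ref, alt))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return variants


def write_vcf_min(path, variants: Iterable[Variant]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos1}\t{v.rsid}\t{v.ref}\t{v.alt}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> List[Tuple[str, GenomicInterval]]:
    """Read BED4/BED6 into [(name, GenomicInterval)].  Strand defaults '+'."""
    out: List[Tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval {start}-{end}")
            name = f[3] if len(f) > 3 and f[3] else f"{chrom}:{start}-{end}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
            out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out


def write_bed(path, records: Iterable[Tuple[str, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for name, iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_footprints(path) -> List[FootprintRecord]:
    return [FootprintRecord(name, iv) for name, iv in read_bed(path)]


def read_utr_bed(path) -> Dict[str, GenomicInterval]:
    """Read a 3' UTR BED keyed by gene id (duplicates raise)."""
    out: Dict[str, GenomicInterval] = {}
    for name, iv in read_bed(path):
        if name in out:
            raise ValueError(f"duplicate UTR annotation for gene {name!r}")
        out[name] = iv
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tsv_table(path, schema: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a headered TSV (``#`` comment lines skipped); enforce a schema.

    ``schema`` maps required column names to dtypes they are cast to.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for col, typ in schema.items():
            if typ is not str:
                df[col] = df[col].astype(typ)
    return df


def write_tsv(path, df: pd.DataFrame, comment_lines: Sequence[str] = ()) -> None:
    """Write a TSV with a commented preamble naming column semantics."""
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


GWAS_SCHEMA = {"chrom": str, "pos": int, "rsid": str, "p": float, "trait": str}


def read_gwas_markers(path) -> pd.DataFrame:
    """GWAS marker table: chrom, pos (1-based), rsid, p, trait."""
    return read_tsv_table(path, GWAS_SCHEMA)


def read_pairs(path) -> List[TargetPair]:
    df = read_tsv_table(path, {"gene_id": str, "mirna": str})
    source = df["source"] if "source" in df.columns else [""] * len(df)
    return [
        TargetPair(g, m, s)
        for g, m, s in zip(df["gene_id"], df["mirna"], source)
    ]


def read_pathways(path) -> pd.DataFrame:
    """Pathway membership: pathway_id, pathway_name, gene_id (one row per gene)."""
    return read_tsv_table(path, {"pathway_id": str, "pathway_name": str, "gene_id": str})


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def read_panel(path) -> pd.DataFrame:
    """Genotype panel TSV: rsid, chrom, pos, then one 0/1/2/NA column per
    individual.  Genotypes come back as float with NaN for missing."""
    df = read_tsv_table(path, {"rsid": str, "chrom": str, "pos": int})
    geno_cols = [c for c in df.columns if c not in ("rsid", "chrom", "pos")]
    for c in geno_cols:
        df[c] = pd.to_numeric(df[c].replace({"NA": np.nan, ".": np.nan}))
        vals = df[c].dropna()
        if not vals.isin([0, 1, 2]).all():
            raise ValueError(f"{path}: genotype column {c} has values outside 0/1/2")
    return df


# ---------------------------------------------------------------------------
# miRNA GFF3 (miRBase convention)
# ---------------------------------------------------------------------------

def _gff_attrs(field: str) -> Dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_mirna_gff(path, mature_sequences: Mapping[str, str] | None = None
                   ) -> List[MirnaAnnotation]:
    """Read miRNA annotations from a miRBase-style GFF3.

    Features of type ``miRNA_primary_transcript`` define precursors; type
    ``miRNA`` features attach to their precursor via ``Derives_from``.
    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    ``mature_sequences`` optionally supplies mature RNA by mature name.
    """
    pres: Dict[str, Tuple[str, GenomicInterval]] = {}  # ID -> (name, interval)
    matures: Dict[str, List[Tuple[str, GenomicInterval]]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs_s = f
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            attrs = _gff_attrs(attrs_s)
            if ftype == "miRNA_primary_transcript":
                fid = attrs.get("ID", attrs.get("Name"))
                pres[fid] = (attrs.get("Name", fid), iv)
                order.append(fid)
            elif ftype == "miRNA":
                parent = attrs.get("Derives_from")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: miRNA without Derives_from")
                matures.setdefault(parent, []).append(
                    (attrs.get("Name", attrs.get("ID", "?")), iv)
                )
    out = []
    for fid in order:
        name, pre_iv = pres[fid]
        mats = tuple(matures.get(fid, []))
        seqs = {}
        if mature_sequences:
            seqs = {mn: mature_sequences[mn] for mn, _ in mats if mn in mature_sequences}
        out.append(MirnaAnnotation(name, pre_iv, mats, seqs))
    return out


def write_mirna_gff(path, mirnas: Iterable[MirnaAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in mirnas:
            iv = m.pre_interval
            fh.write(
                f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\tID={m.name};Name={m.name}\n"
            )
            for mat_name, mat_iv in m.mature_intervals:
                fh.write(
                    f"{mat_iv.chrom}\t.\tmiRNA\t{mat_iv.start + 1}\t{mat_iv.end}"
                    f"\t.\t{mat_iv.strand}\t.\tID={mat_name};Name={mat_name};"
                    f"Derives_from={m.name}\n"
                )


def derive_mature_sequences(mirnas: Sequence[MirnaAnnotation],
                            genome: Mapping[str, str]) -> Dict[str, str]:
    """Transcribe mature RNA sequences from genome coordinates (strand-aware)."""
    from .seeds import revcomp

    out: Dict[str, str] = {}
    for m in mirnas:
        for mat_name, iv in m.mature_intervals:
            dna = genome[iv.chrom][iv.start: iv.end]
            if iv.strand == "-":
                dna = revcomp(dna)
            out[mat_name] = dna.replace("T", "U")
    return out
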