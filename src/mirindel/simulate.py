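"""Synthetic-data generator with known ground truth.

Emulates the statistical structure of the real inputs the pipeline was
designed for — region-dependent variant densities (lower in mature miRNAs
and crosslink footprints than in flanks), the three engineered indel
classes in stated proportions, seed-site motifs planted so that chosen
indels disrupt or create them, and genotype panels with block LD
structure — without downloading anything.

Every output is a pure function of :class:`GeneratorConfig`; sub-seeds are
derived from the master seed by stable hashing of component names, so
reruns are byte-identical.

The generator's verification of planted sites and engineered indel classes
uses its own plain substring/repeat logic, deliberately independent of the
scanning and classification modules it is used to test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import FootprintRecord, GenomicInterval, MirnaAnnotation, TargetPair, Variant
from .regions import build_footprint_regions, build_mirna_regions
from .seeds import DEFAULT_SEED_TYPES, seed_motifs
from . import io as mio

_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def subseed(seed: int, name: str) -> int:
    """Stable 31-bit sub-seed for a named generator component."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Haplotype-panel structure: blocks of perfectly coupled founders with
    free recombination between blocks."""

    n_individuals: int = 120
    n_blocks: int = 2
    markers_per_block: int = 6
    marker_spacing: int = 3000     # bp between adjacent markers in a block
    block_gap: int = 50_000        # bp between consecutive blocks
    founder_freq_range: Tuple[float, float] = (0.3, 0.7)


def _default_densities() -> Dict[str, float]:
    # variants per nt; flanks/UTR at background rate, cores suppressed
    return {
        "flank": 0.012,
        "pre": 0.010,
        "mature": 0.005,
        "utr3": 0.012,
        "footprint": 0.004,
        "footprint_flank": 0.012,
    }


@dataclass
class GeneratorConfig:
    rng_seed: int = 0
    genome_length: int = 400_000
    chrom: str = "chr1"
    gc_fraction: float = 0.41
    n_mirnas: int = 30
    pre_length: int = 100
    mature_length: int = 22
    n_utrs: int = 40
    utr_length_range: Tuple[int, int] = (400, 1200)
    n_footprints: int = 60
    footprint_length: int = 41
    region_density_map: Dict[str, float] = field(default_factory=_default_densities)
    indel_fraction: float = 0.18   # indels among all variants
    indel_class_mix: Tuple[float, float, float] = (0.55, 0.14, 0.31)
    planted_site_fraction: float = 0.5   # of eligible UTR/footprint indels
    created_fraction: float = 0.3        # of planted sites, rest disrupted
    make_panel: bool = True
    panel: PanelConfig = field(default_factory=PanelConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.indel_class_mix) - 1.0) > 1e-9:
            raise ValueError("indel_class_mix must sum to 1")
        if any(d < 0 for d in self.region_density_map.values()):
            raise ValueError("densities must be >= 0")
        for name in ("genome_length", "pre_length", "mature_length",
                     "footprint_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Bundle:
    """Everything one generator run produced, in memory."""

    cfg: GeneratorConfig
    genome: Dict[str, str]
    mirnas: List[MirnaAnnotation]
    catalog: Dict[str, str]                  # mature name -> RNA sequence
    utrs: Dict[str, GenomicInterval]
    footprints: List[FootprintRecord]
    pairs: List[TargetPair]
    pathways: pd.DataFrame
    variants: List[Variant]
    truth: pd.DataFrame
    panel: Optional[pd.DataFrame] = None
    gwas: Optional[pd.DataFrame] = None
    panel_truth: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def gen_genome(cfg: GeneratorConfig) -> Dict[str, str]:
    """An i.i.d. random chromosome at the configured GC fraction."""
    rng = np.random.default_rng(subseed(cfg.rng_seed, "genome"))
    gc = cfg.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                       size=cfg.genome_length, p=p)
    return {cfg.chrom: bases.tobytes().decode("ascii")}


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    mirnas: List[MirnaAnnotation]
    utrs: Dict[str, GenomicInterval]
    utr_strands: Dict[str, str]
    footprints: List[FootprintRecord]
    fp_host: Dict[str, str]        # footprint id -> gene id
    pairs: List[TargetPair]
    pathways: pd.DataFrame


def gen_annotations(cfg: GeneratorConfig) -> _Layout:
    rng = np.random.default_rng(subseed(cfg.rng_seed, "annotations"))
    chrom = cfg.chrom
    cursor = 2 * cfg.pre_length + 10
    mirnas: List[MirnaAnnotation] = []
    for i in range(cfg.n_mirnas):
        strand = "+" if rng.random() < 0.5 else "-"
        pre = GenomicInterval(chrom, cursor, cursor + cfg.pre_length, strand)
        off = int(rng.integers(2, cfg.pre_length - cfg.mature_length - 2))
        mat = GenomicInterval(chrom, cursor + off,
                              cursor + off + cfg.mature_length, strand)
        name = f"syn-mir-{i:03d}"
        mirnas.append(MirnaAnnotation(name, pre,
                                      ((f"syn-miR-{i:03d}", mat),)))
        cursor = pre.end + 2 * cfg.pre_length + int(rng.integers(200, 800))

    utrs: Dict[str, GenomicInterval] = {}
    utr_strands: Dict[str, str] = {}
    for i in range(cfg.n_utrs):
        length = int(rng.integers(*cfg.utr_length_range))
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"GENE{i:04d}"
        utrs[gene] = GenomicInterval(chrom, cursor, cursor + length, strand)
        utr_strands[gene] = strand
        cursor = cursor + length + int(rng.integers(300, 900))
    if cursor + 2 * cfg.footprint_length >= cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too short for the requested "
            f"annotation load (needs ~{cursor})"
        )

    footprints: List[FootprintRecord] = []
    fp_host: Dict[str, str] = {}
    genes = list(utrs)
    fp_len = cfg.footprint_length
    placed = 0
    attempts = 0
    occupied: Dict[str, List[Tuple[int, int]]] = {g: [] for g in genes}
    while placed < cfg.n_footprints and genes:
        attempts += 1
        if attempts > 50 * max(1, cfg.n_footprints):
            raise ValueError("footprint placement failed after bounded retries")
        gene = genes[int(rng.integers(len(genes)))]
        iv = utrs[gene]
        if iv.length() < 3 * fp_len:
            continue
        start = int(rng.integers(iv.start + fp_len, iv.end - 2 * fp_len))
        clash = any(start - 3 * fp_len < e and s < start + 4 * fp_len
                    for s, e in occupied[gene])
        if clash:
            continue
        occupied[gene].append((start, start + fp_len))
        fid = f"fp{placed:04d}"
        footprints.append(FootprintRecord(
            fid, GenomicInterval(iv.chrom, start, start + fp_len, iv.strand)))
        fp_host[fid] = gene
        placed += 1

    mature_names = [m.mature_intervals[0][0] for m in mirnas]
    pairs: List[TargetPair] = []
    if mature_names:
        for gene in utrs:
            k = int(rng.integers(1, min(3, len(mature_names)) + 1))
            chosen = rng.choice(len(mature_names), size=k, replace=False)
            for c in sorted(chosen):
                pairs.append(TargetPair(gene, mature_names[c], "synthetic"))

    rows = []
    gene_list = list(utrs)
    if gene_list:
        n_pathways = min(5, max(1, len(gene_list) // 8))
        for p in range(n_pathways):
            size = int(rng.integers(max(2, len(gene_list) // 3),
                                    max(3, 2 * len(gene_list) // 3)))
            members = rng.choice(len(gene_list), size=min(size, len(gene_list)),
                                 replace=False)
            for gi in sorted(members):
                rows.append((f"path{p:02d}", f"synthetic pathway {p}",
                             gene_list[gi]))
    pathways = pd.DataFrame(rows, columns=["pathway_id", "pathway_name",
                                           "gene_id"])
    return _Layout(mirnas, utrs, utr_strands, footprints, fp_host, pairs,
                   pathways)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _has_adjacent_repeat(s: str, left_ctx: str, right_ctx: str) -> bool:
    """Independent check: is s a whole number of copies of a unit that also
    occurs immediately adjacent (suffix of left_ctx or prefix of right_ctx)?"""
    n = len(s)
    for lu in range(1, n + 1):
        if n % lu:
            continue
        u = s[:lu]
        if u * (n // lu) != s:
            continue
        if right_ctx[:lu] == u or (len(left_ctx) >= lu and left_ctx[-lu:] == u):
            return True
    return False


class _VariantFactory:
    """Engineers variants whose indel class is fixed by construction."""

    def __init__(self, genome: bytearray, chrom: str,
                 rng: np.random.Generator):
        self.g = genome
        self.chrom = chrom
        self.rng = rng
        self.reserved = IntervalTree()
        self.counter = 0

    def seq(self, lo: int, hi: int) -> str:
        return self.g[max(0, lo): hi].decode("ascii")

    def free(self, lo: int, hi: int) -> bool:
        return not self.reserved.overlaps(lo, hi)

    def reserve(self, lo: int, hi: int) -> None:
        self.reserved.addi(lo, hi)

    def next_rsid(self) -> str:
        self.counter += 1
        return f"sv{self.counter:06d}"

    def _rand_base(self, not_base: str | None = None) -> str:
        while True:
            b = "ACGT"[int(self.rng.integers(4))]
            if b != not_base:
                return b

    def make_snv(self, a: int) -> Tuple[str, str]:
        ref = self.seq(a, a + 1)
        return ref, self._rand_base(not_base=ref)

    def make_single(self, a: int) -> Tuple[str, str]:
        if self.rng.random() < 0.5:
            ref = self.seq(a, a + 1)
            return ref, ref + self._rand_base()
        ref = self.seq(a, a + 2)
        return ref, ref[0]

    def make_repeat(self, a: int) -> Tuple[str, str]:
        """Repeat-expansion insertion: the unit is read off the reference
        immediately right of the anchor, so adjacency holds by construction."""
        lu = int(self.rng.integers(1, 3))            # unit length 1 or 2
        k = 2 if lu == 1 else int(self.rng.integers(1, 3))
        if lu * k < 2:
            k = 2
        u = self.seq(a + 1, a + 1 + lu)
        ref = self.seq(a, a + 1)
        return ref, ref + u * k

    def make_other(self, a: int) -> Optional[Tuple[str, str]]:
        for _ in range(50):
            length = int(self.rng.integers(2, 6))
            if self.rng.random() < 0.5:   # insertion of a constructed sequence
                s = "".join(self._rand_base() for _ in range(length))
                left = self.seq(a + 1 - length, a + 1)
                right = self.seq(a + 1, a + 1 + length)
                if not _has_adjacent_repeat(s, left, right):
                    ref = self.seq(a, a + 1)
                    return ref, ref + s
            else:                          # deletion of reference bases
                s = self.seq(a + 1, a + 1 + length)
                left = self.seq(a + 1 - length, a + 1)
                right = self.seq(a + 1 + length, a + 1 + 2 * length)
                if not _has_adjacent_repeat(s, left, right):
                    return self.seq(a, a + 1 + length), self.seq(a, a + 1)
        return None


def _verify_plant(seq: str, a: int, ref: str, alt: str, strand: str,
                  motif: str, status: str, hw: int = 50) -> bool:
    """Plain substring check that an engineered variant flips the presence
    of `motif` between the reference and mutant windows."""
    left = max(0, a - hw)
    right = min(len(seq), a + len(ref) + hw)
    refw = seq[left: right]
    mutw = seq[left: a] + alt + seq[a + len(ref): right]
    if strand == "-":
        refw, mutw = _rc(refw), _rc(mutw)
    if status == "disrupted":
        return motif in refw and motif not in mutw
    return motif in mutw and motif not in refw


_TRUTH_COLS = ["rsid", "chrom", "pos1", "ref", "alt", "kind", "region_label",
               "unit_id", "indel_class", "planted", "gene_id", "mirna",
               "seed_type", "expected_status"]


def gen_variants(cfg: GeneratorConfig, layout: _Layout,
                 genome: Dict[str, str]
                 ) -> Tuple[Dict[str, str], List[Variant], pd.DataFrame]:
    """Poisson-place variants per region at configured densities; engineer
    indel classes; plant seed-site impacts for a fraction of UTR/footprint
    indels.  Returns the (possibly motif-edited) genome, the variants and
    the truth table."""
    rng = np.random.default_rng(subseed(cfg.rng_seed, "variants"))
    chrom = cfg.chrom
    g = bytearray(genome[chrom], "ascii")
    fab = _VariantFactory(g, chrom, rng)
    dens = cfg.region_density_map
    rows: List[tuple] = []
    variants: List[Variant] = []

    catalog = {}
    for m in layout.mirnas:
        mat_name, iv = m.mature_intervals[0]
        dna = genome[chrom][iv.start: iv.end]
        if iv.strand == "-":
            dna = _rc(dna)
        catalog[mat_name] = dna.replace("T", "U")

    gene_pairs: Dict[str, List[str]] = {}
    for p in layout.pairs:
        gene_pairs.setdefault(p.gene_id, []).append(p.mirna_name)

    def sample_pos(intervals: Sequence[GenomicInterval]) -> Optional[int]:
        lens = np.array([iv.length() for iv in intervals], dtype=float)
        if lens.sum() <= 0:
            return None
        for _ in range(100):
            iv = intervals[int(rng.choice(len(intervals), p=lens / lens.sum()))]
            a = int(rng.integers(iv.start, iv.end))
            if a < 10 or a + 12 >= len(g):
                continue
            if fab.free(a - 1, a + 8):
                return a
        return None

    def add_variant(a: int, label: str, unit_id: str,
                    plant_ctx: Optional[dict] = None) -> None:
        rsid = fab.next_rsid()
        is_indel = rng.random() < cfg.indel_fraction
        if not is_indel:
            ref, alt = fab.make_snv(a)
            fab.reserve(a - 1, a + 2)
            v = Variant(chrom, a + 1, rsid, ref, alt)
            variants.append(v)
            rows.append((rsid, chrom, a + 1, ref, alt, v.kind, label, unit_id,
                         "", False, "", "", "", ""))
            return

        cls = ("single_base_pair", "repeat_expansion", "other")[
            int(rng.choice(3, p=cfg.indel_class_mix))]
        plant = (plant_ctx is not None and cls != "repeat_expansion"
                 and rng.random() < cfg.planted_site_fraction)
        if plant:
            planted = _plant_site(cfg, fab, rng, catalog, plant_ctx, cls, rsid)
            if planted is not None:
                variants.append(planted["variant"])
                rows.append(planted["row"])
                return
            # fall through to an ordinary indel if planting failed

        if cls == "single_base_pair":
            ref, alt = fab.make_single(a)
        elif cls == "repeat_expansion":
            ref, alt = fab.make_repeat(a)
        else:
            made = fab.make_other(a)
            if made is None:
                ref, alt = fab.make_single(a)
                cls = "single_base_pair"
            else:
                ref, alt = made
        fab.reserve(a - 1, a + len(ref) + max(len(ref), len(alt)) + 1)
        v = Variant(chrom, a + 1, rsid, ref, alt)
        variants.append(v)
        rows.append((rsid, chrom, a + 1, ref, alt, v.kind, label, unit_id,
                     cls, False, "", "", "", ""))

    def fill_region(intervals, density, label, unit_id, plant_ctx=None):
        intervals = [iv for iv in intervals if iv is not None]
        total = sum(iv.length() for iv in intervals)
        if total == 0 or density <= 0:
            return
        if density > 0.25:
            raise ValueError(f"density {density} too high for region {label}")
        n = rng.poisson(density * total)
        for _ in range(n):
            a = sample_pos(intervals)
            if a is not None:
                add_variant(a, label, unit_id, plant_ctx)

    # --- miRNA systems -----------------------------------------------------
    for m in layout.mirnas:
        sys_ = build_mirna_regions(m)
        for lbl in ("flank2_5p", "flank1_5p", "flank1_3p", "flank2_3p"):
            fill_region(sys_.regions[lbl], dens["flank"], lbl, m.name)
        mat = sys_.regions["mature"]
        seed_ivs = sys_.regions["seed"]
        pre = m.pre_interval
        # precursor outside the mature arm at "pre" density
        non_mature = []
        cur = pre.start
        for iv in sorted(mat, key=lambda x: x.start):
            if iv.start > cur:
                non_mature.append(GenomicInterval(chrom, cur, iv.start, pre.strand))
            cur = iv.end
        if cur < pre.end:
            non_mature.append(GenomicInterval(chrom, cur, pre.end, pre.strand))
        fill_region(non_mature, dens["pre"], "pre", m.name)
        # mature at suppressed density; deepest label wins (seed inside mature)
        mat_n_before = len(variants)
        fill_region(mat, dens["mature"], "mature", m.name)
        for i in range(mat_n_before, len(variants)):
            v = variants[i]
            if any(s.contains_point(v.anchor0) for s in seed_ivs):
                r = list(rows[i])
                r[6] = "seed"
                rows[i] = tuple(r)

    # --- UTRs and footprints ----------------------------------------------
    fp_zones: Dict[str, List[Tuple[int, int]]] = {}
    for fp in layout.footprints:
        gene = layout.fp_host[fp.footprint_id]
        L = fp.interval.length()
        fp_zones.setdefault(gene, []).append(
            (fp.interval.start - 2 * L, fp.interval.end + 2 * L))

    for gene, utr in layout.utrs.items():
        # background UTR intervals exclude footprint+flank zones
        zones = sorted(fp_zones.get(gene, []))
        bg = []
        cur = utr.start
        for lo, hi in zones:
            if lo > cur:
                bg.append(GenomicInterval(chrom, cur, min(lo, utr.end), utr.strand))
            cur = max(cur, hi)
        if cur < utr.end:
            bg.append(GenomicInterval(chrom, cur, utr.end, utr.strand))
        ctx = None
        if gene_pairs.get(gene):
            ctx = {"strand": utr.strand, "gene": gene, "unit": gene,
                   "mirnas": sorted(set(gene_pairs[gene])),
                   "site_intervals": bg, "label": "utr3"}
        fill_region(bg, dens["utr3"], "utr3", gene, ctx)

    all_mirnas = sorted(catalog)
    for fp in layout.footprints:
        gene = layout.fp_host[fp.footprint_id]
        sys_ = build_footprint_regions(fp)
        for lbl in ("flank2_left", "flank1_left", "flank1_right", "flank2_right"):
            fill_region(sys_.regions[lbl], dens["footprint_flank"], lbl,
                        fp.footprint_id)
        ctx = None
        if all_mirnas:
            ctx = {"strand": fp.interval.strand, "gene": gene,
                   "unit": fp.footprint_id, "mirnas": all_mirnas,
                   "site_intervals": [fp.interval], "label": "footprint"}
        fill_region([fp.interval], dens["footprint"], "footprint",
                    fp.footprint_id, ctx)

    genome_out = {chrom: g.decode("ascii")}
    order = np.argsort([v.pos1 for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    rows = [rows[i] for i in order]
    truth = pd.DataFrame(rows, columns=_TRUTH_COLS)
    return genome_out, variants, truth


def _plant_site(cfg: GeneratorConfig, fab: _VariantFactory,
                rng: np.random.Generator, catalog: Mapping[str, str],
                ctx: dict, cls: str, rsid: str) -> Optional[dict]:
    """Write a seed-site motif into the genome and engineer an indel that
    disrupts (or, for single-bp insertions, creates) it.  Returns None if a
    verified construction could not be found."""
    chrom = fab.chrom
    strand = ctx["strand"]
    mirnas = ctx["mirnas"]
    status = "created" if (cls == "single_base_pair"
                           and rng.random() < cfg.created_fraction) else "disrupted"
    for _ in range(12):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        motifs = seed_motifs(catalog[mirna], DEFAULT_SEED_TYPES)
        st_names = sorted(motifs)
        st = st_names[int(rng.integers(len(st_names)))]
        motif = motifs[st]
        n = len(motif)
        planted_len = n - 1 if status == "created" else n
        site = _sample_site(fab, rng, ctx["site_intervals"], planted_len)
        if site is None:
            continue
        if status == "created":
            t = int(rng.integers(1, n - 1))
            gap_seq = motif[:t] + motif[t + 1:]
            seq = gap_seq if strand == "+" else _rc(gap_seq)
            fab.g[site: site + planted_len] = seq.encode("ascii")
            if strand == "+":
                a = site + t - 1
                ins = motif[t]
            else:
                a = site + (planted_len - 1) - t
                ins = _rc(motif[t])
            ref = fab.seq(a, a + 1)
            alt = ref + ins
            if _verify_plant(fab.g.decode("ascii"), a, ref, alt, strand,
                             motif, "created"):
                return _finish_plant(fab, ctx, rsid, chrom, a, ref, alt, cls,
                                     mirna, st, status, site, planted_len)
            continue
        # disrupted
        seq = motif if strand == "+" else _rc(motif)
        fab.g[site: site + n] = seq.encode("ascii")
        made = _disrupting_indel(fab, rng, site, n, strand, motif, cls)
        if made is None:
            continue
        a, ref, alt = made
        return _finish_plant(fab, ctx, rsid, chrom, a, ref, alt, cls, mirna,
                             st, status, site, n)
    return None


def _sample_site(fab: _VariantFactory, rng: np.random.Generator,
                 intervals: Sequence[GenomicInterval], length: int
                 ) -> Optional[int]:
    candidates = [iv for iv in intervals if iv.length() >= length + 4]
    if not candidates:
        return None
    lens = np.array([iv.length() for iv in candidates], dtype=float)
    for _ in range(50):
        iv = candidates[int(rng.choice(len(candidates), p=lens / lens.sum()))]
        s = int(rng.integers(iv.start + 2, iv.end - length - 1))
        if s < 10 or s + length + 10 >= len(fab.g):
            continue
        if fab.free(s - 2, s + length + 2):
            return s
    return None


def _disrupting_indel(fab: _VariantFactory, rng: np.random.Generator,
                      site: int, n: int, strand: str, motif: str, cls: str
                      ) -> Optional[Tuple[int, str, str]]:
    genome_str = fab.g.decode("ascii")
    for _ in range(20):
        if cls == "single_base_pair":
            if rng.random() < 0.5:   # delete one motif-internal base
                t = int(rng.integers(1, n - 1))
                a = site + t - 1
                ref, alt = genome_str[a: a + 2], genome_str[a]
            else:                    # insert a base inside the motif
                t = int(rng.integers(1, n - 1))
                a = site + t - 1
                ins = "ACGT"[int(rng.integers(4))]
                ref = genome_str[a]
                alt = ref + ins
        else:  # "other": delete several motif bases, non-repeat-decomposable
            length = int(rng.integers(2, min(5, n - 1)))
            t = int(rng.integers(1, n - length))
            a = site + t - 1
            s = genome_str[a + 1: a + 1 + length]
            left = genome_str[a + 1 - length: a + 1]
            right = genome_str[a + 1 + length: a + 1 + 2 * length]
            if _has_adjacent_repeat(s, left, right):
                continue
            ref, alt = genome_str[a: a + 1 + length], genome_str[a]
        if _verify_plant(genome_str, a, ref, alt, strand, motif, "disrupted"):
            return a, ref, alt
    return None


def _finish_plant(fab: _VariantFactory, ctx: dict, rsid: str, chrom: str,
                  a: int, ref: str, alt: str, cls: str, mirna: str, st: str,
                  status: str, site: int, site_len: int) -> dict:
    fab.reserve(site - 2, site + site_len + 2)
    fab.reserve(a - 1, a + len(ref) + 1)
    v = Variant(chrom, a + 1, rsid, ref, alt)
    row = (rsid, chrom, a + 1, ref, alt, v.kind, ctx["label"], ctx["unit"],
           cls, True, ctx["gene"], mirna, st, status)
    return {"variant": v, "row": row}


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def gen_panel(cfg: GeneratorConfig, anchor_chrom: str, anchor_pos1: int,
              indel_rsid: str
              ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Block-structured genotype panel plus GWAS marker table and truth.

    Block 0 is centred on the given indel (which becomes one of its
    markers); each block has two complementary founder haplotypes
    (within-block |D'| = 1) recombining freely between blocks.
    """
    pc = cfg.panel
    rng = np.random.default_rng(subseed(cfg.rng_seed, "panel"))
    m = pc.markers_per_block
    i0 = m // 2
    positions: List[int] = []
    rsids: List[str] = []
    block_ids: List[int] = []
    start0 = anchor_pos1 - i0 * pc.marker_spacing
    if start0 < 1:
        start0 = 1
        anchor_pos1 = start0 + i0 * pc.marker_spacing
    for b in range(pc.n_blocks):
        base = start0 + b * (m * pc.marker_spacing + pc.block_gap)
        for i in range(m):
            positions.append(base + i * pc.marker_spacing)
            if b == 0 and i == i0:
                rsids.append(indel_rsid)
            else:
                rsids.append(f"pm{b}_{i:02d}")
            block_ids.append(b)

    n_markers = len(positions)
    geno = np.zeros((n_markers, pc.n_individuals), dtype=int)
    lo, hi = pc.founder_freq_range
    for b in range(pc.n_blocks):
        idx = [k for k in range(n_markers) if block_ids[k] == b]
        h0 = rng.integers(0, 2, size=len(idx))
        h1 = 1 - h0
        f = rng.uniform(lo, hi)
        choice = rng.random((2, pc.n_individuals)) < f   # founder 0 w.p. f
        for hap in range(2):
            hapmat = np.where(choice[hap][None, :], h0[:, None], h1[:, None])
            geno[idx, :] += hapmat
    cols = {"rsid": rsids, "chrom": [anchor_chrom] * n_markers,
            "pos": positions}
    for j in range(pc.n_individuals):
        cols[f"ind{j:03d}"] = geno[:, j]
    panel = pd.DataFrame(cols)

    gwas_idx0 = next(k for k in range(n_markers)
                     if block_ids[k] == 0 and rsids[k] != indel_rsid)
    gwas_rows = [(anchor_chrom, positions[gwas_idx0], rsids[gwas_idx0],
                  1e-8, "synthetic trait A")]
    if pc.n_blocks > 1:
        k1 = next(k for k in range(n_markers) if block_ids[k] == 1)
        gwas_rows.append((anchor_chrom, positions[k1], rsids[k1], 5e-7,
                          "synthetic trait B"))
    gwas = pd.DataFrame(gwas_rows, columns=["chrom", "pos", "rsid", "p",
                                            "trait"])
    panel_truth = pd.DataFrame({"rsid": rsids, "pos": positions,
                                "block": block_ids})
    return panel, gwas, panel_truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def generate(cfg: GeneratorConfig) -> Bundle:
    """Run every generator stage and return the in-memory bundle."""
    genome = gen_genome(cfg)
    layout = gen_annotations(cfg)
    genome, variants, truth = gen_variants(cfg, layout, genome)
    catalog = {}
    for m in layout.mirnas:
        mat_name, iv = m.mature_intervals[0]
        dna = genome[cfg.chrom][iv.start: iv.end]
        if iv.strand == "-":
            dna = _rc(dna)
        catalog[mat_name] = dna.replace("T", "U")

    panel = gwas = panel_truth = None
    if cfg.make_panel:
        anchor = _panel_anchor(layout, variants, truth)
        panel, gwas, panel_truth = gen_panel(cfg, cfg.chrom, anchor[0],
                                             anchor[1])
    return Bundle(cfg, genome, layout.mirnas, catalog, layout.utrs,
                  layout.footprints, layout.pairs, layout.pathways,
                  variants, truth, panel, gwas, panel_truth)


def _panel_anchor(layout: _Layout, variants: List[Variant],
                  truth: pd.DataFrame) -> Tuple[int, str]:
    """(pos1, rsid) of the indel the panel's first LD block is built around:
    prefer a planted UTR/footprint indel, then any miRNA indel."""
    planted = truth[truth["planted"] == True]  # noqa: E712
    if len(planted):
        r = planted.iloc[0]
        return int(r["pos1"]), str(r["rsid"])
    mirna_indels = truth[(truth["kind"].isin(["insertion", "deletion"]))
                         & truth["region_label"].isin(["pre", "mature", "seed"])]
    if len(mirna_indels):
        r = mirna_indels.iloc[0]
        return int(r["pos1"]), str(r["rsid"])
    return 100_000, "sv_panel_anchor"


def write_bundle(bundle: Bundle, outdir) -> Dict[str, str]:
    """Write every input file the pipeline consumes plus a truth/ directory;
    returns {logical name: path}."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    files: Dict[str, str] = {}

    def reg(key: str, name: str) -> Path:
        files[key] = str(outdir / name)
        return outdir / name

    mio.write_fasta(reg("genome", "genome.fa"), bundle.genome)
    mio.write_mirna_gff(reg("mirna_gff", "mirna.gff3"), bundle.mirnas)
    mio.write_fasta(reg("mature_fasta", "mature.fa"), bundle.catalog)
    mio.write_bed(reg("utr_bed", "utr3.bed"),
                  sorted(bundle.utrs.items(), key=lambda kv: kv[1].start))
    mio.write_bed(reg("footprint_bed", "footprints.bed"),
                  [(f.footprint_id, f.interval) for f in bundle.footprints])
    mio.write_tsv(reg("pairs", "pairs.tsv"),
                  pd.DataFrame([(p.gene_id, p.mirna_name, p.evidence_source)
                                for p in bundle.pairs],
                               columns=["gene_id", "mirna", "source"]),
                  ["experimentally supported mRNA:miRNA pairs (synthetic)"])
    mio.write_tsv(reg("pathways", "pathways.tsv"), bundle.pathways,
                  ["pathway membership: pathway_id, pathway_name, gene_id"])
    mio.write_vcf_min(reg("vcf", "variants.vcf"), bundle.variants)
    mio.write_tsv(reg("truth_variants", "truth/variants.tsv"), bundle.truth,
                  ["generator truth: one row per variant"])
    if bundle.panel is not None:
        mio.write_tsv(reg("panel", "panel.tsv"), bundle.panel,
                      ["genotype panel: rsid, chrom, pos, then 0/1/2 per individual"])
        mio.write_tsv(reg("gwas", "gwas_markers.tsv"), bundle.gwas,
                      ["GWAS markers: chrom, pos (1-based), rsid, p, trait"])
        mio.write_tsv(reg("truth_panel", "truth/panel_blocks.tsv"),
                      bundle.panel_truth, ["true LD-block membership"])
    with open(reg("config", "config.yaml"), "w") as fh:
        yaml.safe_dump(bundle.cfg.to_dict(), fh, sort_keys=True)
    return files
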