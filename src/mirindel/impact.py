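"""Impact-analysis orchestration and pathway summarisation.

Two scans mirror the two experimental evidence sources:

* ``footprint_impact`` — every variant anchored inside an Argonaute
  crosslinking footprint is diffed against the seed motifs of *every*
  miRNA in the catalog (footprints evidence binding but not which site).
* ``pair_impact`` — variants in the 3' UTR of a gene with experimentally
  supported miRNA partners are diffed against *only* those partners'
  motifs.

``pathway_table`` counts, per pathway, the member genes whose UTR variants
produced at least one impact call, separately for indels and SNVs sharing
the pathway's gene denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .model import FootprintRecord, GenomicInterval, TargetPair, Variant
from .seeds import DEFAULT_SEED_TYPES, Motif, call_impacts, catalog_motifs, seed_motifs

logger = logging.getLogger(__name__)

IMPACT_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "unit_id", "gene_id",
                  "mirna", "seed_type", "status", "genomic_site_start",
                  "provenance"]


def _interval_trees(items: Iterable[Tuple[str, GenomicInterval]]
                    ) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for name, iv in items:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (name, iv))
    return trees


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=IMPACT_COLUMNS)


def _sort_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    return df.sort_values(
        ["chrom", "pos", "rsid", "mirna", "seed_type", "status"]
    ).reset_index(drop=True)


def footprint_impact(variants: Sequence[Variant],
                     footprints: Sequence[FootprintRecord],
                     mirna_catalog: Mapping[str, str],
                     genome: Mapping[str, str],
                     half_width: int = 50,
                     seed_types=DEFAULT_SEED_TYPES,
                     utrs: Mapping[str, GenomicInterval] | None = None
                     ) -> pd.DataFrame:
    """Scan every variant anchored in a footprint against all miRNAs.

    ``utrs`` (optional) maps footprints to their host gene for downstream
    gene-level counting.
    """
    motifs = catalog_motifs(mirna_catalog, seed_types)
    fp_trees = _interval_trees((f.footprint_id, f.interval) for f in footprints)
    utr_trees = _interval_trees(utrs.items()) if utrs else {}
    rows = []
    for v in variants:
        tree = fp_trees.get(v.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[v.anchor0]):
            fp_id, fp_iv = hit.data
            gene_id = ""
            utr_tree = utr_trees.get(v.chrom)
            if utr_tree is not None:
                genes = sorted(h.data[0] for h in utr_tree[v.anchor0])
                gene_id = genes[0] if genes else ""
            for call in call_impacts(genome, v, motifs, half_width, fp_iv.strand):
                rows.append((v.rsid, v.chrom, v.pos1, v.ref, v.alt, fp_id,
                             gene_id, call.mirna_name, call.seed_type,
                             call.status, call.genomic_site_start,
                             "footprint_scan"))
    if not rows:
        return _empty_table()
    return _sort_table(pd.DataFrame(rows, columns=IMPACT_COLUMNS))


def pair_impact(variants: Sequence[Variant],
                utr3_annotations: Mapping[str, GenomicInterval],
                pairs: Sequence[TargetPair],
                mirna_catalog: Mapping[str, str],
                genome: Mapping[str, str],
                half_width: int = 50,
                seed_types=DEFAULT_SEED_TYPES) -> pd.DataFrame:
    """Scan UTR variants of paired genes against their paired miRNAs only."""
    gene_mirnas: Dict[str, List[str]] = {}
    for p in pairs:
        if p.gene_id not in utr3_annotations:
            logger.warning("pair (%s, %s) skipped: gene has no UTR annotation",
                           p.gene_id, p.mirna_name)
            continue
        if p.mirna_name not in mirna_catalog:
            logger.warning("pair (%s, %s) skipped: unknown miRNA",
                           p.gene_id, p.mirna_name)
            continue
        gene_mirnas.setdefault(p.gene_id, [])
        if p.mirna_name not in gene_mirnas[p.gene_id]:
            gene_mirnas[p.gene_id].append(p.mirna_name)

    utr_trees = _interval_trees(
        (g, iv) for g, iv in utr3_annotations.items() if g in gene_mirnas
    )
    rows = []
    for v in variants:
        tree = utr_trees.get(v.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[v.anchor0]):
            gene_id, utr_iv = hit.data
            motifs = catalog_motifs(
                {m: mirna_catalog[m] for m in gene_mirnas[gene_id]}, seed_types
            )
            for call in call_impacts(genome, v, motifs, half_width, utr_iv.strand):
                rows.append((v.rsid, v.chrom, v.pos1, v.ref, v.alt, gene_id,
                             gene_id, call.mirna_name, call.seed_type,
                             call.status, call.genomic_site_start, "pair_scan"))
    if not rows:
        return _empty_table()
    return _sort_table(pd.DataFrame(rows, columns=IMPACT_COLUMNS))


def flagged_genes(impact_table: pd.DataFrame) -> Set[str]:
    """Genes with at least one impact call (gene_id column, blanks dropped)."""
    if impact_table.empty:
        return set()
    genes = set(impact_table["gene_id"].astype(str))
    return {g for g in genes if g}


def _pct(n: int, d: int) -> float:
    """100*n/d rounded half-up to 2 decimals."""
    if d == 0:
        return 0.0
    return float(
        (Decimal(100 * n) / Decimal(d)).quantize(Decimal("0.01"),
                                                 rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class PathwayRow:
    pathway_id: str
    pathway_name: str
    n_pathway_genes: int
    n_genes_with_indel_impacts: int
    pct_indel: float
    n_genes_with_snp_impacts: int
    pct_snp: float


def pathway_table(impact_genes_indel: Set[str], impact_genes_snp: Set[str],
                  membership: pd.DataFrame, min_genes: int = 10
                  ) -> List[PathwayRow]:
    """Per-pathway counts of genes whose supported target sites carry
    impact-producing indels/SNVs; pathways with fewer than ``min_genes``
    indel-flagged genes are dropped; sorted by that count, descending."""
    rows: List[PathwayRow] = []
    if membership.empty:
        return rows
    for (pid, pname), grp in membership.groupby(["pathway_id", "pathway_name"],
                                                sort=True):
        genes = set(grp["gene_id"])
        n_indel = len(genes & impact_genes_indel)
        n_snp = len(genes & impact_genes_snp)
        if n_indel < min_genes:
            continue
        rows.append(PathwayRow(pid, pname, len(genes), n_indel,
                               _pct(n_indel, len(genes)), n_snp,
                               _pct(n_snp, len(genes))))
    rows.sort(key=lambda r: (-r.n_genes_with_indel_impacts, r.pathway_id))
    return rows


def pathway_table_df(rows: Sequence[PathwayRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway_id, r.pathway_name, r.n_pathway_genes,
          r.n_genes_with_indel_impacts, r.pct_indel,
          r.n_genes_with_snp_impacts, r.pct_snp) for r in rows],
        columns=["pathway_id", "pathway_name", "n_pathway_genes",
                 "n_genes_with_indels", "pct_genes_with_indels",
                 "n_genes_with_snps", "pct_genes_with_snps"],
    )
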