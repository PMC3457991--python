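"""End-to-end pipeline runs over files on disk.

Each function reads the inputs named in a :class:`RunConfig`, executes one
analysis stage and writes deterministic, sorted TSV outputs with a
commented header carrying the tool version and config hash.  The CLI in
:mod:`mirindel.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__, io as mio
from .config import RunConfig
from .impact import (flagged_genes, footprint_impact, pair_impact,
                     pathway_table, pathway_table_df)
from .ld import link_indels, links_df, panel_markers
from .model import Variant
from .regions import (FOOTPRINT_FLANK_LABELS, MIRNA_FLANK_LABELS,
                      build_footprint_regions, build_mirna_regions, compare,
                      density_by_label, summarize)

logger = logging.getLogger(__name__)

MIRNA_COMPARISONS = [("pre", "mature"), ("pre", "seed"), ("pre", "flank_avg"),
                     ("mature", "flank_avg"), ("seed", "flank_avg")]
FOOTPRINT_COMPARISONS = [("footprint", "flank_avg"),
                         ("footprint", "flank1_left"),
                         ("footprint", "flank1_right")]


def _header(cfg: RunConfig, semantics: str) -> List[str]:
    return [f"mirindel {__version__} config={cfg.config_hash()[:12]}",
            semantics]


def _load_common(cfg: RunConfig):
    genome = mio.read_fasta(cfg.input_path("genome"))
    mature = mio.read_rna_fasta(cfg.input_path("mature_fasta"))
    mirnas = mio.read_mirna_gff(cfg.input_path("mirna_gff"), mature)
    variants = mio.read_vcf_min(cfg.input_path("vcf"))
    return genome, mature, mirnas, variants


def _subsets(cfg: RunConfig, variants: Sequence[Variant]
             ) -> List[Tuple[str, List[Variant]]]:
    out = []
    if cfg.variant_subset in ("all", "both"):
        out.append(("all", list(variants)))
    if cfg.variant_subset in ("indels_only", "both"):
        out.append(("indels", [v for v in variants if v.is_indel]))
    return out


def run_density(cfg: RunConfig, outdir: Path) -> Dict[str, pd.DataFrame]:
    """Per-region density summaries and Welch comparisons for the miRNA and
    footprint region systems, for all variants and for indels only."""
    genome, _, mirnas, variants = _load_common(cfg)
    footprints = mio.read_footprints(cfg.input_path("footprint_bed"))
    if not variants:
        raise ValueError("variant file is empty; density summaries refused")
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    mirna_systems = [build_mirna_regions(m, cfg.seed_span,
                                         chrom_lengths.get(m.pre_interval.chrom))
                     for m in mirnas]
    fp_systems = [build_footprint_regions(f,
                                          chrom_lengths.get(f.interval.chrom))
                  for f in footprints]

    results: Dict[str, pd.DataFrame] = {}
    for subset_name, subset in _subsets(cfg, variants):
        for system_name, systems, flank_labels, comparisons in (
                ("mirna", mirna_systems, MIRNA_FLANK_LABELS, MIRNA_COMPARISONS),
                ("footprint", fp_systems, FOOTPRINT_FLANK_LABELS,
                 FOOTPRINT_COMPARISONS)):
            if not systems:
                continue
            dens = density_by_label(systems, subset, flank_labels)
            summaries = [summarize(lbl, vals)
                         for lbl, vals in sorted(dens.items())]
            sdf = pd.DataFrame(
                [(s.label, s.n_units, s.mean_density, s.sem)
                 for s in summaries],
                columns=["label", "n_units", "mean_density", "sem"])
            rows = []
            for a, b in comparisons:
                if a in dens and b in dens and len(dens[a]) >= 2 \
                        and len(dens[b]) >= 2:
                    c = compare(a, dens[a], b, dens[b])
                    rows.append((c.label_a, c.label_b, c.t_stat, c.df,
                                 c.p_value))
            cdf = pd.DataFrame(rows, columns=["label_a", "label_b", "t",
                                              "df", "p"])
            results[f"density_{system_name}_{subset_name}"] = sdf
            results[f"compare_{system_name}_{subset_name}"] = cdf
            mio.write_tsv(outdir / f"density_{system_name}_{subset_name}.tsv",
                          sdf, _header(cfg, "label, n_units, mean variant "
                                            "density (per nt), standard error"))
            mio.write_tsv(outdir / f"compare_{system_name}_{subset_name}.tsv",
                          cdf, _header(cfg, "Welch two-sided t-test between "
                                            "per-unit density groups"))
    return results


def run_impact(cfg: RunConfig, outdir: Path) -> Dict[str, pd.DataFrame]:
    """Footprint and pair seed-impact scans plus the pathway summary."""
    genome, mature, mirnas, variants = _load_common(cfg)
    footprints = mio.read_footprints(cfg.input_path("footprint_bed"))
    utrs = mio.read_utr_bed(cfg.input_path("utr_bed"))
    pairs = mio.read_pairs(cfg.input_path("pairs"))
    membership = mio.read_pathways(cfg.input_path("pathways"))

    indels = [v for v in variants if v.is_indel]
    snvs = [v for v in variants if v.kind == "snv"]

    tables: Dict[str, pd.DataFrame] = {}
    fp_indel = footprint_impact(indels, footprints, mature, genome,
                                cfg.half_width, utrs=utrs)
    pair_indel = pair_impact(indels, utrs, pairs, mature, genome,
                             cfg.half_width)
    # SNVs reuse the identical scan machinery
    fp_snv = footprint_impact(snvs, footprints, mature, genome,
                              cfg.half_width, utrs=utrs)
    pair_snv = pair_impact(snvs, utrs, pairs, mature, genome, cfg.half_width)

    genes_indel = flagged_genes(fp_indel) | flagged_genes(pair_indel)
    genes_snv = flagged_genes(fp_snv) | flagged_genes(pair_snv)
    pw = pathway_table_df(pathway_table(genes_indel, genes_snv, membership,
                                        cfg.min_genes))

    tables["impacts_footprint"] = pd.concat([fp_indel, fp_snv],
                                            ignore_index=True)
    tables["impacts_pairs"] = pd.concat([pair_indel, pair_snv],
                                        ignore_index=True)
    tables["pathway_summary"] = pw
    mio.write_tsv(outdir / "impacts_footprint.tsv",
                  tables["impacts_footprint"],
                  _header(cfg, "seed sites disrupted/created by variants "
                               "inside crosslink footprints (all miRNAs)"))
    mio.write_tsv(outdir / "impacts_pairs.tsv", tables["impacts_pairs"],
                  _header(cfg, "seed sites disrupted/created in UTRs of "
                               "supported pairs (paired miRNAs only)"))
    mio.write_tsv(outdir / "pathway_summary.tsv", pw,
                  _header(cfg, "per pathway: member genes and genes with "
                               "indel/SNV-impacted supported target sites; "
                               "percentages share the pathway denominator"))
    logger.info("impact: %d footprint rows, %d pair rows, %d pathways",
                len(tables["impacts_footprint"]), len(tables["impacts_pairs"]),
                len(pw))
    return tables


def _mirna_indel_candidates(mirnas, variants) -> List[dict]:
    out = []
    for v in variants:
        if not v.is_indel:
            continue
        for m in mirnas:
            iv = m.pre_interval
            if v.chrom == iv.chrom and iv.contains_point(v.anchor0):
                out.append({"rsid": v.rsid, "chrom": v.chrom, "pos1": v.pos1,
                            "linked_name": m.name})
    return out


def run_link(cfg: RunConfig, outdir: Path,
             impact_tables: Optional[Dict[str, pd.DataFrame]] = None
             ) -> pd.DataFrame:
    """Link indels in miRNAs or supported target sites to GWAS markers
    through shared LD blocks called on the genotype panel."""
    genome, mature, mirnas, variants = _load_common(cfg)
    gwas = mio.read_gwas_markers(cfg.input_path("gwas"))
    panel = panel_markers(mio.read_panel(cfg.input_path("panel")))

    if impact_tables is None:
        impact_tables = run_impact(cfg, outdir)
    candidates: List[dict] = []
    seen = set()
    for key in ("impacts_footprint", "impacts_pairs"):
        df = impact_tables[key]
        for row in df.itertuples(index=False):
            v_kind = Variant(row.chrom, int(row.pos), row.rsid, row.ref,
                             row.alt).kind
            if v_kind not in ("insertion", "deletion"):
                continue
            linked = row.mirna
            k = (row.rsid, linked)
            if k not in seen:
                seen.add(k)
                candidates.append({"rsid": row.rsid, "chrom": row.chrom,
                                   "pos1": int(row.pos), "linked_name": linked})
    for rec in _mirna_indel_candidates(mirnas, variants):
        k = (rec["rsid"], rec["linked_name"])
        if k not in seen:
            seen.add(k)
            candidates.append(rec)
    candidates.sort(key=lambda r: (r["chrom"], r["pos1"], r["rsid"],
                                   r["linked_name"]))
    links = link_indels(candidates, gwas, panel, cfg.ld_window, cfg.ld)
    df = links_df(links)
    mio.write_tsv(outdir / "links.tsv", df,
                  _header(cfg, "indel, location, miRNA-or-gene, GWAS marker "
                               "(rsid, p, pos), LD block left/right, trait"))
    return df


def write_manifest(outdir: Path, cfg: RunConfig, command: str,
                   files: Sequence[str]) -> Path:
    """Machine-readable run manifest with checksums of every output."""
    entries = {}
    for f in sorted(files):
        p = Path(f)
        if p.exists():
            entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"tool": "mirindel", "version": __version__,
                "command": command, "config_hash": cfg.config_hash(),
                "files": entries}
    path = outdir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
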