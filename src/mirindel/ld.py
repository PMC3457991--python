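"""Pairwise linkage disequilibrium, confidence-interval LD blocks, and
linking of miRNA-related indels to GWAS markers.

The block caller reimplements the Gabriel et al. confidence-interval rule:
for each marker pair, haplotype frequencies are estimated by a two-locus
EM, |D'| is computed at the maximum-likelihood solution, and a one-sided
95% interval (cl, cu) for |D'| is read off a normalised likelihood grid.
A pair is *strong LD* when cl >= 0.7 and cu >= 0.98 and shows *strong
recombination* when cu < 0.9.  A candidate marker run qualifies as a block
when its end pair is strong LD and at least 95% of its informative
internal pairs are strong LD; non-overlapping qualifying runs are chosen
greedily, largest genomic span first.  Markers with minor allele frequency
below 0.05 are excluded before block calling.

The extra distance-dependent rules some implementations apply to 2- and
3-marker blocks are intentionally not replicated; only the four stated
thresholds are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LdUndefinedError(ValueError):
    """Raised when LD is undefined for a pair (monomorphic/degenerate)."""


@dataclass(frozen=True)
class Marker:
    """A biallelic marker with 0/1/2 genotypes (NaN = missing)."""

    rsid: str
    chrom: str
    pos1: int
    genotypes: np.ndarray = field(repr=False)

    def maf(self) -> float:
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size == 0:
            return 0.0
        p = float(g.sum()) / (2 * g.size)
        return min(p, 1 - p)


@dataclass(frozen=True)
class PairLd:
    marker_a: str
    marker_b: str
    d_prime: float
    cl: float
    cu: float


@dataclass(frozen=True)
class LdBlock:
    chrom: str
    left_pos1: int
    right_pos1: int
    member_markers: Tuple[str, ...]


@dataclass(frozen=True)
class LinkRecord:
    indel_rsid: str
    indel_chrom: str
    indel_pos1: int
    linked_name: str        # miRNA or target gene the indel affects
    marker_rsid: str
    marker_pos1: int
    marker_p: float
    block_left: int
    block_right: int
    trait: str


# ---------------------------------------------------------------------------
# Two-locus EM
# ---------------------------------------------------------------------------

def _genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 table of two-locus genotype counts; missing dropped pairwise."""
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep].astype(int), gb[keep].astype(int)
    n = np.zeros((3, 3), dtype=float)
    for i, j in zip(ga, gb):
        n[i, j] += 1
    return n


def em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray,
                       tol: float = 1e-9, max_iter: int = 1000
                       ) -> Tuple[float, float, float, float]:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Returns (p11, p10, p01, p00) where the first index is the allele at
    marker a and the second at marker b.  Only double heterozygotes carry
    phase ambiguity; everything else is counted directly.
    """
    n = _genotype_counts(ga, gb)
    N = n.sum()
    if N < 2:
        raise LdUndefinedError("need >=2 informative individuals")
    pa = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * N)
    pb = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * N)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise LdUndefinedError("monomorphic marker")

    c11 = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    c10 = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    c01 = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    c00 = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    ndh = n[1, 1]
    total = 2.0 * N

    p11, p10, p01, p00 = pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)
    for _ in range(max_iter):
        cis = p11 * p00
        trans = p10 * p01
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        e11 = (c11 + ndh * w) / total
        e00 = (c00 + ndh * w) / total
        e10 = (c10 + ndh * (1 - w)) / total
        e01 = (c01 + ndh * (1 - w)) / total
        delta = max(abs(e11 - p11), abs(e10 - p10), abs(e01 - p01), abs(e00 - p00))
        p11, p10, p01, p00 = e11, e10, e01, e00
        if delta < tol:
            break
    return p11, p10, p01, p00


def _hap_freqs_at_D(pa: float, pb: float, D: float) -> np.ndarray:
    eps = 1e-12
    h = np.array([
        [(1 - pa) * (1 - pb) + D, (1 - pa) * pb - D],
        [pa * (1 - pb) - D, pa * pb + D],
    ])
    return np.clip(h, eps, None)


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities from 2x2 haplotype frequencies under
    random union of haplotypes."""
    P = np.zeros((3, 3))
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    P[a1 + a2, b1 + b2] += h[a1, b1] * h[a2, b2]
    return P


def dprime_ci(ga: np.ndarray, gb: np.ndarray, rsid_a: str = "a",
              rsid_b: str = "b", grid_points: int = 101) -> PairLd:
    """|D'| at the EM solution plus a likelihood-grid confidence interval.

    Allele frequencies are fixed at their MLEs; the multinomial likelihood
    of the genotype table is evaluated on an evenly spaced |D'| grid in
    [0, 1] (sign taken from the point estimate), normalised, and the 5th /
    95th percentiles of its cumulative distribution give (cl, cu), with
    linear interpolation between grid points.
    """
    p11, p10, p01, p00 = em_haplotype_freqs(ga, gb)
    pa = p11 + p10
    pb = p11 + p01
    D = p11 - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    if dmax <= 1e-12:
        raise LdUndefinedError("degenerate allele frequencies")
    d_prime = abs(D) / dmax

    n = _genotype_counts(ga, gb)
    grid = np.linspace(0.0, 1.0, grid_points)
    ll = np.empty(grid_points)
    for k, d in enumerate(grid):
        h = _hap_freqs_at_D(pa, pb, sign * d * dmax)
        P = _genotype_probs(h)
        ll[k] = float((n * np.log(P)).sum())
    like = np.exp(ll - ll.max())
    cum = np.cumsum(like / like.sum())
    # discrete (ceiling) quantiles: the smallest grid value whose cumulative
    # mass reaches the percentile.  This keeps the MLE inside [cl, cu] even
    # when the likelihood concentrates at the |D'| = 1 boundary.
    cl = float(grid[min(int(np.searchsorted(cum, 0.05)), grid_points - 1)])
    cu = float(grid[min(int(np.searchsorted(cum, 0.95)), grid_points - 1)])
    return PairLd(rsid_a, rsid_b, float(min(d_prime, 1.0)), cl, cu)


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GabrielParams:
    ci_lower: float = 0.7      # strong LD needs cl >= ci_lower
    ci_upper: float = 0.98     # ... and cu >= ci_upper
    recomb_upper: float = 0.9  # strong recombination when cu < recomb_upper
    maf_min: float = 0.05
    strong_fraction: float = 0.95


def gabriel_blocks(markers: Sequence[Marker],
                   params: GabrielParams = GabrielParams()) -> List[LdBlock]:
    """Confidence-interval LD blocks over one chromosome's marker map."""
    if not markers:
        return []
    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError(f"markers span multiple chromosomes: {sorted(chroms)}")
    kept = [m for m in sorted(markers, key=lambda m: m.pos1)
            if m.maf() >= params.maf_min]
    n = len(kept)
    if n < 2:
        return []

    STRONG, RECOMB, OTHER = 1, -1, 0
    status = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pl = dprime_ci(kept[i].genotypes, kept[j].genotypes,
                               kept[i].rsid, kept[j].rsid)
            except LdUndefinedError:
                continue
            if pl.cl >= params.ci_lower and pl.cu >= params.ci_upper:
                status[i, j] = STRONG
            elif pl.cu < params.recomb_upper:
                status[i, j] = RECOMB

    candidates: List[Tuple[int, int, int]] = []  # (span_bp, i, j)
    for i in range(n):
        for j in range(i + 1, n):
            if status[i, j] != STRONG:
                continue
            sub = status[i: j + 1, i: j + 1]
            n_strong = int((sub == STRONG).sum())
            n_inform = n_strong + int((sub == RECOMB).sum())
            if n_inform == 0:
                continue
            if n_strong / n_inform >= params.strong_fraction:
                candidates.append((kept[j].pos1 - kept[i].pos1, i, j))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    used = np.zeros(n, dtype=bool)
    blocks: List[LdBlock] = []
    for _, i, j in candidates:
        if used[i: j + 1].any():
            continue
        used[i: j + 1] = True
        blocks.append(LdBlock(kept[i].chrom, kept[i].pos1, kept[j].pos1,
                              tuple(m.rsid for m in kept[i: j + 1])))
    blocks.sort(key=lambda b: b.left_pos1)
    return blocks


# ---------------------------------------------------------------------------
# Linking indels to GWAS markers
# ---------------------------------------------------------------------------

def panel_markers(panel: pd.DataFrame) -> List[Marker]:
    """Convert a genotype-panel DataFrame (rsid, chrom, pos, individuals...)
    into Marker objects."""
    geno_cols = [c for c in panel.columns if c not in ("rsid", "chrom", "pos")]
    return [
        Marker(row.rsid, row.chrom, int(row.pos),
               np.asarray([getattr(row, c) for c in geno_cols], dtype=float))
        for row in panel.itertuples(index=False)
    ]


def link_indels(indel_records: Sequence[Mapping],
                gwas_markers: pd.DataFrame,
                panel: Sequence[Marker],
                window: int = 100_000,
                params: GabrielParams = GabrielParams()) -> List[LinkRecord]:
    """Link miRNA-related indels to GWAS markers through shared LD blocks.

    ``indel_records`` are dicts with keys rsid, chrom, pos1, linked_name.
    For every (indel, marker) pair within ``window`` bp whose rsids both
    appear in the genotype panel, blocks are called on the surrounding
    panel markers; a LinkRecord is emitted iff both fall inside one block.
    """
    by_rsid: Dict[str, Marker] = {m.rsid: m for m in panel}
    by_chrom: Dict[str, List[Marker]] = {}
    for m in panel:
        by_chrom.setdefault(m.chrom, []).append(m)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: m.pos1)

    links: List[LinkRecord] = []
    seen = set()
    for rec in indel_records:
        indel = by_rsid.get(rec["rsid"])
        if indel is None:
            logger.warning("indel %s not in genotype panel; skipped", rec["rsid"])
            continue
        for g in gwas_markers.itertuples(index=False):
            if g.chrom != rec["chrom"]:
                continue
            if abs(int(g.pos) - int(rec["pos1"])) > window:
                continue
            marker = by_rsid.get(g.rsid)
            if marker is None:
                logger.warning("GWAS marker %s not in genotype panel; skipped",
                               g.rsid)
                continue
            key = (rec["rsid"], rec["linked_name"], g.rsid)
            if key in seen:
                continue
            lo = min(indel.pos1, marker.pos1) - window
            hi = max(indel.pos1, marker.pos1) + window
            local = [m for m in by_chrom[indel.chrom] if lo <= m.pos1 <= hi]
            for block in gabriel_blocks(local, params):
                if indel.rsid in block.member_markers and \
                        marker.rsid in block.member_markers:
                    links.append(LinkRecord(
                        rec["rsid"], rec["chrom"], int(rec["pos1"]),
                        rec["linked_name"], g.rsid, int(g.pos), float(g.p),
                        block.left_pos1, block.right_pos1, g.trait))
                    seen.add(key)
                    break
    links.sort(key=lambda r: (r.indel_chrom, r.indel_pos1, r.marker_rsid))
    return links


def links_df(links: Sequence[LinkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.indel_rsid, f"{r.indel_chrom}:{r.indel_pos1}", r.linked_name,
          r.marker_rsid, r.marker_p, r.marker_pos1, r.block_left,
          r.block_right, r.trait) for r in links],
        columns=["indel", "location", "mirna_or_gene", "marker", "marker_p",
                 "marker_pos", "block_left", "block_right", "trait"],
    )
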