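"""Region systems around miRNAs and footprints; variant densities and tests.

Each miRNA precursor (or footprint) defines a *region system*: the core
region plus two successive flanking windows on each side, every flank the
same length as the core.  Densities (variants per nt) are computed per
unit — one miRNA or one footprint — then summarised across units with a
mean and standard error, which is what bar-chart error bars require.
Two-group comparisons use Welch's unequal-variance two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import FootprintRecord, GenomicInterval, MirnaAnnotation, Variant

MIRNA_LABELS = ("flank2_5p", "flank1_5p", "pre", "mature", "seed",
                "flank1_3p", "flank2_3p")
FOOTPRINT_LABELS = ("flank2_left", "flank1_left", "footprint",
                    "flank1_right", "flank2_right")
MIRNA_FLANK_LABELS = ("flank2_5p", "flank1_5p", "flank1_3p", "flank2_3p")
FOOTPRINT_FLANK_LABELS = ("flank2_left", "flank1_left",
                          "flank1_right", "flank2_right")


@dataclass
class RegionSystem:
    """Labelled regions belonging to one unit (miRNA or footprint).

    ``regions`` maps a label to a tuple of intervals (a tuple because a
    precursor may carry two mature arms; most labels hold one interval).
    """

    unit_id: str
    regions: Dict[str, Tuple[GenomicInterval, ...]]
    truncated: bool = False

    def labels(self) -> List[str]:
        return list(self.regions)


def _clip(chrom: str, start: int, end: int, strand: str,
          chrom_len: int | None) -> Tuple[GenomicInterval | None, bool]:
    lo = max(0, start)
    hi = min(end, chrom_len) if chrom_len is not None else end
    truncated = lo != start or hi != end
    if hi <= lo:
        return None, True
    return GenomicInterval(chrom, lo, hi, strand), truncated


def seed_interval(mature: GenomicInterval,
                  seed_span: Tuple[int, int] = (2, 8)) -> GenomicInterval:
    """Sub-interval of a mature miRNA covering seed positions (1-based,
    inclusive, in mature orientation; default positions 2-8)."""
    i, j = seed_span
    if not (1 <= i <= j <= mature.length()):
        raise ValueError(f"seed span {seed_span} outside mature of length "
                         f"{mature.length()}")
    if mature.strand == "+":
        return GenomicInterval(mature.chrom, mature.start + i - 1,
                               mature.start + j, "+")
    return GenomicInterval(mature.chrom, mature.end - j,
                           mature.end - i + 1, "-")


def build_mirna_regions(m: MirnaAnnotation,
                        seed_span: Tuple[int, int] = (2, 8),
                        chrom_length: int | None = None) -> RegionSystem:
    """Precursor, mature and seed regions plus four flanks, each flank the
    precursor's length.  On the '-' strand the 5' flanks have the larger
    coordinates.  Flanks running off the chromosome are truncated and the
    unit flagged."""
    pre = m.pre_interval
    L = pre.length()
    chrom, strand = pre.chrom, pre.strand
    truncated = False

    def flank(delta_lo: int, delta_hi: int):
        nonlocal truncated
        iv, trunc = _clip(chrom, pre.start + delta_lo, pre.start + delta_hi,
                          strand, chrom_length)
        truncated = truncated or trunc
        return (iv,) if iv is not None else ()

    left1 = flank(-L, 0)
    left2 = flank(-2 * L, -L)
    span = pre.end - pre.start
    right1 = flank(span, span + L)
    right2 = flank(span + L, span + 2 * L)
    if strand == "+":
        regions = {"flank2_5p": left2, "flank1_5p": left1,
                   "flank1_3p": right1, "flank2_3p": right2}
    else:
        regions = {"flank2_5p": right2, "flank1_5p": right1,
                   "flank1_3p": left1, "flank2_3p": left2}
    regions["pre"] = (pre,)
    matures = []
    seeds = []
    for _, iv in m.mature_intervals:
        if not pre.contains(iv):
            raise ValueError(f"mature outside precursor for {m.name}")
        matures.append(iv)
        seeds.append(seed_interval(iv, seed_span))
    regions["mature"] = tuple(matures)
    regions["seed"] = tuple(seeds)
    return RegionSystem(m.name, regions, truncated)


def build_footprint_regions(f: FootprintRecord,
                            chrom_length: int | None = None) -> RegionSystem:
    """Footprint plus two successive flanks of footprint length per side."""
    iv = f.interval
    L = iv.length()
    truncated = False

    def flank(lo: int, hi: int):
        nonlocal truncated
        out, trunc = _clip(iv.chrom, lo, hi, iv.strand, chrom_length)
        truncated = truncated or trunc
        return (out,) if out is not None else ()

    regions = {
        "flank2_left": flank(iv.start - 2 * L, iv.start - L),
        "flank1_left": flank(iv.start - L, iv.start),
        "footprint": (iv,),
        "flank1_right": flank(iv.end, iv.end + L),
        "flank2_right": flank(iv.end + L, iv.end + 2 * L),
    }
    return RegionSystem(f.footprint_id, regions, truncated)


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def unit_density(variants: Sequence[Variant], region) -> float:
    """Variants per nt in a region (anchor-base point assignment).

    ``region`` may be one interval or a tuple of intervals (counts pooled
    over the summed length).  Deletions count at their anchor base.
    """
    intervals = (region,) if isinstance(region, GenomicInterval) else tuple(region)
    total_len = sum(iv.length() for iv in intervals)
    if total_len == 0:
        raise ValueError("zero-length region")
    count = 0
    for v in variants:
        for iv in intervals:
            if v.chrom == iv.chrom and iv.contains_point(v.anchor0):
                count += 1
                break
    return count / total_len


def density_by_label(systems: Sequence[RegionSystem],
                     variants: Sequence[Variant],
                     flank_labels: Sequence[str] = ()
                     ) -> Dict[str, List[float]]:
    """Per-unit densities for every label across a set of region systems.

    If ``flank_labels`` is given, an extra ``flank_avg`` label holds, per
    unit, the pooled density over those flank regions (the "average across
    all flanking regions" statistic).
    """
    # pre-bin variants per chromosome for speed
    by_chrom: Dict[str, List[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    out: Dict[str, List[float]] = {}
    for sys_ in systems:
        chrom = next(iv.chrom for ivs in sys_.regions.values() for iv in ivs)
        vs = by_chrom.get(chrom, [])
        for label, intervals in sys_.regions.items():
            if not intervals:
                continue
            out.setdefault(label, []).append(unit_density(vs, intervals))
        if flank_labels:
            flank_ivs = tuple(iv for lbl in flank_labels
                              for iv in sys_.regions.get(lbl, ()))
            if flank_ivs:
                out.setdefault("flank_avg", []).append(unit_density(vs, flank_ivs))
    return out


@dataclass(frozen=True)
class DensitySummary:
    label: str
    n_units: int
    mean_density: float
    sem: float


@dataclass(frozen=True)
class DensityComparison:
    label_a: str
    label_b: str
    t_stat: float
    df: float
    p_value: float


def summarize(label: str, densities: Sequence[float]) -> DensitySummary:
    x = np.asarray(densities, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one unit")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return DensitySummary(label, int(x.size), float(np.mean(x)), sem)


def compare(label_a: str, densities_a: Sequence[float],
            label_b: str, densities_b: Sequence[float]) -> DensityComparison:
    """Welch two-sample two-sided t-test between per-unit density groups."""
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"comparison {label_a} vs {label_b} refused: both groups need "
            f">=2 units (got {a.size}, {b.size})"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return DensityComparison(label_a, label_b, float(res.statistic),
                             float(res.df), float(res.pvalue))
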