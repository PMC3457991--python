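"""Two-locus EM, |D'| confidence intervals, Gabriel blocks and linking."""

import numpy as np
import pandas as pd
import pytest

from mirindel.ld import (GabrielParams, LdUndefinedError, Marker,
                         dprime_ci, em_haplotype_freqs, gabriel_blocks,
                         link_indels, panel_markers)


def _genotypes_from_haps(h1, h2):
    return np.asarray(h1) + np.asarray(h2)


def _coupled_panel(n=100, freq=0.4, n_markers=4, seed=5):
    """Two complementary founder haplotypes -> |D'| = 1 between all pairs."""
    rng = np.random.default_rng(seed)
    h0 = rng.integers(0, 2, n_markers)
    h1 = 1 - h0
    picks = rng.random((2, n)) < freq
    geno = np.zeros((n_markers, n), dtype=float)
    for hap in range(2):
        geno += np.where(picks[hap][None, :], h0[:, None], h1[:, None])
    return geno


def _independent_pair(n=200, seed=9):
    rng = np.random.default_rng(seed)
    ga = rng.integers(0, 2, (2, n)).sum(axis=0).astype(float)
    gb = rng.integers(0, 2, (2, n)).sum(axis=0).astype(float)
    return ga, gb


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def test_em_without_double_hets_matches_direct_counting():
    # phase fully determined: genotypes only 0 or 2
    ga = np.array([0, 0, 2, 2, 2, 0], float)
    gb = np.array([0, 0, 2, 2, 2, 0], float)
    p11, p10, p01, p00 = em_haplotype_freqs(ga, gb)
    assert p11 == pytest.approx(0.5, abs=1e-9)
    assert p00 == pytest.approx(0.5, abs=1e-9)
    assert p10 == pytest.approx(0.0, abs=1e-9)


def test_em_frequencies_sum_to_one_on_random_data():
    rng = np.random.default_rng(3)
    for _ in range(20):
        ga = rng.integers(0, 3, 60).astype(float)
        gb = rng.integers(0, 3, 60).astype(float)
        try:
            p = em_haplotype_freqs(ga, gb)
        except LdUndefinedError:
            continue
        assert sum(p) == pytest.approx(1.0, abs=1e-12)
        assert all(x >= -1e-12 for x in p)


def _grid_oracle_p11(ga, gb, step=1e-4):
    """Grid-search maximum-likelihood p11 with allele freqs at their MLE."""
    from mirindel.ld import _genotype_counts, _genotype_probs

    n = _genotype_counts(ga, gb)
    N = n.sum()
    pa = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * N)
    pb = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * N)
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    best, best_ll = None, -np.inf
    for p11 in np.arange(lo, hi + step, step):
        h = np.array([[1 - pa - pb + p11, pb - p11],
                      [pa - p11, p11]])
        h = np.clip(h, 1e-12, None)
        ll = float((n * np.log(_genotype_probs(h))).sum())
        if ll > best_ll:
            best, best_ll = p11, ll
    return best


def test_em_matches_grid_search_oracle_with_double_hets():
    # constructed table with plenty of double heterozygotes
    ga = np.array([1] * 20 + [0] * 30 + [2] * 25 + [1] * 10 + [0] * 5 + [2] * 10, float)
    gb = np.array([1] * 20 + [0] * 30 + [2] * 25 + [0] * 10 + [1] * 5 + [1] * 10, float)
    p11, _, _, _ = em_haplotype_freqs(ga, gb)
    # note p11 here indexes (allele 1 at a, allele 1 at b)
    assert p11 == pytest.approx(_grid_oracle_p11(ga, gb), abs=1e-3)


def test_em_monomorphic_marker_flagged():
    with pytest.raises(LdUndefinedError):
        em_haplotype_freqs(np.zeros(10), np.array([0, 1, 2, 1, 0, 0, 1, 2, 1, 0], float))


# ---------------------------------------------------------------------------
# D' and its confidence interval
# ---------------------------------------------------------------------------

def test_coupled_markers_have_dprime_one_and_strong_ci():
    geno = _coupled_panel(n=100)
    pl = dprime_ci(geno[0], geno[1])
    assert pl.d_prime == pytest.approx(1.0, abs=1e-6)
    assert pl.cl >= 0.7
    assert pl.cu >= 0.98


def test_independent_markers_show_strong_recombination():
    ga, gb = _independent_pair(n=200)
    pl = dprime_ci(ga, gb)
    assert pl.cu < 0.9
    assert pl.d_prime < 0.4


def test_dprime_zero_at_product_frequencies():
    # genotype table that factorises exactly: D = 0 by definition
    ga = np.repeat([0, 1, 2], 16).astype(float)
    gb = np.tile([0, 1, 1, 2], 12).astype(float)
    pl = dprime_ci(ga, gb)
    assert pl.d_prime == pytest.approx(0.0, abs=1e-6)


def test_dprime_invariant_under_allele_label_swap():
    rng = np.random.default_rng(17)
    for seed in range(5):
        geno = _coupled_panel(n=80, freq=0.35, seed=seed)
        ga, gb = geno[0], geno[1]
        base = dprime_ci(ga, gb).d_prime
        assert dprime_ci(2 - ga, gb).d_prime == pytest.approx(base, abs=1e-6)
        assert dprime_ci(ga, 2 - gb).d_prime == pytest.approx(base, abs=1e-6)
    # and on noisy, partially coupled data
    ga, gb = _independent_pair(seed=rng.integers(1 << 30))
    assert dprime_ci(2 - ga, 2 - gb).d_prime == pytest.approx(
        dprime_ci(ga, gb).d_prime, abs=1e-6)


def test_mle_dprime_inside_its_own_interval():
    rng = np.random.default_rng(23)
    ok = 0
    trials = 30
    for t in range(trials):
        if t % 2:
            geno = _coupled_panel(n=60, freq=0.3, seed=100 + t)
            ga, gb = geno[0], geno[1]
        else:
            ga, gb = _independent_pair(n=60, seed=200 + t)
        try:
            pl = dprime_ci(ga, gb)
        except LdUndefinedError:
            ok += 1
            continue
        if pl.cl - 1e-9 <= pl.d_prime <= pl.cu + 1e-9:
            ok += 1
    assert ok >= trials - 1


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------

def _two_block_markers(seed=1, n=120, m=5, gap=50_000, spacing=2000,
                       chrom="chr1"):
    rng = np.random.default_rng(seed)
    markers = []
    truth = []
    pos = 10_000
    for b in range(2):
        h0 = rng.integers(0, 2, m)
        h1 = 1 - h0
        f = rng.uniform(0.3, 0.7)
        picks = rng.random((2, n)) < f
        geno = np.zeros((m, n))
        for hap in range(2):
            geno += np.where(picks[hap][None, :], h0[:, None], h1[:, None])
        for i in range(m):
            markers.append(Marker(f"b{b}m{i}", chrom, pos, geno[i]))
            truth.append(b)
            pos += spacing
        pos += gap
    return markers, truth


def test_two_block_panel_recovered_exactly():
    markers, truth = _two_block_markers(seed=4)
    blocks = gabriel_blocks(markers)
    assert len(blocks) == 2
    got = [set(b.member_markers) for b in blocks]
    want = [{m.rsid for m, t in zip(markers, truth) if t == b} for b in (0, 1)]
    assert got == want
    # boundary coordinates are first/last member positions
    assert blocks[0].left_pos1 == markers[0].pos1
    assert blocks[0].right_pos1 == markers[4].pos1


def test_low_maf_marker_excluded_without_breaking_block():
    markers, truth = _two_block_markers(seed=8)
    n = markers[0].genotypes.size
    rare = np.zeros(n)
    rare[:max(1, int(0.03 * n))] = 1  # MAF 0.03
    mid_pos = markers[2].pos1 + 500
    with_rare = markers[:3] + [Marker("rare", "chr1", mid_pos, rare)] + markers[3:]
    blocks = gabriel_blocks(with_rare)
    assert all("rare" not in b.member_markers for b in blocks)
    assert {m.rsid for m, t in zip(markers, truth) if t == 0} in \
        [set(b.member_markers) for b in blocks]


def test_all_independent_panel_yields_no_blocks():
    rng = np.random.default_rng(12)
    markers = [Marker(f"m{i}", "chr1", 1000 + 2000 * i,
                      rng.integers(0, 2, (2, 150)).sum(axis=0).astype(float))
               for i in range(6)]
    assert gabriel_blocks(markers) == []


def test_stricter_informative_fraction_never_grows_blocks():
    markers, _ = _two_block_markers(seed=6)
    loose = gabriel_blocks(markers, GabrielParams(strong_fraction=0.80))
    strict = gabriel_blocks(markers, GabrielParams(strong_fraction=0.99))
    assert sum(len(b.member_markers) for b in strict) <= \
        sum(len(b.member_markers) for b in loose)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _table2_like_panel(n=100, seed=2):
    """A synthetic analogue of a published-style locus: one strong-LD block
    spanning 25,150,296-25,182,193 containing both the indel and marker."""
    positions = [25150296, 25158008, 25166699, 25172000, 25182193]
    rsids = ["pmA", "rs713586", "rs34922018", "pmB", "pmC"]
    rng = np.random.default_rng(seed)
    m = len(positions)
    h0 = rng.integers(0, 2, m)
    h1 = 1 - h0
    picks = rng.random((2, n)) < 0.45
    geno = np.zeros((m, n))
    for hap in range(2):
        geno += np.where(picks[hap][None, :], h0[:, None], h1[:, None])
    return [Marker(r, "chr2", p, geno[i])
            for i, (r, p) in enumerate(zip(rsids, positions))]


def test_link_indel_and_marker_in_shared_block():
    panel = _table2_like_panel()
    gwas = pd.DataFrame([("chr2", 25158008, "rs713586", 6e-22,
                          "Body Mass Index")],
                        columns=["chrom", "pos", "rsid", "p", "trait"])
    recs = [{"rsid": "rs34922018", "chrom": "chr2", "pos1": 25166699,
             "linked_name": "DNAJC27"}]
    (link,) = link_indels(recs, gwas, panel)
    assert link.block_left == 25150296
    assert link.block_right == 25182193
    assert link.trait == "Body Mass Index"
    assert link.marker_p == pytest.approx(6e-22)


def test_link_window_excludes_distant_markers():
    panel = _table2_like_panel()
    gwas = pd.DataFrame([("chr2", 25158008 + 200_000, "far", 1e-9, "t")],
                        columns=["chrom", "pos", "rsid", "p", "trait"])
    recs = [{"rsid": "rs34922018", "chrom": "chr2", "pos1": 25166699,
             "linked_name": "DNAJC27"}]
    assert link_indels(recs, gwas, panel) == []


def test_link_skips_indels_absent_from_panel():
    panel = _table2_like_panel()
    gwas = pd.DataFrame([("chr2", 25158008, "rs713586", 6e-22, "BMI")],
                        columns=["chrom", "pos", "rsid", "p", "trait"])
    recs = [{"rsid": "not_in_panel", "chrom": "chr2", "pos1": 25166699,
             "linked_name": "X"}]
    assert link_indels(recs, gwas, panel) == []


def test_panel_markers_roundtrip(bundle):
    ms = panel_markers(bundle.panel)
    assert len(ms) == len(bundle.panel)
    assert all(m.maf() >= 0.05 for m in ms)
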