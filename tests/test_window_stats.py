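"""Window statistics: π, d_XY, Patterson's D, dynamic f_d.

Brute-force oracles work directly on allele counts: π and d_XY as mean
pairwise differences over (pairs of) alleles, D/f_d as direct per-site
evaluation of the frequency-weighted pattern sums.
"""

import itertools

import numpy as np
import pytest

from triadscan.io import polarize
from triadscan.windows import (Window, absolute_divergence, dynamic_fd,
                               genome_wide_D, nucleotide_diversity,
                               patterson_D, scan_windows, tile_windows)

from conftest import TRIAD, make_matrix, random_matrix


def _freqs_for(rng, n_sites=40):
    g, pops = random_matrix(rng, n_sites=n_sites)
    return g, pops, polarize(g, pops)


def _site_alleles(g, pops, pop, i):
    """Alternate-allele list at site i for population pop, by brute force.

    π and d_XY are invariant to which allele is called ancestral, so the
    oracle counts raw alternate alleles."""
    alleles = []
    for j, s in enumerate(g.samples):
        if pops.sample_to_pop[s] != pop or g.dosage[i, j] < 0:
            continue
        d = int(g.dosage[i, j])
        alleles += [1] * d + [0] * (2 - d)
    return alleles


class TestPi:
    def test_monomorphic_window_is_zero(self):
        samples = [f"{p}_{i}" for p in ("P1", "P2", "P3", "OUT") for i in range(2)]
        from triadscan.io import PopulationAssignment
        pops = PopulationAssignment({s: s.rsplit("_", 1)[0] for s in samples}, TRIAD)
        g = make_matrix([[2] * 6 + [2, 2], [0] * 8], samples=samples)
        f = polarize(g, pops)
        w = Window("1", 0, 10)
        assert nucleotide_diversity(f, w, "P1") == 0.0

    def test_two_haplotypes_pi_is_k_over_L(self):
        # one diploid sample per population; P1 het at 3 of 10 accessible sites
        samples = ["P1_0", "P2_0", "P3_0", "OUT_0"]
        from triadscan.io import PopulationAssignment
        pops = PopulationAssignment({s: s.split("_")[0] for s in samples}, TRIAD)
        d = [[1, 0, 0, 0]] * 3 + [[0, 0, 0, 0]] * 7
        g = make_matrix(d, samples=samples)
        f = polarize(g, pops)
        w = Window("1", 0, 10)
        assert nucleotide_diversity(f, w, "P1") == pytest.approx(3 / 10)

    def test_matches_mean_pairwise_difference(self):
        rng = np.random.default_rng(10)
        g, pops, f = _freqs_for(rng, n_sites=200)
        w = Window("1", 0, 200)
        for pop in ("P1", "P2", "P3"):
            total, L = 0.0, 0
            for i in range(g.n_sites):
                al = _site_alleles(g, pops, pop, i)
                if len(al) < 2:
                    continue
                L += 1
                diffs = sum(a != b for a, b in itertools.combinations(al, 2))
                total += diffs / (len(al) * (len(al) - 1) / 2)
            expect = total / L
            got = nucleotide_diversity(f, w, pop, accessible="variant")
            assert got == pytest.approx(expect, rel=1e-12)


class TestDxy:
    def test_identical_monomorphic_populations_zero(self):
        samples = [f"{p}_0" for p in ("P1", "P2", "P3", "OUT")]
        from triadscan.io import PopulationAssignment
        pops = PopulationAssignment({s: s.split("_")[0] for s in samples}, TRIAD)
        g = make_matrix([[0, 0, 0, 0]] * 5, samples=samples)
        f = polarize(g, pops)
        assert absolute_divergence(f, Window("1", 0, 5), "P1", "P2") == 0.0

    def test_opposite_fixation_gives_one(self):
        samples = [f"{p}_0" for p in ("P1", "P2", "P3", "OUT")]
        from triadscan.io import PopulationAssignment
        pops = PopulationAssignment({s: s.split("_")[0] for s in samples}, TRIAD)
        g = make_matrix([[2, 0, 0, 0]] * 5, samples=samples)
        f = polarize(g, pops)
        assert absolute_divergence(f, Window("1", 0, 5), "P1", "P2",
                                   accessible="variant") == 1.0

    def test_matches_between_population_pairwise_mean(self):
        rng = np.random.default_rng(11)
        g, pops, f = _freqs_for(rng, n_sites=200)
        w = Window("1", 0, 200)
        total, L = 0.0, 0
        for i in range(g.n_sites):
            a = _site_alleles(g, pops, "P1", i)
            b = _site_alleles(g, pops, "P2", i)
            if not a or not b:
                continue
            L += 1
            total += sum(x != y for x in a for y in b) / (len(a) * len(b))
        got = absolute_divergence(f, w, "P1", "P2", accessible="variant")
        assert got == pytest.approx(total / L, rel=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(12)
        g, pops, f = _freqs_for(rng, n_sites=100)
        w = Window("1", 0, 100)
        assert absolute_divergence(f, w, "P1", "P3") == \
            absolute_divergence(f, w, "P3", "P1")


def _freq_table_matrix(p1, p2, p3):
    """Build a matrix whose polarized frequencies are exactly the given
    per-site values (two diploids per population, frequencies in quarters)."""
    from triadscan.io import PopulationAssignment
    samples = [f"{p}_{i}" for p in ("P1", "P2", "P3", "OUT") for i in range(2)]
    pops = PopulationAssignment({s: s.rsplit("_", 1)[0] for s in samples}, TRIAD)
    rows = []
    for a, b, c in zip(p1, p2, p3):
        def dos(x):
            n = round(4 * x)
            return [min(n, 2), max(n - 2, 0)]
        rows.append(dos(a) + dos(b) + dos(c) + [0, 0])
    g = make_matrix(rows, samples=samples)
    return g, pops, polarize(g, pops)


class TestPattersonD:
    def test_pure_abba_site(self):
        g, pops, f = _freq_table_matrix([0.0], [1.0], [1.0])
        a, b, d = patterson_D(f, Window("1", 0, 1), pops)
        assert (a, b, d) == (1.0, 0.0, 1.0)

    def test_p1_equals_p2_gives_zero(self):
        rng = np.random.default_rng(13)
        p = rng.integers(0, 5, 30) / 4
        p3 = rng.integers(0, 5, 30) / 4
        g, pops, f = _freq_table_matrix(p, p, p3)
        _, _, d = patterson_D(f, Window("1", 0, 30), pops)
        assert d == 0.0

    def test_matches_direct_per_site_evaluation(self):
        rng = np.random.default_rng(14)
        g, pops, f = _freqs_for(rng, n_sites=50)
        w = Window("1", 0, 50)
        a = b = 0.0
        cols = {r: f.pop_col(r) for r in ("P1", "P2", "P3", "OUT")}
        for i in range(g.n_sites):
            if not f.retained[i]:
                continue
            p1, p2, p3, po = (f.freq[i, cols[r]] for r in ("P1", "P2", "P3", "OUT"))
            a += (1 - p1) * p2 * p3 * (1 - po)
            b += p1 * (1 - p2) * p3 * (1 - po)
        ga, gb, gd = patterson_D(f, w, pops)
        assert ga == pytest.approx(a, rel=1e-12)
        assert gb == pytest.approx(b, rel=1e-12)
        assert gd == pytest.approx((a - b) / (a + b), rel=1e-12)

    def test_fixed_populations_reduce_to_integer_pattern_counts(self):
        rng = np.random.default_rng(15)
        p1, p2, p3 = (rng.integers(0, 2, 40).astype(float) for _ in range(3))
        g, pops, f = _freq_table_matrix(p1, p2, p3)
        a, b, _ = patterson_D(f, Window("1", 0, 40), pops)
        assert a == int(a) and b == int(b)
        n_abba = int(sum((p1 == 0) & (p2 == 1) & (p3 == 1)))
        n_baba = int(sum((p1 == 1) & (p2 == 0) & (p3 == 1)))
        assert (a, b) == (n_abba, n_baba)


class TestDynamicFd:
    def test_receptor_equals_donor_gives_one(self):
        rng = np.random.default_rng(16)
        p = rng.integers(1, 5, 20) / 4
        p1 = rng.integers(0, 5, 20) / 4
        g, pops, f = _freq_table_matrix(p1, p, p)
        num, den, fd = dynamic_fd(f, Window("1", 0, 20), pops)
        assert den == pytest.approx(num)
        if num > 0:
            assert fd == pytest.approx(1.0)

    def test_no_excess_sharing_gives_zero(self):
        rng = np.random.default_rng(17)
        p = rng.integers(0, 5, 20) / 4
        p3 = rng.integers(1, 5, 20) / 4
        g, pops, f = _freq_table_matrix(p, p, p3)
        num, den, fd = dynamic_fd(f, Window("1", 0, 20), pops)
        assert num == 0.0
        assert fd == 0.0

    def test_negative_D_reported_missing(self):
        # all BABA: p1=1, p2=0, p3=1
        g, pops, f = _freq_table_matrix([1.0] * 5, [0.0] * 5, [1.0] * 5)
        _, _, fd = dynamic_fd(f, Window("1", 0, 5), pops)
        assert np.isnan(fd)

    def test_within_unit_interval_when_defined(self, pulse_sim, pops_for):
        cfg, g, truth, _ = pulse_sim
        stats = scan_windows(g, pops_for(cfg),
                             chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_names})
        fd = stats["fd"].dropna()
        assert len(fd) > 50
        assert ((fd >= 0) & (fd <= 1)).all()

    def test_introgressed_windows_have_higher_fd(self, pulse_sim, pops_for):
        cfg, g, truth, _ = pulse_sim
        stats = scan_windows(g, pops_for(cfg),
                             chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_names})
        intro = truth["state"].eq("introgressed").to_numpy()
        assert np.nanmean(stats["fd"][intro]) > np.nanmean(stats["fd"][~intro])


class TestScanWindows:
    def test_tiling_includes_short_terminal_window(self):
        wins = tile_windows({"chr1": 12_000}, width=5_000)
        assert wins[["start", "end"]].values.tolist() == \
            [[0, 5000], [5000, 10000], [10000, 12000]]

    def test_empty_window_emitted_with_missing_stats(self):
        rng = np.random.default_rng(18)
        g, pops = random_matrix(rng, n_sites=30)
        # sites at 0..29; second window 100..200 empty
        stats = scan_windows(g, pops, width=100, min_snps=1,
                             chrom_lengths={"1": 250})
        assert len(stats) == 3
        assert stats.loc[1, "n_sites"] == 0
        assert np.isnan(stats.loc[1, "D"]) and np.isnan(stats.loc[1, "fd"])

    def test_low_snp_windows_masked(self):
        rng = np.random.default_rng(19)
        g, pops = random_matrix(rng, n_sites=30)
        stats = scan_windows(g, pops, width=100, min_snps=1000,
                             chrom_lengths={"1": 100})
        assert stats["pi_P1"].isna().all()

    def test_composition_matches_single_window_operations(self, pulse_sim, pops_for):
        cfg, g, truth, _ = pulse_sim
        pops = pops_for(cfg)
        lengths = {c: cfg.chrom_length for c in cfg.chrom_names}
        stats = scan_windows(g, pops, chrom_lengths=lengths)
        freqs = polarize(g, pops, min_calls=2)
        rng = np.random.default_rng(20)
        for i in rng.choice(len(stats), 15, replace=False):
            row = stats.iloc[i]
            w = Window(row["chrom"], int(row["start"]), int(row["end"]))
            if row["n_snps"] < 10:
                continue
            assert nucleotide_diversity(freqs, w, TRIAD.p2) == \
                pytest.approx(row["pi_P2"], rel=1e-9)
            assert absolute_divergence(freqs, w, TRIAD.p2, TRIAD.p3) == \
                pytest.approx(row["dxy_P2_P3"], rel=1e-9)
            a, b, d = patterson_D(freqs, w, pops)
            assert a == pytest.approx(row["abba_sum"], rel=1e-9)
            num, den, fd = dynamic_fd(freqs, w, pops)
            assert num == pytest.approx(row["S_num"], rel=1e-9, abs=1e-12)
            if not np.isnan(fd):
                assert fd == pytest.approx(row["fd"], rel=1e-9)

    def test_dxy_columns_symmetric_under_role_swap(self, calib_sim, pops_for):
        cfg, g, truth = calib_sim
        pops = pops_for(cfg)
        freqs = polarize(g, pops)
        w = Window("chr1", 0, cfg.window_length)
        # two disjoint half-samples of the same population never go negative
        assert absolute_divergence(freqs, w, TRIAD.p1, TRIAD.p1) >= 0


class TestGenomeWideD:
    def test_zero_gene_flow_D_within_three_se(self, ils_sim, pops_for):
        cfg, g, truth = ils_sim
        stats = scan_windows(g, pops_for(cfg),
                             chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_names})
        d, se, nb = genome_wide_D(stats)
        assert nb >= 10
        assert abs(d) < 3 * se

    def test_admixture_shifts_D_positive(self, pulse_sim, pops_for):
        cfg, g, truth, _ = pulse_sim
        stats = scan_windows(g, pops_for(cfg),
                             chrom_lengths={c: cfg.chrom_length for c in cfg.chrom_names})
        d, se, _ = genome_wide_D(stats)
        assert d > 3 * se


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

dosage_rows = st.lists(
    st.lists(st.sampled_from([0, 1, 2, -1]), min_size=8, max_size=8),
    min_size=2, max_size=25)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(dosage_rows)
def test_patterson_D_bounded_and_dxy_symmetric(rows):
    """For any dosage table: D ∈ [−1, 1] when defined, d_XY(A,B) = d_XY(B,A)
    exactly, and f_d ∈ numerator/denominator contract holds."""
    from triadscan.io import PopulationAssignment
    samples = [f"{p}_{i}" for p in ("P1", "P2", "P3", "OUT") for i in range(2)]
    pops = PopulationAssignment({s: s.rsplit("_", 1)[0] for s in samples}, TRIAD)
    g = make_matrix(rows, samples=samples)
    f = polarize(g, pops)
    w = Window("1", 0, g.n_sites)
    _, _, d = patterson_D(f, w, pops)
    if not np.isnan(d):
        assert -1.0 <= d <= 1.0
    for a, b in (("P1", "P2"), ("P2", "P3")):
        xab = absolute_divergence(f, w, a, b)
        xba = absolute_divergence(f, w, b, a)
        assert (np.isnan(xab) and np.isnan(xba)) or xab == xba


@settings(max_examples=60, deadline=None, derandomize=True)
@given(dosage_rows)
def test_singleton_filter_idempotent_and_order_preserving(rows):
    from triadscan.io import filter_singletons
    g = make_matrix(rows)
    once = filter_singletons(g)
    twice = filter_singletons(once)
    assert np.array_equal(once.pos, twice.pos)
    assert np.array_equal(once.dosage, twice.dosage)
    # retained sites keep their original order and coordinates
    assert set(once.pos.tolist()) <= set(g.pos.tolist())
    assert np.all(np.diff(once.pos) > 0)
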