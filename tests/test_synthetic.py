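import numpy as np
import pytest
from scipy.stats import chisquare

import rtprofiler as rt
from rtprofiler.synthetic import genome_from_landscapes


def brute_force_timing(origins, fork_speed, positions):
    """Independent oracle: explicit min over origins, python loop."""
    out = []
    for x in positions:
        t = min(t0 + abs(x - p) / fork_speed for p, t0 in origins)
        out.append(min(t, 1.0))
    return np.array(out)


class TestLandscapeValidation:
    def test_origins_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            rt.Landscape(1000, ((500, 0.1), (500, 0.2)), 1.0)

    def test_origin_out_of_range(self):
        with pytest.raises(ValueError, match="within"):
            rt.Landscape(1000, ((1000, 0.1),), 1.0)

    def test_firing_time_range(self):
        with pytest.raises(ValueError, match="firing times"):
            rt.Landscape(1000, ((10, 1.0),), 1.0)

    def test_fork_speed_positive(self):
        with pytest.raises(ValueError, match="fork_speed"):
            rt.Landscape(1000, ((10, 0.1),), 0.0)

    def test_gaps_sorted_nonoverlapping(self):
        with pytest.raises(ValueError, match="gaps"):
            rt.Landscape(1000, ((10, 0.1),), 1.0, gaps=((100, 300), (200, 400)))

    def test_json_round_trip(self):
        ls = rt.Landscape(1000, ((10, 0.1), (500, 0.3)), 2.5, gaps=((100, 200),))
        assert rt.Landscape.from_dict(ls.to_dict()) == ls


class TestTimingCurve:
    def test_value_at_origin(self):
        ls = rt.Landscape(10_000_000, ((5_000_000, 0.2),), 1e7)
        assert rt.timing_curve(ls, [5_000_000]) == pytest.approx(0.2)

    def test_value_off_origin(self):
        ls = rt.Landscape(10_000_000, ((5_000_000, 0.2),), 1e7)
        assert rt.timing_curve(ls, [6_000_000]) == pytest.approx(0.3)

    def test_two_origins_matches_brute_force(self):
        origins = ((2_000_000, 0.1), (8_000_000, 0.1))
        ls = rt.Landscape(10_000_000, origins, 1e7)
        grid = np.arange(0, 10_000_000, 1000)
        expected = brute_force_timing(origins, 1e7, grid)
        np.testing.assert_allclose(rt.timing_curve(ls, grid), expected)
        assert rt.timing_curve(ls, [5_000_000]) == pytest.approx(0.4)
        assert grid[np.argmax(expected)] == 5_000_000

    def test_capped_at_one(self):
        ls = rt.Landscape(10_000_000, ((0, 0.5),), 1e6)
        assert rt.timing_curve(ls, [9_000_000]) == pytest.approx(1.0)

    def test_no_origins(self):
        ls = rt.Landscape(1000, (), 1.0)
        with pytest.raises(ValueError, match="no origins"):
            rt.timing_curve(ls, [10])

    def test_position_out_of_range(self):
        ls = rt.Landscape(1000, ((10, 0.1),), 1.0)
        with pytest.raises(ValueError):
            rt.timing_curve(ls, [1000])


class TestCopyNumberCurve:
    @pytest.mark.parametrize("tau,expected", [(0.0, 2.0), (1.0, 1.0), (0.5, 1.5)])
    def test_affine_map(self, tau, expected):
        assert rt.copy_number_curve([tau]) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rt.copy_number_curve([1.5])

    def test_monotone_in_tau(self):
        tau = np.linspace(0, 1, 101)
        c = rt.copy_number_curve(tau)
        assert np.all(np.diff(c) < 0)
        assert c.min() >= 1.0 and c.max() <= 2.0

    def test_peaks_coincide_with_origins(self):
        # the analytic c(x) curve has its local maxima exactly at origins
        ls = rt.Landscape(
            10_000_000, ((2_000_000, 0.1), (5_500_000, 0.25), (8_000_000, 0.15)), 1e7
        )
        grid = np.arange(0, 10_000_000, 1000)
        c = rt.copy_number_curve(rt.timing_curve(ls, grid))
        interior = np.arange(1, grid.size - 1)
        is_max = (c[interior] > c[interior - 1]) & (c[interior] > c[interior + 1])
        called = set(grid[interior[is_max]])
        assert called == {2_000_000, 5_500_000, 8_000_000}


class TestSampleReads:
    def _landscape(self, gaps=()):
        return rt.Landscape(10_000_000, ((5_000_000, 0.2),), 1e7, gaps=gaps)

    def test_g1_density_uniform_within_binomial_error(self):
        ls = self._landscape()
        cfg = rt.SimConfig(n_reads_g1=1_000_000, n_reads_s=1000, seed=5)
        reads = rt.sample_reads(ls, cfg, "G1")
        pos = reads.positions["chr1"]
        counts, _ = np.histogram(pos, bins=10, range=(0, 10_000_000))
        sd = np.sqrt(1_000_000 * 0.1 * 0.9)
        assert np.all(np.abs(counts - 100_000) < 5 * sd)

    def test_deterministic_under_seed(self):
        ls = self._landscape()
        cfg = rt.SimConfig(n_reads_g1=10_000, n_reads_s=10_000, seed=11)
        a = rt.sample_reads(ls, cfg, "S")
        b = rt.sample_reads(ls, cfg, "S")
        np.testing.assert_array_equal(a.positions["chr1"], b.positions["chr1"])

    def test_multinomial_invariant_to_weight_scaling(self):
        ls = self._landscape()
        cfg1 = rt.SimConfig(n_reads_g1=10_000, n_reads_s=10_000, seed=3,
                            bias_curve=lambda x: np.ones_like(x))
        cfg5 = rt.SimConfig(n_reads_g1=10_000, n_reads_s=10_000, seed=3,
                            bias_curve=lambda x: np.full_like(x, 5.0))
        a = rt.sample_reads(ls, cfg1, "G1")
        b = rt.sample_reads(ls, cfg5, "G1")
        np.testing.assert_array_equal(a.positions["chr1"], b.positions["chr1"])

    def test_output_sorted_and_exact_count(self):
        ls = self._landscape()
        cfg = rt.SimConfig(n_reads_g1=5000, n_reads_s=7000, seed=2)
        s = rt.sample_reads(ls, cfg, "S")
        pos = s.positions["chr1"]
        assert pos.size == 7000
        assert np.all(np.diff(pos) >= 0)
        assert s.phase == "S"

    def test_gaps_emit_zero_reads(self):
        gaps = ((2_000_000, 2_500_000), (7_000_000, 7_100_000))
        ls = self._landscape(gaps=gaps)
        cfg = rt.SimConfig(n_reads_g1=200_000, n_reads_s=200_000, seed=4)
        for phase in ("G1", "S"):
            pos = rt.sample_reads(ls, cfg, phase).positions["chr1"]
            for gs, ge in gaps:
                assert not np.any((pos >= gs) & (pos < ge))

    def test_all_weights_zero(self):
        ls = self._landscape()
        cfg = rt.SimConfig(n_reads_g1=100, n_reads_s=100, seed=0,
                           bias_curve=lambda x: np.zeros_like(x))
        with pytest.raises(ValueError, match="zero"):
            rt.sample_reads(ls, cfg, "G1")

    def test_bad_phase(self):
        cfg = rt.SimConfig(n_reads_g1=10, n_reads_s=10, seed=0)
        with pytest.raises(ValueError, match="phase"):
            rt.sample_reads(self._landscape(), cfg, "M")


def test_g1_uniformity_chi_square_across_seeds():
    # chi-square GOF at alpha=0.001 not rejected for >= 99 of 100 seeds
    ls = rt.Landscape(10_000_000, ((5_000_000, 0.2),), 1e7)
    passed = 0
    for seed in range(100):
        cfg = rt.SimConfig(n_reads_g1=50_000, n_reads_s=1000, seed=seed)
        pos = rt.sample_reads(ls, cfg, "G1").positions["chr1"]
        counts, _ = np.histogram(pos, bins=100, range=(0, 10_000_000))
        if chisquare(counts).pvalue > 0.001:
            passed += 1
    assert passed >= 99


def test_s_over_g1_density_converges_to_copy_number():
    # empirical S/G1 density ratio per 100-kb window -> c(x)/mean(c)
    ls = rt.Landscape(
        10_000_000, ((2_000_000, 0.1), (5_000_000, 0.3), (8_000_000, 0.2)), 1.5e7
    )
    cfg = rt.SimConfig(n_reads_g1=10_000_000, n_reads_s=10_000_000, seed=9)
    g1 = rt.sample_reads(ls, cfg, "G1").positions["chr1"]
    s = rt.sample_reads(ls, cfg, "S").positions["chr1"]
    edges = np.arange(0, 10_000_001, 100_000)
    hg1, _ = np.histogram(g1, bins=edges)
    hs, _ = np.histogram(s, bins=edges)
    empirical = (hs / hs.sum()) / (hg1 / hg1.sum())
    mids = (edges[:-1] + edges[1:]) / 2
    c = rt.copy_number_curve(rt.timing_curve(ls, mids))
    expected = c / c.mean()
    assert np.max(np.abs(empirical - expected)) < 0.02


def test_simulate_genome_deterministic_and_complete(sim22):
    cfg = rt.SimConfig(n_reads_g1=200_000, n_reads_s=200_000, seed=1)
    g1b, sb = rt.simulate_genome(sim22["landscapes"], cfg)
    assert g1b.n_reads == 200_000 and sb.n_reads == 200_000
    for chrom in sim22["g1"].positions:
        np.testing.assert_array_equal(sim22["g1"].positions[chrom], g1b.positions[chrom])
    genome = genome_from_landscapes(sim22["landscapes"])
    assert len(genome.names) == 22
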