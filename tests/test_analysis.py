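import numpy as np
import pytest

from replitime.analysis import (
    call_plasticity_regions,
    compare_profiles,
    correlation_matrix,
    fit_fork_density,
    initiation_rate,
    scan_fork_count,
    sphase_stats,
)
from replitime.fixtures import FixtureSpec, make_ipls_fixture
from replitime.genome_io import BinnedTrack, GenomeIndex
from replitime.replication_engine import SimConfig, run_population


def track_of(values, chrom="chrT", bin_width=500):
    g = GenomeIndex((chrom,), (len(values) * bin_width,), bin_width)
    return BinnedTrack(g, {chrom: np.asarray(values, float)})


class TestCompareProfiles:
    def test_self_correlation_is_one(self, rng):
        t = track_of(rng.random(50))
        res = compare_profiles(t, t)
        assert res.per_chromosome["chrT"] == pytest.approx(1.0)
        assert res.mean == pytest.approx(1.0) and res.sem == 0.0

    def test_negated_profile(self, rng):
        v = rng.random(50)
        res = compare_profiles(track_of(v), track_of(-v + 3.0))
        assert res.per_chromosome["chrT"] == pytest.approx(-1.0)

    def test_flip_b(self, rng):
        v = rng.random(50)
        res = compare_profiles(track_of(v), track_of(-v), flip_b=True)
        assert res.mean == pytest.approx(1.0)

    def test_textbook_pearson(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 5])
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        res = compare_profiles(track_of(x), track_of(y))
        assert res.per_chromosome["chrT"] == pytest.approx(r_oracle)

    def test_too_few_shared_bins(self):
        a = track_of([1.0, 2.0, np.nan, np.nan])
        b = track_of([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_profiles(a, b)

    def test_missing_bins_dropped_pairwise(self, rng):
        v = rng.random(50)
        a = v.copy()
        a[:10] = np.nan
        res = compare_profiles(track_of(a), track_of(v))
        assert res.mean == pytest.approx(1.0)


class TestPlasticityRegions:
    def test_no_regions_on_pure_noise(self, rng):
        v = rng.normal(size=500)
        a, b = track_of(v + rng.normal(0, 1, 500)), track_of(v)
        assert call_plasticity_regions(a, b) == []

    def test_injected_shift_called(self, rng):
        noise = rng.normal(size=2000)
        d = noise.copy()
        d[1000:1010] += 6.0
        regions = call_plasticity_regions(track_of(d), track_of(np.zeros(2000)))
        assert len(regions) == 1
        r = regions[0]
        assert r.start_bin >= 998 and r.end_bin <= 1011 and r.n_bins >= 8
        assert r.direction == 1

    def test_run_of_two_not_called(self, rng):
        d = rng.normal(size=2000)
        d[1000:1002] += 6.0
        assert call_plasticity_regions(track_of(d), track_of(np.zeros(2000))) == []

    def test_missing_bins_break_runs(self, rng):
        d = rng.normal(size=2000)
        d[1000:1006] += 6.0
        d[1002] = np.nan  # splits the run into 2 + 3
        regions = call_plasticity_regions(track_of(d), track_of(np.zeros(2000)))
        assert len(regions) == 1 and regions[0].start_bin == 1003

    def test_degenerate_difference_raises(self):
        t = track_of(np.ones(100))
        with pytest.raises(ValueError, match="degenerate"):
            call_plasticity_regions(t, t)


class TestForkScan:
    def test_single_candidate_is_optimum(self, clustered_fixture):
        fix = clustered_fixture
        cfg = SimConfig(ipls=fix.ipls, n_factors=6, n_cycles=30, seed=1)
        from replitime.flow_sorter import population_profile

        emp = population_profile(run_population(cfg))
        res = scan_fork_count(fix.ipls, emp, [6], cycles=10, seed=2)
        assert res.optimal_n == {"chrS1": 6}
        assert np.isnan(res.slope)  # regression needs >= 2 chromosomes

    def test_exact_line_recovered(self):
        lengths = np.array([1e7, 2e7, 4e7, 8e7])
        optima = 3.0 + 2e-7 * lengths
        slope, intercept, r = fit_fork_density(lengths, optima)
        assert slope == pytest.approx(2e-7)
        assert intercept == pytest.approx(3.0)
        assert r == pytest.approx(1.0)


class TestSphaseStats:
    def test_unit_inversion(self):
        # 720 steps * 500 bp / (2 forks * 50 bp/s) / 3600 s = exactly 1 h
        assert sphase_stats([720], 500, 50)["median_hours"] == pytest.approx(1.0)

    def test_median_and_mean(self):
        out = sphase_stats([1, 2, 3])
        assert out["median_steps"] == 2 and out["mean_steps"] == 2

    def test_dimensional_exactness(self):
        h1 = sphase_stats([5000], 500, 50)["median_hours"]
        h2 = sphase_stats([5000], 500, 100)["median_hours"]
        assert h1 == pytest.approx(2 * h2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sphase_stats([])


class TestInitiationRate:
    def test_lone_origin_single_event_at_t1(self):
        fix = make_ipls_fixture(FixtureSpec(site_model="lone", n_bins=20, lone_bin=10))
        pop = run_population(
            SimConfig(ipls=fix.ipls, n_factors=1, n_cycles=5, seed=0, record_initiations=True)
        )
        tbl = initiation_rate(pop)
        nz = tbl[tbl["initiations_per_unreplicated_bin"] > 0]
        assert list(nz["t"]) == [1]
        assert nz["initiations_per_unreplicated_bin"].iloc[0] == pytest.approx(
            1 / 20
        )  # one initiation per cycle over 20 unreplicated bins

    def test_initiation_totals_match_events(self, clustered_fixture):
        pop = run_population(
            SimConfig(ipls=clustered_fixture.ipls, n_factors=8, n_cycles=10, seed=4,
                      record_initiations=True)
        )
        n_events = sum(len(ev) for unit in pop.initiations for ev in unit)
        assert n_events >= 10  # at least one initiation per cycle
        # each event consumed one free factor and created one bubble; the
        # replicated series must end at full territory for complete cycles
        for unit, series_list in zip(pop.units, pop.replicated_series):
            for series in series_list:
                assert series[-1] == unit.n_bins

    def test_rate_rises_then_falls_for_uniform_landscape(self):
        from replitime.genome_io import BinnedTrack, GenomeIndex
        from replitime.ipls import IPLS

        g = GenomeIndex(("chrT",), (500 * 500,), 500)
        lm = IPLS(BinnedTrack(g, {"chrT": np.full(500, 0.05)}), background=0.0)
        pop = run_population(
            SimConfig(ipls=lm, n_factors=16, n_cycles=100, seed=9, record_initiations=True)
        )
        tbl = initiation_rate(pop)
        rate = tbl["initiations_per_unreplicated_bin"].to_numpy()
        # smooth and require an interior maximum (rise then fall)
        k = np.ones(5) / 5
        smooth = np.convolve(rate, k, mode="valid")
        peak = smooth.argmax()
        assert 0 < peak < len(smooth) - 1
        assert smooth[peak] > 1.5 * smooth[0]

    def test_requires_event_recording(self, clustered_population):
        with pytest.raises(ValueError, match="record_initiations"):
            initiation_rate(clustered_population)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        profiles = [track_of(rng.random(40)) for _ in range(3)]
        m, _ = correlation_matrix(profiles, list("abc"))
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_identical_pair_clusters_first(self, rng):
        v = rng.random(40)
        profiles = [track_of(v), track_of(v + 1e-9), track_of(-v)]
        m, order = correlation_matrix(profiles, ["a", "a2", "inv"])
        pos = {m.index[i]: rank for rank, i in enumerate(order)}
        assert abs(pos["a"] - pos["a2"]) == 1  # adjacent leaves

    def test_three_profile_brute_force(self, rng):
        vecs = [rng.random(30) for _ in range(3)]
        m, _ = correlation_matrix([track_of(v) for v in vecs])
        for i in range(3):
            for j in range(3):
                assert m.values[i, j] == pytest.approx(np.corrcoef(vecs[i], vecs[j])[0, 1])
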