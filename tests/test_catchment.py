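import numpy as np
import pytest

from echoplace.catchment import (
    angular_catchment,
    linear_catchment,
    linear_catchment_summary,
    median_pairwise_dissimilarity,
    monotone_run_length,
    tradeoff_report,
)
from echoplace.geometry import direction_unit_vector
from echoplace.scene import ConfigurationError, DirectionGrid, SamplingDesign
from echoplace.templates import Template, TemplateSet

GRID = DirectionGrid.default()


def brute_force_run_length(d, M, tol_frac=0.01, min_frac=0.10):
    """Independent scanner: walk the curve, stop at the first disqualifying
    decrease, then look back for the last point above the rise threshold."""
    run_end = len(d) - 1
    for k in range(1, len(d)):
        if d[k - 1] - d[k] >= tol_frac * M:
            run_end = k - 1
            break
    best = 0
    for k in range(run_end + 1):
        if d[k] >= min_frac * M:
            best = k
    return best


class TestMonotoneRunLength:
    M = 1.0

    def test_strictly_increasing_runs_to_end(self):
        d = np.array([0.0, 0.2, 0.5, 1.0])
        assert monotone_run_length(d, self.M) == 3

    def test_never_reaching_rise_threshold_gives_zero(self):
        # stays below 10% of the median dissimilarity: trivial increase
        d = np.array([0.0, 0.02, 0.05, 0.08])
        assert monotone_run_length(d, self.M) == 0

    def test_small_dip_tolerated(self):
        # 0.5%-of-M dip is below the 1% threshold: run continues through it
        d = np.array([0.0, 0.3, 0.295, 0.6])
        assert monotone_run_length(d, self.M) == 3

    def test_large_dip_ends_run(self):
        d = np.array([0.0, 0.3, 0.2, 0.9])
        assert monotone_run_length(d, self.M) == 1

    def test_agrees_with_brute_force_scanner(self):
        rng = np.random.default_rng(42)
        for _ in range(10000):
            n = rng.integers(2, 12)
            d = np.r_[0.0, rng.random(n)]
            M = rng.uniform(0.2, 2.0)
            assert monotone_run_length(d, M) == brute_force_run_length(d, M)

    def test_edge_cases_against_brute_force(self):
        M = 1.0
        cases = [
            np.array([0.0, 0.101, 0.1005, 0.5]),  # dip of exactly ~0.05% of M
            np.array([0.0, 0.5, 0.49, 0.48, 0.47]),  # staircase of 1% dips
            np.array([0.0, 0.099, 0.0999, 0.09999]),  # hugs the 10% floor
            np.array([0.0, 0.1]),  # exactly at the floor
            np.array([0.0, 0.5, 0.5, 0.5]),  # flat (zero decrease)
        ]
        for d in cases:
            assert monotone_run_length(d, M) == brute_force_run_length(d, M)


class TestMedianPairwise:
    def test_two_templates(self):
        ts = TemplateSet(
            [Template(np.zeros(4), 0, 0), Template(np.r_[5.0, np.zeros(3)], 0, 1)],
            GRID,
        )
        assert median_pairwise_dissimilarity(ts, 1.0) == pytest.approx(5.0)

    def test_identical_templates(self):
        ts = TemplateSet(
            [Template(np.ones(4), 0, d) for d in range(3)], GRID
        )
        assert median_pairwise_dissimilarity(ts, 1.0) == 0.0

    def test_median_of_three_pairs(self):
        # collinear values 0, 1, 3 → pairwise distances {1, 2, 3}, median 2
        ts = TemplateSet(
            [Template(np.array([v]), 0, d) for d, v in enumerate([0.0, 1.0, 3.0])],
            GRID,
        )
        assert median_pairwise_dissimilarity(ts, 1.0) == pytest.approx(2.0)

    def test_singleton_rejected(self):
        ts = TemplateSet([Template(np.zeros(3), 0, 0)], GRID)
        with pytest.raises(ConfigurationError):
            median_pairwise_dissimilarity(ts, 1.0)


def _panorama_from_unit_vectors(scale=10.0):
    """217 templates whose pairwise distance is the chord between direction
    unit vectors — strictly increasing in great-circle separation."""
    dirs = GRID.directions
    vecs = direction_unit_vector(dirs[:, 0], dirs[:, 1]) * scale
    return TemplateSet(
        [Template(vecs[d], 0, d) for d in range(len(dirs))], GRID
    )


class TestAngularCatchment:
    def test_identical_panorama_flat_zero(self):
        ts = TemplateSet([Template(np.ones(5), 0, d) for d in range(217)], GRID)
        prof = angular_catchment(ts, 0, sigma_n2=1.0, M=1.0)
        assert prof.catchment_distance == 0.0
        assert np.allclose(prof.dissimilarities, 0.0)

    def test_monotone_construction_reaches_last_bin(self):
        ts = _panorama_from_unit_vectors()
        prof = angular_catchment(ts, 0, sigma_n2=1.0)
        assert prof.catchment_distance == prof.separations[-1]
        assert np.all(np.diff(prof.separations) > 0)

    def test_bin_width_invariance_for_monotone_curve(self):
        ts = _panorama_from_unit_vectors()
        a = angular_catchment(ts, 0, sigma_n2=1.0, bin_width=10.0)
        b = angular_catchment(ts, 0, sigma_n2=1.0, bin_width=5.0)
        # both runs extend to the maximum separation bin
        assert a.catchment_distance == a.separations[-1]
        assert b.catchment_distance == b.separations[-1]

    def test_catchment_bounded_by_max_separation(self):
        rng = np.random.default_rng(0)
        ts = TemplateSet(
            [Template(rng.random(5), 0, d) for d in range(217)], GRID
        )
        prof = angular_catchment(ts, 0, sigma_n2=0.01)
        assert 0.0 <= prof.catchment_distance <= prof.separations[-1]


def _transect_set(values, grid=GRID, spacing=0.25, direction=0):
    design = SamplingDesign.transect(len(values), spacing)
    return TemplateSet(
        [
            Template(np.atleast_1d(np.asarray(v, float)), p, direction)
            for p, v in enumerate(values)
        ],
        grid,
        design,
    )


class TestLinearCatchment:
    def test_strictly_increasing_dissimilarity_runs_to_transect_end(self):
        # template value grows quadratically with position, so dissimilarity
        # from any x increases with |Δx| in both directions on average
        ts = _transect_set([x**2 * 5.0 for x in range(8)])
        catchments, median = linear_catchment(ts, 0, sigma_n2=1.0, M=10.0)
        # endpoint sees the full transect length
        assert catchments[0] == pytest.approx(7 * 0.25)

    def test_uniform_scene_zero_catchment(self):
        ts = _transect_set([1.0] * 6)
        catchments, median = linear_catchment(ts, 0, sigma_n2=1.0, M=1.0)
        assert np.allclose(catchments, 0.0)
        assert median == 0.0

    def test_short_transect_rejected(self):
        ts = _transect_set([0.0, 1.0])
        with pytest.raises(ConfigurationError):
            linear_catchment(ts, 0, sigma_n2=1.0, M=1.0)

    def test_requires_transect_design(self):
        ts = TemplateSet(
            [Template(np.zeros(3), p, 0) for p in range(4)], GRID,
            SamplingDesign(poses=np.zeros((4, 3))),
        )
        with pytest.raises(ConfigurationError):
            linear_catchment(ts, 0, sigma_n2=1.0, M=1.0)

    def test_scale_invariance(self):
        # scaling all templates and σ_n together leaves catchments unchanged
        vals = [0.0, 1.0, 3.0, 3.5, 7.0, 9.0]
        a, _ = linear_catchment(_transect_set(vals), 0, sigma_n2=1.0, M=3.0)
        scaled = [v * 10 for v in vals]
        b, _ = linear_catchment(_transect_set(scaled), 0, sigma_n2=100.0, M=3.0)
        assert np.array_equal(a, b)

    def test_summary_covers_all_directions(self):
        design = SamplingDesign.transect(5, 0.2)
        templates = [
            Template(np.array([float(p * (d + 1))]), p, d)
            for p in range(5)
            for d in range(3)
        ]
        ts = TemplateSet(templates, GRID, design)
        summary, per_pos = linear_catchment_summary(ts, sigma_n2=1.0)
        assert summary.per_direction_median.shape == (3,)
        assert per_pos.shape == (3, 5)
        assert summary.median_pairwise_dissimilarity > 0


class TestTradeoffReport:
    def test_constant_pc_not_applicable(self):
        rep = tradeoff_report(np.ones(10), np.arange(10.0))
        assert not rep.applicable
        assert np.isnan(rep.rho)

    def test_identical_sites_ranksum_null(self):
        rng = np.random.default_rng(0)
        catch = np.r_[rng.random(50), np.zeros(0)]
        values = np.r_[catch, catch]
        labels = np.r_[np.zeros(50), np.ones(50)]
        pc = np.tile(rng.random(50), 2)
        rep = tradeoff_report(pc, values, labels)
        assert rep.ranksum_p == pytest.approx(1.0, abs=0.05)

    def test_negative_association_detected(self):
        rng = np.random.default_rng(1)
        catch = rng.random(200)
        pc = 1.0 - catch + rng.normal(0, 0.05, 200)
        rep = tradeoff_report(pc, catch)
        assert rep.applicable
        assert rep.rho < -0.9
        assert rep.rho_ci[0] < rep.rho < rep.rho_ci[1]
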