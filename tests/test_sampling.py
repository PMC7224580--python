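"""ILR sampling, volume estimation and VEGAS adaptation."""

import numpy as np
import pytest
from scipy import stats

from ptmgeo._batch import STAT_CODE
from ptmgeo.fixtures import EXPECTED_STATIONARITY, FIXTURE_SIGMAS, THETA_FIXTURES
from ptmgeo.model import SamplingBox
from ptmgeo.sampling import (
    LabelledSample,
    VegasGrid,
    estimate_volume,
    ilr_sample,
    label_sample,
    vegas_run,
    vegas_step,
)
from ptmgeo.solver import Stationarity

BOX = SamplingBox(1, 8)


class TestIlrSampling:
    def test_marginals_are_uniform(self):
        pts = ilr_sample(20000, BOX, 123)
        assert pts.shape == (20000, 8)
        assert np.abs(pts).max() <= 1.0
        for j in range(8):
            p = stats.kstest(pts[:, j], stats.uniform(loc=-1, scale=2).cdf).pvalue
            assert p > 0.01

    def test_single_point(self):
        pts = ilr_sample(1, SamplingBox(3, 6), 5)
        assert pts.shape == (1, 6)
        assert np.abs(pts).max() <= 3.0

    def test_determinism(self):
        assert (ilr_sample(500, BOX, 9) == ilr_sample(500, BOX, 9)).all()
        assert not (ilr_sample(500, BOX, 9) == ilr_sample(500, BOX, 10)).all()

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            ilr_sample(0, BOX, 1)


class TestLabelling:
    def test_fixture_pattern_through_batch_labelling(self):
        """The batch labelling path reproduces the four reference points'
        stationarity pattern across sigma in {3,...,10}."""
        pts = np.log10([THETA_FIXTURES[k] for k in (1, 2, 3, 4)])
        sample = label_sample(pts, FIXTURE_SIGMAS, box=BOX)
        for row, k in enumerate((1, 2, 3, 4)):
            for si, sigma in enumerate(FIXTURE_SIGMAS):
                expected = STAT_CODE[EXPECTED_STATIONARITY[k][si]]
                assert sample.labels[sigma][row] == expected

    def test_empty_sigma_grid(self):
        pts = ilr_sample(5, BOX, 0)
        sample = label_sample(pts, [], box=BOX)
        assert sample.labels == {}


def _synthetic_sample(labels):
    n = len(labels)
    sample = LabelledSample(box=BOX, seed=0, points=np.zeros((n, 8)))
    sample.labels[10.0] = np.asarray(labels, dtype=np.int8)
    sample.nongeneric_tally[10.0] = int((np.asarray(labels) == 2).sum())
    return sample


class TestVolumeEstimator:
    def test_half_width_formula(self):
        """100 points, 50 bistable: v = 0.5 and the 95% half-width equals
        1.96 sqrt(0.25 * 100/99) / 10 ~ 0.0985."""
        sample = _synthetic_sample([1] * 50 + [0] * 50)
        est = estimate_volume(sample, 10.0)
        assert est.v_hat == 0.5
        half = (est.ci_high - est.ci_low) / 2
        assert abs(half - 0.0985) < 2e-3

    def test_all_bistable(self):
        est = estimate_volume(_synthetic_sample([1] * 40), 10.0)
        assert est.v_hat == 1.0
        assert est.ci_high - est.ci_low == 0.0

    def test_rule_of_three_when_empty(self):
        est = estimate_volume(_synthetic_sample([0] * 60), 10.0)
        assert est.v_hat == 0.0 and est.degenerate
        assert np.isclose(est.ci_high, 3.0 / 60)

    def test_nongeneric_points_excluded(self):
        est = estimate_volume(_synthetic_sample([1, 0, 2, 2, 0, 1]), 10.0)
        assert est.n == 4 and est.v_hat == 0.5 and est.n_nongeneric == 2

    def test_calibration_against_analytic_region(self):
        """CI coverage on a region of known volume: an axis-aligned sub-box
        with log-volume fraction f, indicator evaluated exactly."""
        f = 0.5 * 0.3  # two axes restricted to 50% and 30% of their range
        rng = np.random.default_rng(77)
        cover = 0
        trials = 200
        for _ in range(trials):
            pts = rng.uniform(-1, 1, size=(800, 8))
            inside = (np.abs(pts[:, 0]) < 0.5) & (np.abs(pts[:, 1]) < 0.3)
            sample = _synthetic_sample(inside.astype(int))
            est = estimate_volume(sample, 10.0)
            cover += est.ci_low <= f <= est.ci_high
        assert cover / trials >= 0.93


def test_bistable_volume_grows_with_box_size():
    """At sigma = 500 the bistable fraction of the larger box H_2 exceeds
    that of H_1: widening the sampling domain gains bistable points faster
    than it dilutes them.  The fractions differ roughly threefold
    (~1% vs ~3%), so a moderate sample resolves the ordering decisively."""
    estimates = []
    for p in (1, 2):
        box = SamplingBox(p, 8)
        pts = ilr_sample(8000, box, 555 + p)
        sample = label_sample(pts, [500.0], box=box)
        estimates.append(estimate_volume(sample, 500.0))
    assert estimates[0].ci_high < estimates[1].ci_low


class TestVegas:
    def test_bin_lengths_always_sum_to_two(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, size=(300, 8))
        grid = VegasGrid.uniform()
        for it in range(3):
            new, grid = vegas_step(pts, grid, 200, seed=it)
            np.testing.assert_allclose(grid.bin_lengths().sum(axis=1), 2.0)
            assert np.abs(new).max() <= 1.0
            assert (np.diff(grid.edges, axis=1) > 0).all()

    def test_uniform_density_keeps_bins_equal(self):
        # equally spread mass (one point per bin centre) leaves the grid
        # unchanged up to rounding of the smoothed frequencies
        grid = VegasGrid.uniform(dim=2, n_bins=10)
        centres = (grid.edges[0, :-1] + grid.edges[0, 1:]) / 2
        pts = np.stack([centres, centres], axis=1)
        _, g2 = vegas_step(pts, grid, 50, seed=1)
        np.testing.assert_allclose(g2.bin_lengths(), 0.2, atol=1e-9)

    def test_empty_bins_still_receive_mass(self):
        """Smoothing increments every bin frequency, so a degenerate input
        set concentrated in one bin cannot starve the rest of the axis."""
        pts = np.full((50, 2), 0.01)
        grid = VegasGrid.uniform(dim=2, n_bins=10, smoothing_k=1000)
        new, g2 = vegas_step(pts, grid, 2000, seed=3)
        occupied, _ = np.histogram(new[:, 0], bins=g2.edges[0])
        assert (occupied > 0).all()
        # ... while most bins contract onto the host interval of the mass
        lengths = g2.bin_lengths()[0]
        assert np.median(lengths) < 0.05
        assert lengths.max() > 0.5  # the empty stretches pool into long bins

    def test_zero_iterations_returns_initial_set(self):
        init = np.zeros((4, 8))
        res = vegas_run(init, 0, 100, 10.0, seed=1, ilr_fraction=0.01)
        assert res.n_sampled == 0
        assert (res.bistable_points == init).all()

    def test_empty_initial_set_is_an_error(self):
        with pytest.raises(ValueError, match="ILR"):
            vegas_step(np.empty((0, 8)), VegasGrid.uniform(), 10, 0)

    def test_points_outside_unit_box_rejected(self):
        with pytest.raises(ValueError):
            vegas_step(np.full((3, 8), 1.5), VegasGrid.uniform(), 10, 0)

    def test_no_bistability_found_at_sigma_one(self):
        """A VEGAS sample steered by bistable points found at sigma = 2.5
        contains no bistable points at sigma = 1 (small-scale check of the
        substrate threshold)."""
        pts = ilr_sample(20000, BOX, 314)
        sample = label_sample(pts, [2.5], box=BOX)
        seeds = sample.bistable_points(2.5)
        assert seeds.shape[0] > 0
        res = vegas_run(seeds, 1, 4000, 1.0, seed=11,
                        ilr_fraction=seeds.shape[0] / 20000)
        assert res.n_new_bistable == 0
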