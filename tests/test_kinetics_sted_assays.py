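import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prewetbelt import Movie
from prewetbelt.quantify import (
    apical_offset_distribution,
    correlate,
    enrichment_ratio_series,
    fit_hill,
    partition_coefficient,
    permeability_ratio,
    signed_offsets,
    teer_normalize,
)
from prewetbelt.synth import generate_sted_fixture
from prewetbelt.synth.fixtures import _hill


@pytest.fixture()
def ratio_movie():
    rng = np.random.default_rng(5)
    stack = rng.uniform(10, 100, size=(12, 32, 32))
    junction = np.zeros((32, 32), bool)
    junction[10:14, :] = True
    cytoplasm = np.zeros((32, 32), bool)
    cytoplasm[20:30, :] = True
    return Movie(stack, 0.1, 1.0), junction, cytoplasm


class TestEnrichmentRatio:
    def test_equal_compartments_give_unity(self):
        stack = np.full((5, 16, 16), 7.0)
        movie = Movie(stack, 0.1, 1.0)
        j = np.zeros((16, 16), bool)
        j[:8] = True
        c = ~j
        np.testing.assert_allclose(enrichment_ratio_series(movie, j, c), 1.0)

    def test_bleaching_invariance_to_machine_precision(self, ratio_movie):
        movie, j, c = ratio_movie
        base = enrichment_ratio_series(movie, j, c)
        t = np.arange(movie.n_frames)
        bleached = Movie(
            movie.stack * np.exp(-0.08 * t)[:, None, None], 0.1, 1.0
        )
        np.testing.assert_allclose(
            enrichment_ratio_series(bleached, j, c), base, rtol=1e-12
        )

    def test_empty_mask_yields_nan_with_warning(self, ratio_movie):
        movie, j, _ = ratio_movie
        with pytest.warns(UserWarning, match="empty mask"):
            out = enrichment_ratio_series(movie, j, np.zeros((32, 32), bool))
        assert np.isnan(out).all()

    def test_overlapping_masks_rejected(self, ratio_movie):
        movie, j, _ = ratio_movie
        with pytest.raises(ValueError, match="overlap"):
            enrichment_ratio_series(movie, j, j)


class TestHillFit:
    def test_noiseless_parameters_recovered(self):
        t = np.linspace(0, 60, 60)
        y = _hill(t, 1.0, 2.0, 2.0, 10.0)
        fit = fit_hill(t, y)
        assert fit.ok
        assert fit.base == pytest.approx(1.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.n == pytest.approx(2.0, abs=1e-6)
        assert fit.t_half == pytest.approx(10.0, abs=1e-6)

    def test_decreasing_series_flagged(self):
        t = np.linspace(0, 30, 20)
        fit = fit_hill(t, 5.0 - 0.1 * t)
        assert not fit.ok

    def test_too_few_points_flagged(self):
        fit = fit_hill(np.arange(4.0), np.arange(4.0))
        assert not fit.ok

    def test_arrival_time_difference_is_t_half_difference(self):
        t = np.linspace(0, 80, 80)
        f1 = fit_hill(t, _hill(t, 0.0, 1.0, 2.0, 5.0))
        f2 = fit_hill(t, _hill(t, 0.0, 1.0, 2.0, 18.0))
        assert f2.t_half - f1.t_half == pytest.approx(13.0, abs=1e-4)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)
        assert correlate(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(np.ones(5), np.arange(5.0))

    def test_programmed_rho_within_fisher_interval(self):
        rho, n = 0.7, 101
        rng = np.random.default_rng(42)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r = correlate(xy[:, 0], xy[:, 1])
        half = 1.96 / np.sqrt(n - 3)
        assert abs(np.arctanh(r) - np.arctanh(rho)) <= half


class TestApicalOffsets:
    def test_uniform_displacement_mode_exact(self):
        strand = np.array([[0.0, 0.0], [1000.0, 0.0]])
        xs = np.linspace(100, 900, 25)
        clusters = np.column_stack([xs, np.full(25, 40.0)])
        hist = apical_offset_distribution(strand, clusters, [0, 1], bin_width=20.0)
        assert hist.mode == pytest.approx(40.0)
        np.testing.assert_allclose(hist.offsets, 40.0, atol=1e-9)

    def test_clusters_on_strand_zero_offsets(self):
        strand = np.array([[0.0, 0.0], [500.0, 0.0]])
        clusters = np.column_stack([np.linspace(10, 490, 9), np.zeros(9)])
        offs = signed_offsets(strand, clusters, [0, 1])
        np.testing.assert_allclose(offs, 0.0, atol=1e-9)

    def test_lateral_side_is_negative(self):
        strand = np.array([[0.0, 0.0], [100.0, 0.0]])
        offs = signed_offsets(strand, [[50.0, -30.0]], [0, 1])
        assert offs[0] == pytest.approx(-30.0)

    def test_empty_cluster_set_empty_histogram(self):
        strand = np.array([[0.0, 0.0], [100.0, 0.0]])
        hist = apical_offset_distribution(strand, np.empty((0, 2)), [0, 1])
        assert hist.counts.size == 0

    def test_generator_mode_recovered_within_one_bin(self):
        strand, clusters, truth = generate_sted_fixture(
            n_clusters=10_000, offset_mode=40.0, seed=9
        )
        hist = apical_offset_distribution(
            strand, clusters, truth.params["apical_direction"], bin_width=20.0
        )
        assert abs(hist.mode - 40.0) <= 20.0

    def test_zero_width_distribution_exact_distance(self):
        strand, clusters, truth = generate_sted_fixture(
            n_clusters=50, offset_mode=60.0, decay_apical=0.0,
            decay_lateral=0.0, seed=1,
        )
        offs = signed_offsets(strand, clusters, truth.params["apical_direction"])
        np.testing.assert_allclose(offs, 60.0, atol=0.5)


class TestScalarAssays:
    def test_permeability_trivials(self):
        img = np.ones((20, 20))
        lumen = np.zeros((20, 20), bool)
        lumen[8:12, 8:12] = True
        outside = np.zeros((20, 20), bool)
        outside[:3] = True
        assert permeability_ratio(img, lumen, outside) == pytest.approx(1.0)
        img2 = img.copy()
        img2[lumen] = 0.0
        assert permeability_ratio(img2, lumen, outside) == 0.0

    def test_permeability_empty_mask_rejected(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError):
            permeability_ratio(img, np.zeros((8, 8), bool), img > 0)

    def test_partition_coefficient_cases(self):
        assert partition_coefficient(10.0, 10.0, 0.0) == 1.0
        assert partition_coefficient(2.0, 12.0, 2.0) == 0.0
        assert partition_coefficient(30.0, 12.0, 2.0) == pytest.approx(2.8)

    def test_partition_bad_denominator(self):
        with pytest.raises(ValueError):
            partition_coefficient(5.0, 1.0, 2.0)

    def test_teer_cases(self):
        assert teer_normalize(100.0, 100.0) == 0.0
        assert teer_normalize(200.0, 100.0, 1.12) == pytest.approx(112.0)

    def test_teer_negative_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert teer_normalize(90.0, 100.0, 1.0) == pytest.approx(-10.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        extra=st.floats(min_value=0.1, max_value=1e4),
        blank=st.floats(min_value=0.0, max_value=1e3),
        area=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_teer_linearity(self, extra, blank, area):
        one = teer_normalize(blank + extra, blank, area)
        two = teer_normalize(blank + 2 * extra, blank, area)
        assert two == pytest.approx(2 * one, rel=1e-9)
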