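import numpy as np
import pytest

from prewetbelt.quantify import (
    belt_length_per_cell,
    fit_hill,
    permeability_ratio,
    segment_condensates,
)
from prewetbelt.synth import (
    TissueConfig,
    generate_belt_mask,
    generate_cyst_image,
    generate_kinetics,
    generate_tissue_movie,
)
from prewetbelt.synth.fixtures import _hill

SMALL = dict(box_um=25.6, n_cells=5, duration=12.0)


class TestTissueMovie:
    def test_deterministic_per_seed(self):
        cfg = TissueConfig(**SMALL)
        m1, k1, t1 = generate_tissue_movie(cfg, seed=4)
        m2, k2, t2 = generate_tissue_movie(cfg, seed=4)
        np.testing.assert_array_equal(m1.stack, m2.stack)
        np.testing.assert_array_equal(k1, k2)
        assert t1.records == t2.records

    def test_mutant_like_class_stays_short(self):
        cfg = TissueConfig(genotype="mutant", **SMALL)
        _, _, truth = generate_tissue_movie(cfg, seed=3)
        for rec in truth.records:
            L = np.asarray(rec["true_length_per_frame"])
            active = L[L > 0]
            if active.size:
                # ground-truth length changes at most by the drawn velocity
                assert np.ptp(active) <= rec["velocity"] * cfg.duration + 1e-9

    def test_condensate_count_matches_recorded_draw(self):
        cfg = TissueConfig(**SMALL)
        _, masks, truth = generate_tissue_movie(cfg, seed=8)
        assert truth.params["n_condensates"] == len(truth.records)
        # every recorded condensate eventually appears in the label masks
        labels_seen = set(np.unique(masks)) - {0}
        assert labels_seen == {r["condensate"] + 1 for r in truth.records}

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            TissueConfig(n_cells=0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_segmentation_finds_condensate_groups(self, seed):
        # the segmenter reports one label per spatially connected group
        # of condensates (physically merged neighbours are one object);
        # oracle: connected components of the ground-truth footprints
        from scipy.ndimage import binary_dilation, label as cc_label

        cfg = TissueConfig(
            box_um=32.0, n_cells=6, duration=12.0,
            nucleation_rate=0.12, nucleation_window=0.25,
        )
        movie, masks, truth = generate_tissue_movie(cfg, seed=seed)
        f = movie.n_frames - 1  # every condensate has nucleated by now
        assert len(truth.records) >= 1
        merged = binary_dilation(masks[f] > 0, iterations=2)
        _, n_groups = cc_label(merged, structure=np.ones((3, 3)))
        labels = segment_condensates(movie.stack[f], rolling_ball_radius=15.0)
        assert labels.max() == n_groups


class TestBeltMask:
    def test_belt_length_recovered_within_5_percent(self):
        cfg = TissueConfig()
        mask, truth = generate_belt_mask(cfg, seed=5)
        per_cell = belt_length_per_cell(
            mask, truth.params["n_cells"], cfg.pixel_size, weighting="calibrated"
        )
        true_per_cell = (
            truth.params["total_belt_length_um"] / truth.params["n_cells"]
        )
        assert per_cell == pytest.approx(true_per_cell, rel=0.05)


class TestKinetics:
    def test_zero_noise_matches_formula(self):
        t, traces, truth = generate_kinetics([12.0], noise_sd=0.0, seed=0)
        rec = truth.records[0]
        expected = _hill(t, rec["base"], rec["amplitude"], rec["hill_n"], 12.0)
        np.testing.assert_allclose(traces[0], expected)

    def test_order_preserved_in_truth(self):
        _, _, truth = generate_kinetics([5.0, 18.0, 35.0], seed=1)
        halves = [r["t_half"] for r in truth.records]
        assert halves == sorted(halves)

    def test_fit_on_noiseless_trace_self_consistent(self):
        t, traces, _ = generate_kinetics([18.0], noise_sd=0.0, seed=0)
        fit = fit_hill(t, traces[0])
        assert fit.ok
        assert fit.t_half == pytest.approx(18.0, abs=1e-5)

    def test_invalid_t_half_rejected(self):
        with pytest.raises(ValueError):
            generate_kinetics([-1.0])


class TestCyst:
    @pytest.mark.parametrize("leak", [0.0, 0.3, 1.0])
    def test_measured_ratio_matches_programmed(self, leak):
        img, lumen, outside, truth = generate_cyst_image(leak, seed=6)
        assert permeability_ratio(img, lumen, outside) == pytest.approx(
            leak, abs=0.02
        )

    def test_out_of_range_leakiness_rejected(self):
        with pytest.raises(ValueError):
            generate_cyst_image(1.2)

    def test_deterministic(self):
        a = generate_cyst_image(0.4, seed=2)[0]
        b = generate_cyst_image(0.4, seed=2)[0]
        np.testing.assert_array_equal(a, b)
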