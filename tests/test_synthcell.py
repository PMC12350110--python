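import numpy as np
import pytest
from scipy import stats

from metquant.synthcell import (PlacementError, SimConfig, simulate_field,
                                simulate_timelapse)


class TestSimConfig:
    def test_fraction_sum_validated(self):
        with pytest.raises(Exception):
            SimConfig(frac_pyroptotic=0.7, frac_apoptotic=0.5)

    def test_stage_probs_must_sum_to_one(self):
        with pytest.raises(Exception):
            SimConfig(staining_stage_probs=(0.5, 0.5, 0.5, 0.5))

    def test_unknown_key_rejected(self):
        with pytest.raises(Exception):
            SimConfig(bogus=1)


class TestSimulateField:
    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_cells=30, field_size_px=(360, 360))
        s1, t1 = simulate_field(cfg, 42)
        s2, t2 = simulate_field(cfg, 42)
        np.testing.assert_array_equal(s1.data, s2.data)
        assert [c.center_x for c in t1.cells] == [c.center_x for c in t2.cells]

    def test_empty_field(self):
        cfg = SimConfig(n_cells=0, field_size_px=(64, 64)).noiseless()
        stack, truth = simulate_field(cfg, 0)
        assert truth.n_cells == 0
        assert np.allclose(stack.data, cfg.background_level)

    def test_all_pyroptotic_nuclei_in_both_dna_channels(self):
        cfg = SimConfig(n_cells=15, field_size_px=(360, 360), frac_pyroptotic=1.0,
                        frac_apoptotic=0.0, frac_met_positive=0.0).noiseless()
        stack, truth = simulate_field(cfg, 1)
        for cell in truth.cells:
            y, x = int(round(cell.center_y)), int(round(cell.center_x))
            assert stack.plane("hoechst")[y, x] > cfg.background_level
            assert stack.plane("sytox")[y, x] > cfg.background_level

    def test_monotone_staging_rendered_before_noise(self, highres_field):
        """A punctum bright in a later-stage channel is bright in all
        earlier-stage channels (nested staining)."""
        cfg, stack, truth = highres_field
        thr = cfg.background_level + cfg.punctum_intensity / 2
        order = ["hoechst", "sytox", "mpo", "cith3"]
        for cell, p in truth.all_puncta():
            y, x = int(round(p.y)), int(round(p.x))
            bright = [stack.plane(ch, p.z)[y, x] > thr for ch in order]
            assert bright == [s <= p.stage for s in (1, 2, 3, 4)]

    def test_rendered_puncta_count_matches_truth(self, highres_field, pipeline_config):
        from metquant.nucgate import count_nuclei
        from metquant.puncta import detect_puncta, find_cell_rois
        cfg, stack, truth = highres_field
        _, _, nlab = count_nuclei(stack.plane("hoechst"), pipeline_config.nuclei)
        _, clab = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        rec, _, n_extra, _ = detect_puncta(stack.plane("hoechst"), nlab, clab,
                                           pipeline_config.puncta)
        assert len(rec) + n_extra == len(truth.all_puncta())

    def test_kappa_zero_angles_uniform(self):
        """With no polarization, punctum angles pass a chi-square uniformity
        test pooled over 10 seeds."""
        angles = []
        cfg = SimConfig.high_res(polarity_kappa=0.0, n_cells=20,
                                 field_size_px=(640, 640)).noiseless()
        for seed in range(10):
            _, truth = simulate_field(cfg.model_copy(update={"psf_sigma_px": 0.0}), seed)
            angles += [p.angle_deg for _, p in truth.all_puncta()]
        counts, _ = np.histogram(angles, bins=8, range=(-180, 180))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            simulate_field(SimConfig(n_cells=500, field_size_px=(128, 128)), 0)

    def test_condensed_nuclei_smaller_and_brighter(self):
        cfg = SimConfig(n_cells=40, field_size_px=(512, 512), frac_apoptotic=0.5,
                        frac_pyroptotic=0.0, frac_met_positive=0.0,
                        nucleus_radius_jitter_px=0.0).noiseless()
        stack, truth = simulate_field(cfg, 3)
        img = stack.plane("hoechst")
        for cell in truth.cells:
            y, x = int(round(cell.center_y)), int(round(cell.center_x))
            center_val = img[y, x] - cfg.background_level
            if cell.condensed:
                assert cell.nucleus_radius_px < cfg.nucleus_radius_px
                assert center_val == pytest.approx(
                    cfg.nucleus_intensity * cfg.condensed_intensity_factor)
            else:
                assert center_val == pytest.approx(cfg.nucleus_intensity)


class TestSimulateTimelapse:
    CFG = SimConfig(n_cells=120, field_size_px=(512, 512), frac_met_positive=0.0)

    def test_frame_count_16h_at_15min(self):
        frames, truth = simulate_timelapse(
            self.CFG.noiseless().model_copy(update={"n_cells": 10}),
            0, interval_h=0.25, duration_h=16.0)
        assert len(frames) == 65
        assert truth.frame_times_h[-1] == pytest.approx(16.0)

    def test_plateau_zero_no_sytox(self):
        frames, truth = simulate_timelapse(
            self.CFG.noiseless().model_copy(update={"n_cells": 10}),
            1, plateau_frac=0.0, duration_h=2.0)
        for f in frames:
            assert np.allclose(f.plane("sytox"), self.CFG.background_level)

    def test_final_dead_fraction_within_binomial_error(self):
        frames, truth = simulate_timelapse(self.CFG.noiseless(), 3,
                                           plateau_frac=0.20, onset_midpoint_h=5.0)
        n = len(truth.death_time_h)
        final = truth.dead_fraction_at(truth.frame_times_h[-1])
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(final - 0.20) <= 3 * sd

    def test_hoechst_only_in_first_frame(self):
        frames, _ = simulate_timelapse(
            self.CFG.noiseless().model_copy(update={"n_cells": 10}),
            2, plateau_frac=0.5, duration_h=2.0)
        assert frames[0].plane("hoechst").max() > self.CFG.background_level
        for f in frames[1:]:
            assert np.allclose(f.plane("hoechst"), self.CFG.background_level)

    def test_invalid_plateau(self):
        with pytest.raises(ValueError):
            simulate_timelapse(self.CFG, 0, plateau_frac=1.5)
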