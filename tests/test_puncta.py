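import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from metquant.imgio import ChannelStack
from metquant.puncta import (ChannelPositivityRule, classify_puncta,
                             detect_puncta, find_cell_rois,
                             puncta_positive_fraction)
from metquant.segment import SegmentParams

PUNCTA_PARAMS = SegmentParams(close_radius_px=0, fill_holes=False, min_area_px=3)


def _toy_cell(shape=(96, 96)):
    """One disk cell with nucleus and a configurable set of puncta."""
    cell_labels = np.zeros(shape, np.int32)
    nuclear = np.zeros(shape, np.int32)
    rr, cc = disk((48, 48), 36, shape=shape)
    cell_labels[rr, cc] = 1
    rr, cc = disk((48, 48), 12, shape=shape)
    nuclear[rr, cc] = 1
    return cell_labels, nuclear


class TestFindCellRois:
    def test_disjoint_cells_contain_their_nuclei(self, highres_field, pipeline_config):
        from metquant.nucgate import count_nuclei
        _, stack, truth = highres_field
        table, labels = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        assert len(table) == truth.n_cells
        for cell in truth.cells:
            y, x = int(round(cell.center_y)), int(round(cell.center_x))
            assert labels[y, x] > 0

    def test_empty_channel_no_rois(self):
        table, labels = find_cell_rois(np.zeros((64, 64)), SegmentParams())
        assert len(table) == 0

    def test_touching_cells_split(self):
        img = np.zeros((100, 100))
        for c in [(50, 35), (50, 65)]:  # distance 30 = 1.5 x radius 20
            rr, cc = disk(c, 20, shape=img.shape)
            img[rr, cc] = 80.0
        table, _ = find_cell_rois(img, SegmentParams(min_area_px=50))
        assert len(table) == 2


class TestDetectPuncta:
    def test_five_puncta_one_cell(self):
        cells, nuc = _toy_cell()
        dna = np.zeros((96, 96))
        spots = [(48, 70), (30, 48), (66, 48), (35, 62), (62, 35)]
        for s in spots:
            rr, cc = disk(s, 2, shape=dna.shape)
            dna[rr, cc] = 200.0
        rec, labels, n_extra, _ = detect_puncta(dna, nuc, cells, PUNCTA_PARAMS)
        assert len(rec) == 5 and n_extra == 0
        assert set(rec["cell_id"]) == {1}

    def test_punctum_inside_nucleus_excluded(self):
        cells, nuc = _toy_cell()
        dna = np.zeros((96, 96))
        rr, cc = disk((48, 48), 2, shape=dna.shape)  # dead center of nucleus
        dna[rr, cc] = 200.0
        rec, labels, n_extra, _ = detect_puncta(dna, nuc, cells, PUNCTA_PARAMS)
        assert len(rec) == 0 and n_extra == 0
        assert labels.max() == 0

    def test_centroid_outside_cells_is_extracellular(self):
        cells, nuc = _toy_cell()
        dna = np.zeros((96, 96))
        rr, cc = disk((5, 5), 2, shape=dna.shape)  # far outside the cell
        dna[rr, cc] = 200.0
        rec, _, n_extra, _ = detect_puncta(dna, nuc, cells, PUNCTA_PARAMS)
        assert len(rec) == 0 and n_extra == 1

    def test_no_detected_punctum_overlaps_nuclear_mask(self, highres_field, pipeline_config):
        from metquant.nucgate import count_nuclei
        _, stack, _ = highres_field
        _, _, nlab = count_nuclei(stack.plane("hoechst"), pipeline_config.nuclei)
        _, clab = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        _, plab, _, _ = detect_puncta(stack.plane("hoechst"), nlab, clab,
                                      pipeline_config.puncta)
        assert not np.logical_and(plab[0] > 0, nlab > 0).any()

    def test_count_conservation(self, highres_field, pipeline_config):
        """Cell-assigned plus extracellular puncta equal all labeled components."""
        from metquant.nucgate import count_nuclei
        _, stack, _ = highres_field
        _, _, nlab = count_nuclei(stack.plane("hoechst"), pipeline_config.nuclei)
        _, clab = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        rec, plab, n_extra, _ = detect_puncta(stack.plane("hoechst"), nlab, clab,
                                              pipeline_config.puncta)
        n_components = len(np.unique(plab)) - 1
        assert len(rec) + n_extra == n_components

    def test_zstack_links_slices(self):
        cells, nuc = _toy_cell()
        dna = np.zeros((3, 96, 96))
        for z in range(3):  # same punctum through all slices
            rr, cc = disk((48, 70), 2, shape=(96, 96))
            dna[z][rr, cc] = 200.0
        rec, _, _, n_per_slice = detect_puncta(dna, nuc, cells, PUNCTA_PARAMS)
        assert len(rec) == 1
        assert n_per_slice == 3


class TestClassifyPuncta:
    def _records_and_stack(self, intensities):
        """One punctum; ``intensities`` gives its per-channel brightness."""
        cells, nuc = _toy_cell()
        data = np.zeros((4, 1, 96, 96))
        rr, cc = disk((48, 70), 2, shape=(96, 96))
        for i, v in enumerate(intensities):
            data[i, 0][cells > 0] = 10.0   # diffuse in-cell level
            data[i, 0][rr, cc] = v
        stack = ChannelStack(data, ("hoechst", "sytox", "mpo", "cith3"))
        # fixed threshold: the diffuse in-cell level would dominate Otsu here
        params = PUNCTA_PARAMS.model_copy(update={"threshold_method": "fixed:100"})
        rec, plab, _, _ = detect_puncta(data[0, 0], nuc, cells, params)
        return rec, plab, stack, cells, nuc

    @pytest.mark.parametrize("intens,expected", [
        ((200, 10, 10, 10), "H"),
        ((200, 200, 10, 10), "H+S"),
        ((200, 200, 200, 10), "H+S+M"),
        ((200, 200, 200, 200), "H+S+M+C"),
        ((200, 10, 200, 10), "other"),
    ])
    def test_combo_classes(self, intens, expected):
        rec, plab, stack, cells, nuc = self._records_and_stack(intens)
        out, fr = classify_puncta(rec, plab, stack, ChannelPositivityRule(),
                                  cell_labels=cells, nuclear_mask=nuc)
        assert out["combo_class"].iloc[0] == expected

    def test_all_channels_saturated_full_class(self):
        rec, plab, stack, cells, nuc = self._records_and_stack((255, 255, 255, 255))
        sat = ChannelStack(np.full_like(stack.data, 255.0), stack.channel_names)
        out, _ = classify_puncta(rec, plab, sat,
                                 ChannelPositivityRule(method="fixed",
                                                       fixed_thresholds={c: 1.0 for c in sat.channel_names}))
        assert (out["combo_class"] == "H+S+M+C").all()

    def test_missing_channel_is_error(self):
        rec, plab, stack, cells, nuc = self._records_and_stack((200, 10, 10, 10))
        bad = ChannelStack(stack.data[:3], ("hoechst", "sytox", "mpo"))
        with pytest.raises(KeyError):
            classify_puncta(rec, plab, bad, ChannelPositivityRule(), cell_labels=cells)

    def test_fraction_table_sums_to_one(self, highres_field, pipeline_config):
        from metquant.nucgate import count_nuclei
        _, stack, _ = highres_field
        _, _, nlab = count_nuclei(stack.plane("hoechst"), pipeline_config.nuclei)
        _, clab = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        rec, plab, _, _ = detect_puncta(stack.plane("hoechst"), nlab, clab,
                                        pipeline_config.puncta)
        _, fr = classify_puncta(rec, plab, stack, ChannelPositivityRule(),
                                cell_labels=clab, nuclear_mask=nlab)
        assert abs(fr.sum() - 1.0) < 1e-9

    def test_no_other_class_in_noiseless_simulation(self, highres_field, pipeline_config):
        from metquant.nucgate import count_nuclei
        _, stack, _ = highres_field
        _, _, nlab = count_nuclei(stack.plane("hoechst"), pipeline_config.nuclei)
        _, clab = find_cell_rois(stack.plane("mpo"), pipeline_config.cells)
        rec, plab, _, _ = detect_puncta(stack.plane("hoechst"), nlab, clab,
                                        pipeline_config.puncta)
        out, fr = classify_puncta(rec, plab, stack, ChannelPositivityRule(),
                                  cell_labels=clab, nuclear_mask=nlab)
        assert (out["combo_class"] != "other").all()


class TestPositiveFraction:
    def test_every_cell_positive(self):
        rec = pd.DataFrame({"cell_id": [1, 2, 3, 3]})
        assert puncta_positive_fraction(rec, 3) == 100.0

    def test_no_puncta(self):
        rec = pd.DataFrame({"cell_id": pd.Series(dtype=int)})
        assert puncta_positive_fraction(rec, 10) == 0.0

    def test_zero_cells_error(self):
        with pytest.raises(ValueError):
            puncta_positive_fraction(pd.DataFrame({"cell_id": []}), 0)
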