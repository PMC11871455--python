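"""Registration, C/N measurement and trace extraction against ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import ktrkit as k
from ktrkit.imaging import shift_integer
from ktrkit.quantification import estimate_background
from ktrkit.segmentation import disk_mask

from conftest import match_cells, sensor_with_score


class TestMeasureCn:
    def test_textbook_arithmetic(self):
        frame = np.zeros((20, 20))
        nuc = disk_mask((20, 20), (6, 6), 3)
        cyto = disk_mask((20, 20), (14, 14), 3)
        frame[nuc] = 40.0
        frame[cyto] = 80.0
        m = k.measure_cn(frame, nuc, cyto, background=20.0)
        assert m.cn_ratio == pytest.approx(3.0)
        assert m.c_over_total == pytest.approx(0.75)

    def test_equal_compartments_give_unity(self):
        frame = np.full((10, 10), 55.0)
        nuc = np.zeros((10, 10), bool); nuc[2:4, 2:4] = True
        cyto = np.zeros((10, 10), bool); cyto[6:8, 6:8] = True
        assert k.measure_cn(frame, nuc, cyto).cn_ratio == pytest.approx(1.0)

    def test_empty_roi_is_an_error(self):
        frame = np.ones((10, 10))
        with pytest.raises(ValueError, match="empty"):
            k.measure_cn(frame, np.zeros((10, 10), bool), np.ones((10, 10), bool))

    def test_oversubtracted_measurement_flagged_invalid(self):
        frame = np.full((10, 10), 30.0)
        nuc = np.zeros((10, 10), bool); nuc[2:4, 2:4] = True
        cyto = np.zeros((10, 10), bool); cyto[6:8, 6:8] = True
        m = k.measure_cn(frame, nuc, cyto, background=50.0)
        assert not m.valid
        assert np.isnan(m.cn_ratio)

    def test_ratio_and_bounded_metric_are_consistent_bijections(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c, n = rng.uniform(1, 200, 2)
            m = k.CnMeasurement(cell_id=1, frame=0, c_mean=c, n_mean=n)
            assert m.cn_ratio == pytest.approx(
                m.c_over_total / (1 - m.c_over_total), abs=1e-12, rel=1e-12
            )

    def test_invariant_to_shared_offset_supplied_as_background(self):
        frame = np.zeros((12, 12))
        nuc = np.zeros((12, 12), bool); nuc[2:5, 2:5] = True
        cyto = np.zeros((12, 12), bool); cyto[7:10, 7:10] = True
        frame[nuc] = 40.0
        frame[cyto] = 90.0
        base = k.measure_cn(frame, nuc, cyto, background=0.0)
        shifted = k.measure_cn(frame + 25.0, nuc, cyto, background=25.0)
        assert shifted.cn_ratio == pytest.approx(base.cn_ratio, rel=1e-12)


class TestRegisterStack:
    def test_zero_drift_gives_zero_offsets_and_idempotence(self, small_experiment):
        _, field, _ = small_experiment
        offsets, corrected = k.register_stack(field.stack, "ER_marker")
        assert np.all(offsets == 0)
        offsets2, _ = k.register_stack(corrected, "ER_marker")
        assert np.all(offsets2 == 0)

    def test_random_walk_drift_recovered_within_one_pixel(self):
        cfg = k.ExperimentConfig(
            seed=13, n_fields=1, n_cells=8, n_frames=15, field_px=(256, 256),
            drift_step_sigma=1.5, drift_max_px=10,
        )
        (field,), _ = k.run_experiment(cfg)
        offsets, _ = k.register_stack(field.stack, "ER_marker")
        assert np.abs(offsets - field.ground_truth.drift).max() <= 1

    def test_featureless_stack_warns_and_assumes_zero(self):
        pixels = np.full((1, 3, 32, 32), 100, dtype=np.uint16)
        stack = k.ImageStack(pixels=pixels, channel_names=["ER_marker"])
        with pytest.warns(UserWarning, match="featureless"):
            offsets, _ = k.register_stack(stack, "ER_marker")
        assert np.all(offsets == 0)


class TestExtractTraces:
    def _labels(self, field):
        marker = field.stack.channel("ER_marker")[0]
        return k.derive_compartments(k.segment_nuclei(marker), marker)

    def test_noise_free_cn_matches_ground_truth(self, clean_experiment):
        _, field, _ = clean_experiment
        gt = field.ground_truth
        labels = self._labels(field)
        traces = k.extract_traces(field.stack, labels, "KTR_PKA", background_mode="mode")
        mapping = match_cells(labels, gt)
        rel = []
        for tr in traces:
            gi = gt.cell_ids.index(mapping[tr.cell_id])
            rel.extend(np.abs(tr.cn_ratio - gt.cn["KTR_PKA"][gi]) / gt.cn["KTR_PKA"][gi])
        assert np.median(rel) < 0.01

    def test_static_cells_all_valid(self, small_experiment):
        _, field, _ = small_experiment
        labels = self._labels(field)
        traces = k.extract_traces(field.stack, labels, "KTR_PKA")
        assert traces and all(tr.valid for tr in traces)

    def test_cell_leaving_its_region_is_flagged(self, small_experiment):
        """Blank one cell's pixels in the last frames: its trace is invalid,
        the others are untouched."""
        _, field, _ = small_experiment
        labels = self._labels(field)
        doomed = labels.cell_ids[0]
        region = (labels.nucleus_labels == doomed) | (labels.cytoplasm_labels == doomed)
        pixels = field.stack.pixels.copy()
        bg = int(estimate_background(pixels[0, -1], labels))
        for c in range(pixels.shape[0]):
            frame = pixels[c, -1].copy()
            frame[region] = bg
            pixels[c, -1] = frame
        stack = k.ImageStack(pixels=pixels, channel_names=list(field.stack.channel_names))
        traces = k.extract_traces(stack, labels, "KTR_PKA")
        by_id = {tr.cell_id: tr for tr in traces}
        assert not by_id[doomed].valid
        assert all(tr.valid for cid, tr in by_id.items() if cid != doomed)

    def test_roi_disk_mode_agrees_with_mask_mode(self, clean_experiment):
        _, field, _ = clean_experiment
        labels = self._labels(field)
        pairs = k.place_roi_pairs(labels, radius_px=4, rng_seed=3)
        disk_traces = k.extract_traces(field.stack, labels, "KTR_PKA", roi_pairs=pairs)
        mask_traces = {t.cell_id: t for t in k.extract_traces(field.stack, labels, "KTR_PKA")}
        for tr in disk_traces:
            # noise-free: disks sample the same uniform compartment value
            assert np.allclose(tr.cn_ratio, mask_traces[tr.cell_id].cn_ratio, rtol=0.02)

    def test_agonist_response_trace_rises_to_plateau(self):
        cfg = k.ExperimentConfig(
            seed=31, n_fields=1, n_cells=8, n_frames=30, field_px=(256, 256),
            sensors=[sensor_with_score(10.5)],
            schedule=[k.TreatmentEvent(time_min=3.0, agent="Fsk", dose=10.0, dose_unit="uM")],
        )
        (field,), _ = k.run_experiment(cfg)
        labels = self._labels(field)
        traces = k.extract_traces(field.stack, labels, "KTR_PKA")
        mean_cn = np.nanmean([tr.cn_ratio for tr in traces], axis=0)
        # near-monotone rise from agonist to plateau (tolerate noise blips)
        post = mean_cn[3:]
        assert post[-1] > 1.5 * mean_cn[:3].mean()
        diffs = np.diff(post)
        assert (diffs > -0.05 * post.max()).all()


class TestNormalizeStain:
    def test_control_population_normalises_to_unit_mean(self):
        rng = np.random.default_rng(1)
        control = rng.uniform(50, 150, 40)
        out = k.normalize_stain(control, control.mean())
        assert out.mean() == pytest.approx(1.0)

    def test_double_intensity_maps_to_two(self):
        assert k.normalize_stain(np.array([200.0]), 100.0)[0] == pytest.approx(2.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            k.normalize_stain(np.array([1.0]), 0.0)

    def test_stain_and_cn_correlate_through_shared_activity(self, params):
        """Cells with higher kinase activity show both more phospho-stain and a
        higher C/N: rank correlation on a shared latent activity > 0.9.

        Activities are drawn from the graded (sub-saturating) regime; at
        saturating activity the Michaelian phospho-cycle flattens C/N and
        rank information is lost by construction.
        """
        rng = np.random.default_rng(7)
        sensor = sensor_with_score(10.5)
        activity = rng.uniform(0.0, 0.2, 60)
        stain = 100.0 * (0.2 + activity) * rng.lognormal(0, 0.05, 60)
        cn = np.array([k.steady_state_cn(sensor, a, params) for a in activity])
        cn *= rng.lognormal(0, 0.05, 60)
        norm = k.normalize_stain(stain, stain.mean())
        rho = spearmanr(norm, cn).statistic
        assert rho > 0.9


def test_shift_integer_round_trips_interior_content():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 100, (32, 32))
    back = shift_integer(shift_integer(img, 4, -3), -4, 3)
    assert np.array_equal(back[8:-8, 8:-8], img[8:-8, 8:-8])
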