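"""Generator contracts: forward-model inversion, determinism, ground truth."""

import numpy as np
import pytest

from isoipipe.orchestration import process_block
from isoipipe.protocols import CONDENSED, INITIAL_DIP, OVERSHOOT, SPARSE
from isoipipe.ratio import select_phase_frame
from isoipipe.synthetic import (
    SignalGroundTruth,
    StudyDesign,
    TtcGroundTruth,
    make_block,
    make_study,
    make_trial_stack,
    make_ttc_series,
    sample_group_outcomes,
    temporal_kernel,
)

SHAPE = (64, 64)
FULL = np.ones(SHAPE, dtype=bool)


def quiet_truth(**kw):
    kw.setdefault("center", (32, 32))
    kw.setdefault("noise_sd", 0.0)
    return SignalGroundTruth(**kw)


class TestTrialStack:
    def test_silent_truth_gives_static_frames(self):
        truth = quiet_truth(dip_amp=0.0, overshoot_amp=0.0, undershoot_amp=0.0)
        stack = make_trial_stack(SPARSE, truth, seed=1)
        assert np.array_equal(stack.frames[0], stack.frames[-1])
        assert np.all(stack.frames[10] == stack.frames[50])

    def test_sparse_duration_and_onset(self):
        stack = make_trial_stack(SPARSE, quiet_truth(), seed=1)
        assert stack.n_frames == 160  # 16 s at 100 ms
        assert stack.onset_frame == 15  # 1.5 s pre-stimulus
        cond = make_trial_stack(CONDENSED, quiet_truth(), seed=1)
        assert cond.n_frames == 45  # 4.5 s

    def test_forward_model_inversion_noise_free(self):
        """The downstream ratio pipeline reads back the dip amplitude at the
        blob centre at the kernel plateau, to within float32 round-off."""
        truth = quiet_truth(dip_amp=-5e-4)
        series = process_block([make_trial_stack(SPARSE, truth, seed=0)])
        k = select_phase_frame(series, INITIAL_DIP, FULL)
        assert abs(series.times_s[k] - 2.5) <= 0.5
        assert series.fc_frames[k, 32, 32] == pytest.approx(-5e-4, abs=1e-6)
        k2 = select_phase_frame(series, OVERSHOOT, FULL)
        assert abs(series.times_s[k2] - 5.0) <= 0.5
        assert series.fc_frames[k2, 32, 32] == pytest.approx(7e-4, abs=1e-6)

    def test_block_mask_zeroes_signal(self):
        bm = np.zeros(SHAPE, dtype=bool)
        bm[20:45, 20:45] = True
        series = process_block(
            [make_trial_stack(SPARSE, quiet_truth(block_mask=bm), seed=0)]
        )
        assert np.all(np.abs(series.fc_frames[:, 20:45, 20:45]) < 1e-6)

    def test_block_mask_shape_mismatch(self):
        bm = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError):
            make_trial_stack(SPARSE, quiet_truth(block_mask=bm), seed=0)

    def test_invalid_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            SignalGroundTruth(dip_amp=+1e-4)
        with pytest.raises(ValueError):
            SignalGroundTruth(dip_amp=-0.5)  # beyond physiological scale
        with pytest.raises(ValueError):
            SignalGroundTruth(dip_peak_s=6.0, overshoot_peak_s=5.0)

    def test_condensed_kernel_plateau_in_quant_window(self):
        t = np.array([0.75])
        truth = quiet_truth(dip_amp=-4e-4)
        assert temporal_kernel(truth, t, "condensed")[0] == pytest.approx(-4e-4)


class TestMakeBlock:
    def test_block_size_and_determinism(self):
        truth = quiet_truth(noise_sd=1e-4)
        a = make_block(CONDENSED, truth, n_trials=3, seed=5)
        b = make_block(CONDENSED, truth, n_trials=3, seed=5)
        assert len(a) == 3
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.frames, s2.frames)
        # trials differ from each other
        assert not np.array_equal(a[0].frames, a[1].frames)

    def test_trial_averaging_shrinks_noise(self):
        truth = quiet_truth(
            dip_amp=0.0, overshoot_amp=0.0, undershoot_amp=0.0, noise_sd=1e-3
        )
        n = 40
        block = make_block(CONDENSED, truth, n_trials=n, seed=7, shape=(16, 16))
        single = process_block(block[:1]).fc_frames.std()
        avg = process_block(block).fc_frames.std()
        assert avg == pytest.approx(single / np.sqrt(n), rel=0.2)

    def test_bad_n_trials(self):
        with pytest.raises(ValueError):
            make_block(SPARSE, quiet_truth(), n_trials=0, seed=1)


class TestTtcSeries:
    def test_empty_infarct_no_white_pixels(self):
        slices, rec = make_ttc_series(TtcGroundTruth(), seed=1)
        assert rec["raw_volume_mm3"] == 0.0
        assert all(n == 0 for n in rec["infarct_px"])

    def test_edema_one_means_equal_hemispheres(self):
        _, rec = make_ttc_series(TtcGroundTruth(edema_factor=1.0), seed=2)
        assert rec["ipsi_px"] == rec["contra_px"]

    def test_edema_scales_ipsi_area(self):
        _, rec = make_ttc_series(TtcGroundTruth(edema_factor=1.2), seed=2)
        ratio = rec["ipsi_px"][0] / rec["contra_px"][0]
        assert ratio == pytest.approx(1.2, rel=0.02)

    def test_explicit_mask_pixel_count_to_area(self):
        mask = np.zeros((120, 160), dtype=bool)
        mask[40:60, 100:125] = True  # 500 px in the right hemisphere
        truth = TtcGroundTruth(n_slices=1, infarct_masks=[mask])
        slices, rec = make_ttc_series(truth, seed=3)
        assert rec["infarct_px"][0] == 500
        # downstream: 500 px at 0.1 mm/px -> 5 mm^2 per slice
        assert rec["raw_volume_mm3"] == pytest.approx(500 * 0.1**2 * 2.0)

    def test_contralateral_mask_rejected(self):
        mask = np.zeros((120, 160), dtype=bool)
        mask[40:60, 30:40] = True  # left hemisphere
        with pytest.raises(ValueError):
            make_ttc_series(TtcGroundTruth(n_slices=1, infarct_masks=[mask]), seed=1)

    def test_edema_below_one_rejected(self):
        with pytest.raises(ValueError):
            TtcGroundTruth(edema_factor=0.9)


class TestStudyDesign:
    def test_forty_animals_in_five_groups(self):
        study = make_study(StudyDesign(), seed=3)
        assert len(study.animals) == 40
        assert study.truth.groupby("group").size().to_dict() == {g: 8 for g in range(1, 6)}

    def test_wrong_group_count_rejected(self):
        from isoipipe.synthetic import DEFAULT_GROUPS

        groups = {k: v for k, v in DEFAULT_GROUPS.items() if k < 5}
        with pytest.raises(ValueError):
            StudyDesign(groups=groups)

    def test_outcome_rules(self):
        d = StudyDesign()
        for g, expect_affected in ((1, False), (2, False), (3, True), (4, True), (5, True)):
            outs = sample_group_outcomes(d, g, 20, seed=11)
            assert all(o["affected"] == expect_affected for o in outs)
        assert all(o["infarct_volume_mm3"] == 0 for o in sample_group_outcomes(d, 1, 20, 1))

    def test_group4_volume_linear_in_slit(self):
        d = StudyDesign()
        outs = sample_group_outcomes(d, 4, 200, seed=13)
        x = np.array([o["slit_size_mm2"] for o in outs])
        y = np.array([o["infarct_volume_mm3"] for o in outs])
        slope = np.polyfit(x, y, 1)[0]
        se = d.infarct_noise_sd / (x.std() * np.sqrt(len(x)))
        assert abs(slope - d.infarct_slope) < 2 * se

    def test_group5_mixture_weights(self):
        """Bimodal group-5 infarct: the extended-mode fraction matches the
        mixture weight within binomial sampling error at n=400, and the
        localized / extended volume components stay well separated."""
        d = StudyDesign()
        outs = sample_group_outcomes(d, 5, 400, seed=17)
        vols = np.array([o["infarct_volume_mm3"] for o in outs])
        ext = np.array([o["extended_infarct"] for o in outs])
        assert abs(ext.mean() - d.group5_extended_p) < 2.5 * np.sqrt(0.25 / 400)
        assert vols[~ext].max() < 12.0 < vols[ext].min()
        assert (vols > 0).all()  # every group-5 animal carries an infarct

    def test_study_determinism(self):
        d = StudyDesign()
        s1, s2 = make_study(d, 23), make_study(d, 23)
        assert s1.truth.equals(s2.truth)
        a1, a2 = s1.artifacts("A05"), s2.artifacts("A05")
        key = ("condensed", "h24")
        assert np.array_equal(a1.blocks[key][0].frames, a2.blocks[key][0].frames)
        assert np.array_equal(a1.ttc_slices[0].image, a2.ttc_slices[0].image)

    def test_group1_24h_blocks_not_attenuated(self):
        """Control animals keep the same generating truth at both timepoints."""
        study = make_study(StudyDesign(), seed=29)
        row = study.truth.set_index("animal").loc["A01"]
        assert row["group"] == 1 and not row["affected"]
        art = study.artifacts("A01")
        base = process_block(art.blocks[("sparse", "baseline")])
        h24 = process_block(art.blocks[("sparse", "h24")])
        k = select_phase_frame(base, INITIAL_DIP, FULL)
        c = (int(row["center_row"]), int(row["center_col"]))
        assert h24.fc_frames[k][c] == pytest.approx(base.fc_frames[k][c], abs=3e-4)

    def test_affected_animal_blocked_inside_roi(self):
        study = make_study(StudyDesign(), seed=29)
        g4 = study.truth[study.truth["group"] == 4].iloc[0]["animal"]
        art = study.artifacts(g4)
        h24 = process_block(art.blocks[("sparse", "h24")])
        k = 4  # nominal dip plateau frame
        inside = h24.fc_frames[k][art.rois.analysis_roi]
        # residual inside the ROI is pure noise, far below threshold on average
        assert np.abs(inside.mean()) < 1e-4
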