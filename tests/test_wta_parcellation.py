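import numpy as np
import pytest

from thalcon.core_io import ROI_NAMES, LabelVolume, SubjectRecord, Volume4D
from thalcon.hemisphere_align import flip_lr
from thalcon.signal_clean import ConfoundSet, clean_pipeline
from thalcon.synthetic_cohort import make_phantom, plan_cohort, iter_subject_data, simulate_subject
from thalcon.wta_parcellation import (
    CorrelationMaps,
    cortical_roi_timeseries,
    group_wta,
    render_confidence,
    roi_mean_timeseries,
    subregion_summary,
    voxel_cortex_correlations,
    winner_take_all,
)


def _cm(r, affine=None, shape=(4, 4, 4)):
    r = np.asarray(r, dtype=float)
    idx = np.argwhere(np.ones(shape))[: len(r)]
    return CorrelationMaps(r=r, voxel_index=idx, affine=affine or np.eye(4),
                           shape3=shape)


class TestRoiMean:
    def test_single_voxel_mask(self, rng):
        vol = Volume4D(rng.standard_normal((4, 4, 4, 10)), np.eye(4), 2.0)
        mask = np.zeros((4, 4, 4), dtype=int)
        mask[1, 2, 3] = 1
        out = roi_mean_timeseries(vol, LabelVolume(mask, np.eye(4)))
        np.testing.assert_array_equal(out, vol.data[1, 2, 3])

    def test_opposite_series_cancel(self):
        data = np.zeros((2, 1, 1, 8))
        s = np.sin(np.arange(8.0))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        vol = Volume4D(data, np.eye(4), 2.0)
        mask = LabelVolume(np.ones((2, 1, 1), dtype=int), np.eye(4))
        np.testing.assert_allclose(roi_mean_timeseries(vol, mask), 0.0)

    def test_empty_mask_rejected(self, rng):
        vol = Volume4D(rng.standard_normal((2, 2, 2, 5)), np.eye(4), 2.0)
        with pytest.raises(ValueError, match="empty"):
            roi_mean_timeseries(vol, LabelVolume(np.zeros((2, 2, 2), int), np.eye(4)))

    def test_phantom_roi_tracks_latent_source(self, noisefree_subject,
                                              truth16_noisefree):
        """At high SNR the ROI mean recovers the generator's latent source."""
        for i, name in enumerate(ROI_NAMES):
            ts = roi_mean_timeseries(noisefree_subject.volume,
                                     truth16_noisefree.cortical_masks[name])
            r = np.corrcoef(ts, noisefree_subject.sources[:, i])[0, 1]
            assert r > 0.95


class TestVoxelCortexCorrelations:
    def test_voxel_equal_to_roi_series(self, rng):
        t = 40
        cortex = rng.standard_normal((t, 6))
        data = rng.standard_normal((3, 3, 3, t))
        data[0, 0, 0] = cortex[:, 1]  # voxel copies ROI-2 series
        vol = Volume4D(data, np.eye(4), 2.0)
        thal = np.zeros((3, 3, 3), int)
        thal[0, 0, 0] = 1
        cm = voxel_cortex_correlations(vol, LabelVolume(thal, np.eye(4)), cortex)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert np.all(cm.r[0, [0, 2, 3, 4, 5]] < 0.999)

    def test_matches_per_voxel_loop_oracle(self, rng):
        t = 30
        cortex = rng.standard_normal((t, 6))
        vol = Volume4D(rng.standard_normal((4, 4, 4, t)), np.eye(4), 2.0)
        thal = LabelVolume((rng.random((4, 4, 4)) < 0.4).astype(int), np.eye(4))
        cm = voxel_cortex_correlations(vol, thal, cortex)
        for row, (i, j, k) in zip(cm.r, cm.voxel_index):
            for c in range(6):
                expected = np.corrcoef(vol.data[i, j, k], cortex[:, c])[0, 1]
                assert row[c] == pytest.approx(expected, abs=1e-12)

    def test_noise_voxel_has_small_r(self, rng):
        t = 200
        cortex = rng.standard_normal((t, 6))
        vol = Volume4D(rng.standard_normal((2, 2, 2, t)), np.eye(4), 2.0)
        thal = LabelVolume(np.ones((2, 2, 2), int), np.eye(4))
        cm = voxel_cortex_correlations(vol, thal, cortex)
        assert np.abs(cm.r).max() < 0.25

    def test_zero_variance_voxel_warns_and_zeroes(self, rng):
        t = 30
        cortex = rng.standard_normal((t, 6))
        data = rng.standard_normal((2, 2, 2, t))
        data[0, 0, 0] = 3.0
        vol = Volume4D(data, np.eye(4), 2.0)
        thal = LabelVolume(np.ones((2, 2, 2), int), np.eye(4))
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = voxel_cortex_correlations(vol, thal, cortex)
        np.testing.assert_array_equal(cm.r[0], 0.0)


class TestWinnerTakeAll:
    def test_simple_row(self):
        wta = winner_take_all(_cm([[0.1, 0.5, 0.2, 0.0, -0.1, 0.3]]))
        assert wta.label[0] == 2
        assert wta.winning_r[0] == pytest.approx(0.5)

    def test_tie_breaks_to_lowest_index(self):
        wta = winner_take_all(_cm([[0.4, 0.4, 0, 0, 0, 0]]))
        assert wta.label[0] == 1

    def test_nonpositive_max_unassigned(self):
        wta = winner_take_all(_cm([[-0.2, -0.1, -0.5, -0.9, -0.3, -0.4]]))
        assert wta.label[0] == 0
        assert wta.winning_r[0] == pytest.approx(-0.1)

    def test_noise_free_subject_recovers_truth(self, truth16_noisefree,
                                               noisefree_subject):
        for side in ("left", "right"):
            cortex = cortical_roi_timeseries(noisefree_subject.volume,
                                             truth16_noisefree.cortical_masks)
            cm = voxel_cortex_correlations(
                noisefree_subject.volume,
                truth16_noisefree.thalamus_masks[side], cortex)
            wta = winner_take_all(cm)
            np.testing.assert_array_equal(
                wta.label, truth16_noisefree.assignment_vector(side))

    def test_roi_permutation_equivariance(self, rng):
        r = rng.uniform(0.05, 0.9, size=(20, 6))
        perm = np.array([3, 0, 5, 1, 4, 2])
        base = winner_take_all(_cm(r, shape=(20, 1, 1)))
        permuted = winner_take_all(_cm(r[:, perm], shape=(20, 1, 1)))
        # label k in the permuted map corresponds to perm[k-1]+1 in the base
        assert np.array_equal(perm[permuted.label - 1] + 1, base.label)


class TestGroupWta:
    def test_single_subject_identity(self, rng):
        r = rng.uniform(0.1, 0.9, (15, 6))
        cm = _cm(r, shape=(15, 1, 1))
        solo = winner_take_all(cm)
        group = group_wta([cm])
        np.testing.assert_array_equal(group.label, solo.label)
        np.testing.assert_allclose(group.winning_r, solo.winning_r, atol=1e-12)
        np.testing.assert_array_equal(group.agreement, 1.0)

    def test_identical_subjects(self, rng):
        r = rng.uniform(0.1, 0.9, (15, 6))
        cms = [_cm(r.copy(), shape=(15, 1, 1)) for _ in range(5)]
        group = group_wta(cms)
        np.testing.assert_array_equal(group.label,
                                      winner_take_all(cms[0]).label)
        np.testing.assert_array_equal(group.agreement, 1.0)

    def test_vote_rule(self, rng):
        r = rng.uniform(0.1, 0.9, (15, 6))
        cms = [_cm(r.copy(), shape=(15, 1, 1)) for _ in range(5)]
        avg = group_wta(cms, method="average")
        vote = group_wta(cms, method="vote")
        np.testing.assert_array_equal(avg.label, vote.label)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_wta([])

    def test_recovery_monotone_in_noise(self, control_record):
        """Group recovery accuracy does not improve as noise grows.

        The signal amplitude is held at the level solved for noise_sd=0.5
        (weight_noise_sd) so that increasing noise_sd degrades the data
        rather than being compensated by larger mixing weights.
        """
        fractions = []
        for noise_sd in (0.5, 2.0, 8.0):
            truth = make_phantom(grid_shape=(16, 16, 16), noise_sd=noise_sd,
                                 weight_noise_sd=0.5)
            cms = []
            for s in range(6):
                sub = simulate_subject(truth, control_record, n_timepoints=80,
                                       seed=900 + s)
                cortex = cortical_roi_timeseries(sub.volume, truth.cortical_masks)
                cms.append(voxel_cortex_correlations(
                    sub.volume, truth.thalamus_masks["left"], cortex))
            group = group_wta(cms)
            fractions.append(
                (group.label == truth.assignment_vector("left")).mean())
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[0] > 0.9

    def test_group_map_symmetry(self, truth16):
        """Contralesional map equals the flipped ipsilesional map on the
        symmetric phantom (>= 90% of voxels)."""
        plan = plan_cohort(truth16, n_patients=0, n_controls=8, seed=5)
        cms = {"left": [], "right": []}
        for rec, sub in iter_subject_data(truth16, plan, n_timepoints=100):
            cortex = cortical_roi_timeseries(sub.volume, truth16.cortical_masks)
            for side in ("left", "right"):
                cms[side].append(voxel_cortex_correlations(
                    sub.volume, truth16.thalamus_masks[side], cortex, side=side))
        left = group_wta(cms["left"]).to_label_volume()
        right = group_wta(cms["right"]).to_label_volume()
        flipped = flip_lr(left)
        sel = right.data > 0
        assert (flipped.data[sel] == right.data[sel]).mean() >= 0.90


class TestRenderConfidence:
    def test_peak_and_half_peak(self):
        wta = winner_take_all(_cm([[0.8, 0, 0, 0, 0, 0],
                                   [0.4, 0, 0, 0, 0, 0],
                                   [0.6, 0, 0, 0, 0, 0]], shape=(3, 1, 1)))
        disp = render_confidence(wta)
        assert disp[0] == pytest.approx(100.0)
        assert disp[1] == pytest.approx(50.0)  # half the ROI max -> floor
        assert disp[2] == pytest.approx(75.0)

    def test_monotone_within_roi(self, rng):
        r = np.zeros((30, 6))
        r[:, 2] = rng.uniform(0.01, 0.99, 30)
        wta = winner_take_all(_cm(r, shape=(30, 1, 1)))
        disp = render_confidence(wta)
        order = np.argsort(wta.winning_r)
        assert np.all(np.diff(disp[order]) >= -1e-12)


class TestSummary:
    def test_labels_partition_thalamus(self, truth16, small_subject):
        cortex = cortical_roi_timeseries(small_subject.volume,
                                         truth16.cortical_masks)
        cm = voxel_cortex_correlations(small_subject.volume,
                                       truth16.thalamus_masks["left"], cortex)
        wta = winner_take_all(cm)
        assert set(np.unique(wta.label)) <= set(range(7))
        assert len(wta.label) == truth16.thalamus_masks["left"].mask().sum()
        summary = subregion_summary(wta)
        assert summary["n_voxels"].sum() == len(wta.label)
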