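"""GLM activation, conjunction ROI, ILC, MVLC similarity, and ROI-to-ROI FC."""

import numpy as np
import pytest

from engramflow import bold_features as bf
from engramflow.errors import DegenerateDataError, EmptyRoiError, InputError


def ilc_oracle(data, voxel_size, kernel_mm):
    """Naive double-loop ILC: for every voxel, walk every other voxel."""
    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1]).astype(float)
    coords = np.array(np.unravel_index(np.arange(flat.shape[0]), shape)).T
    out = np.zeros(flat.shape[0])
    for v in range(flat.shape[0]):
        num = den = 0.0
        for u in range(flat.shape[0]):
            if u == v:
                continue
            d = voxel_size * np.linalg.norm(coords[u] - coords[v])
            if d > 3.0 * kernel_mm + 1e-12:
                continue
            w = np.exp(-d ** 2 / (2.0 * kernel_mm ** 2))
            sa, sb = flat[v].std(), flat[u].std()
            corr = 0.0
            if sa > 0 and sb > 0:
                corr = np.corrcoef(flat[v], flat[u])[0, 1]
            num += w * corr
            den += w
        out[v] = num / den if den > 0 else 0.0
    return out.reshape(shape)


def _run(data, voxel_size=1.6):
    return bf.BoldRun(data=data, tr=1.0, condition="test", voxel_size=voxel_size)


class TestHrfAndGlm:
    def test_hrf_peaks_early_and_undershoots(self):
        h = bf.double_gamma_hrf(tr=0.5)
        t = np.arange(len(h)) * 0.5
        assert 4.0 <= t[np.argmax(h)] <= 7.0
        assert h.min() < 0  # undershoot
        assert h.max() == pytest.approx(1.0)

    def test_planted_late_block_voxel_detected(self, rng):
        tr, n_vols = 1.0, 200
        onsets = [10.0, 60.0, 110.0, 160.0]
        durations = [20.0] * 4
        reg = bf._convolved_boxcar(onsets[2:], durations[2:], n_vols, tr)
        data = rng.standard_normal((4, 4, 4, n_vols)) * 0.1
        data[1, 1, 1] += 5.0 * reg
        out = bf.glm_activation(_run(data), onsets, durations, early_blocks=(0, 1))
        assert out["z_late"][1, 1, 1] > 3.1
        assert abs(out["z_late"][3, 3, 3]) < 2.5

    def test_permuting_volumes_destroys_activation(self, rng):
        tr, n_vols = 1.0, 200
        onsets, durations = [20.0, 120.0], [30.0, 30.0]
        reg = bf._convolved_boxcar(onsets, durations, n_vols, tr)
        data = rng.standard_normal((3, 3, 3, n_vols)) * 0.1
        data[1, 1, 1] += 3.0 * reg
        perm = rng.permutation(n_vols)
        out = bf.glm_activation(_run(data[..., perm]), onsets, durations,
                                early_blocks=(0,))
        assert abs(out["z_late"][1, 1, 1]) < 2.0

    def test_zero_variance_voxel_gets_zero_z(self, rng):
        data = rng.standard_normal((3, 3, 3, 60))
        data[0, 0, 0] = 0.0
        out = bf.glm_activation(_run(data), [5.0, 30.0], [10.0, 10.0],
                                early_blocks=(0,))
        assert out["z_late"][0, 0, 0] == 0.0

    def test_rank_deficient_design_names_columns(self, rng):
        data = rng.standard_normal((2, 2, 2, 60))
        with pytest.raises(InputError, match="early"):
            # no block assigned early -> the early regressor is identically zero
            bf.glm_activation(_run(data), [10.0], [20.0], early_blocks=())


class TestConjunctionRoi:
    def test_identical_maps_idempotent(self, rng):
        z = rng.standard_normal((6, 6, 6)) * 2
        mask = bf.conjunction_roi(z, z)
        assert (mask == (z > 3.1)).all() or mask.any()

    def test_disjoint_maps_raise(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 5.0
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 5.0
        with pytest.raises(EmptyRoiError, match="1 voxels"):
            bf.conjunction_roi(a, b)

    def test_planted_cube_recovered(self, rng):
        shape = (12, 12, 12)
        truth = np.zeros(shape, bool)
        truth[4:7, 4:7, 4:7] = True
        z1 = rng.standard_normal(shape) + truth * 8.0
        z2 = rng.standard_normal(shape) + truth * 8.0
        mask = bf.conjunction_roi(z1, z2, min_cluster=2)
        recovered = (mask & truth).sum() / truth.sum()
        false_rate = (mask & ~truth).sum() / max(mask.sum(), 1)
        assert recovered >= 0.9
        assert false_rate <= 0.05


class TestComputeIlc:
    def test_shared_timecourse_gives_unit_ilc(self, rng):
        ts = rng.standard_normal(60)
        data = np.tile(ts, (5, 5, 5, 1))
        ilc = bf.compute_ilc(_run(data))
        assert ilc == pytest.approx(np.ones_like(ilc))

    def test_iid_noise_has_zero_mean_ilc(self, rng):
        means = [bf.compute_ilc(_run(rng.standard_normal((8, 8, 8, 80)))).mean()
                 for _ in range(20)]
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * max(se, 1e-4)

    def test_matches_double_loop_oracle(self, rng):
        data = rng.standard_normal((5, 5, 5, 40))
        fast = bf.compute_ilc(_run(data))
        slow = ilc_oracle(data, 1.6, 1.0)
        assert np.abs(fast - slow).max() < 1e-10

    def test_roi_restriction_equals_full_map_on_roi(self, rng):
        data = rng.standard_normal((10, 10, 10, 40))
        roi = np.zeros((10, 10, 10), bool)
        roi[3:7, 3:7, 3:7] = True
        full = bf.compute_ilc(_run(data))
        cropped = bf.compute_ilc(_run(data), roi=roi)
        assert np.abs(full[roi] - cropped[roi]).max() == 0.0

    def test_zero_variance_voxel_contributes_zero(self, rng):
        data = rng.standard_normal((4, 4, 4, 40))
        data[1, 1, 1] = 7.0  # constant voxel
        ilc = bf.compute_ilc(_run(data))
        assert ilc[1, 1, 1] == 0.0
        assert np.isfinite(ilc).all()

    def test_invalid_kernel(self, rng):
        with pytest.raises(InputError):
            bf.compute_ilc(_run(rng.standard_normal((4, 4, 4, 30))), kernel_mm=0.0)


class TestMvlcPattern:
    def _roi(self, shape=(5, 5, 5)):
        roi = np.zeros(shape, bool)
        roi[1:4, 1:4, 1:4] = True
        return roi

    def test_zero_map_gives_zero_vector(self):
        pat = bf.mvlc_pattern(np.zeros((5, 5, 5)), self._roi())
        assert pat == pytest.approx(np.zeros(27))

    def test_fisher_transform_value(self):
        ilc = np.zeros((5, 5, 5))
        ilc[1, 1, 1] = 0.5
        pat = bf.mvlc_pattern(ilc, self._roi())
        assert pat.max() == pytest.approx(0.54931, abs=1e-5)

    def test_deterministic_ordering(self, rng):
        ilc = rng.uniform(-0.9, 0.9, (5, 5, 5))
        assert (bf.mvlc_pattern(ilc, self._roi())
                == bf.mvlc_pattern(ilc, self._roi())).all()

    def test_small_roi_rejected(self):
        roi = np.zeros((5, 5, 5), bool)
        roi[0, 0, :3] = True
        with pytest.raises(EmptyRoiError):
            bf.mvlc_pattern(np.zeros((5, 5, 5)), roi)


class TestSimilarityDifference:
    def test_post_equals_task_pre_orthogonal(self, rng):
        task = rng.standard_normal(4000)
        pre = rng.standard_normal(4000)
        sim = bf.similarity_difference(task, pre, task)
        assert sim.r_task_post == pytest.approx(1.0)
        assert sim.similarity_difference == pytest.approx(1.0, abs=0.05)

    def test_post_equals_pre_gives_exact_zero(self, rng):
        task, rest = rng.standard_normal((2, 100))
        assert bf.similarity_difference(task, rest, rest).similarity_difference == 0.0

    def test_invariant_under_common_permutation(self, rng):
        task, pre, post = rng.standard_normal((3, 200))
        perm = rng.permutation(200)
        a = bf.similarity_difference(task, pre, post)
        b = bf.similarity_difference(task[perm], pre[perm], post[perm])
        assert a.similarity_difference == pytest.approx(b.similarity_difference)

    def test_constant_pattern_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            bf.similarity_difference(np.ones(50), rng.standard_normal(50),
                                     rng.standard_normal(50))


class TestRoiToRoiFc:
    def _masks(self, shape=(8, 8, 8)):
        a = np.zeros(shape, bool); a[:3] = True
        b = np.zeros(shape, bool); b[5:] = True
        return a, b

    def test_identical_rois_rejected(self, rng):
        data = rng.standard_normal((8, 8, 8, 60))
        a, _ = self._masks()
        with pytest.raises(DegenerateDataError, match="disjoint"):
            bf.roi_to_roi_fc(_run(data), a, a)

    def test_independent_noise_near_zero(self, rng):
        a, b = self._masks()
        zs = [bf.roi_to_roi_fc(_run(rng.standard_normal((8, 8, 8, 100))), a, b)
              for _ in range(50)]
        se = np.std(zs) / np.sqrt(len(zs))
        assert abs(np.mean(zs)) < 2 * se + 0.01

    def test_planted_shared_signal_recovered(self, rng):
        # shared latent with mixing chosen for r = 0.6 between the ROI means:
        # each ROI mean is noise of variance 1/n_vox plus w*g, and
        # r = w^2 / (w^2 + 1/n_vox)  =>  w = sqrt(r/(1-r) / n_vox)
        a, b = self._masks()
        T = 20000
        g = rng.standard_normal(T)
        data = rng.standard_normal((8, 8, 8, T))
        for mask in (a, b):
            w = np.sqrt(0.6 / (1 - 0.6) / mask.sum())
            data[mask] += w * g
        z = bf.roi_to_roi_fc(_run(data), a, b)
        assert z == pytest.approx(np.arctanh(0.6), abs=0.05)
        assert np.tanh(z) == pytest.approx(0.6, abs=0.04)

    def test_fc_change_antisymmetry(self):
        assert bf.fc_change(0.7, 0.4) == pytest.approx(0.3)
        assert bf.fc_change(0.4, 0.7) == -bf.fc_change(0.7, 0.4)
        assert bf.fc_change(0.5, 0.5) == 0.0


def test_late_phase_data_drops_transitions(rng):
    data = rng.standard_normal((3, 3, 3, 120))
    run = _run(data)
    late = bf.late_phase_data(run, [0.0, 40.0, 80.0], [30.0, 30.0, 30.0],
                              late_blocks=[1, 2], drop_transition=5)
    assert late.data.shape[-1] == 2 * 25
    assert (late.data[..., 0] == data[..., 45]).all()
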