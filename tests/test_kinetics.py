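import numpy as np
import pytest

from hpmfm import (
    AcquisitionConfig,
    DynamicSeries,
    KineticParams,
    ParametricMapSet,
    compute_maps,
    compute_mean_time,
    compute_pyr_auc,
    fit_kpl_inputless,
    resample_maps,
    simulate_dynamics,
)


def _series_from_signals(sp, sl, acq, n=1):
    sp = np.broadcast_to(sp, (n, acq.n_frames)).reshape(n, 1, 1, acq.n_frames)
    sl = np.broadcast_to(sl, (n, acq.n_frames)).reshape(n, 1, 1, acq.n_frames)
    return DynamicSeries(np.array(sp, float), np.array(sl, float), acq, np.eye(4))


class TestKplFit:
    def test_zero_lactate_yields_zero_kpl(self, noiseless_acq):
        sp, _ = simulate_dynamics(KineticParams(), noiseless_acq)
        ser = _series_from_signals(sp, np.zeros_like(sp), noiseless_acq)
        assert fit_kpl_inputless(ser).ravel()[0] == 0.0

    def test_roundtrip_17ks(self, noiseless_acq):
        sp, sl = simulate_dynamics(KineticParams(kpl_per_second=0.017), noiseless_acq)
        ser = _series_from_signals(sp, sl, noiseless_acq)
        assert fit_kpl_inputless(ser).ravel()[0] == pytest.approx(17.0, abs=1e-3)

    def test_mean_bias_under_noise_below_5pct(self):
        """SNR ~ 20, 100 replicate voxels: mean fitted k_PL near truth."""
        acq = AcquisitionConfig(noise_sigma=0.0074)
        p = KineticParams(kpl_per_second=0.017)
        rng = np.random.default_rng(99)
        pairs = [simulate_dynamics(p, acq, rng) for _ in range(100)]
        sp = np.stack([a for a, _ in pairs]).reshape(100, 1, 1, -1)
        sl = np.stack([b for _, b in pairs]).reshape(100, 1, 1, -1)
        fitted = fit_kpl_inputless(DynamicSeries(sp, sl, acq, np.eye(4))).ravel()
        assert abs(fitted.mean() - 17.0) / 17.0 < 0.05

    def test_scale_invariance(self, noiseless_acq):
        """Joint rescaling of both signals leaves k_PL unchanged."""
        sp, sl = simulate_dynamics(KineticParams(kpl_per_second=0.02), noiseless_acq)
        k1 = fit_kpl_inputless(_series_from_signals(sp, sl, noiseless_acq)).ravel()[0]
        k2 = fit_kpl_inputless(
            _series_from_signals(7.3 * sp, 7.3 * sl, noiseless_acq)
        ).ravel()[0]
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_nonfinite_voxels_zeroed(self, noiseless_acq, caplog):
        sp, sl = simulate_dynamics(KineticParams(kpl_per_second=0.02), noiseless_acq)
        sp4 = np.stack([sp, sp]).reshape(2, 1, 1, -1).copy()
        sl4 = np.stack([sl, sl]).reshape(2, 1, 1, -1).copy()
        sp4[1, 0, 0, 3] = np.nan
        with caplog.at_level("WARNING"):
            k = fit_kpl_inputless(DynamicSeries(sp4, sl4, noiseless_acq, np.eye(4)))
        assert k.ravel()[1] == 0.0 and k.ravel()[0] > 0


class TestAucAndMeanTime:
    def test_auc_examples(self, noiseless_acq):
        acq = noiseless_acq
        ones = np.ones(acq.n_frames)
        assert compute_pyr_auc(_series_from_signals(ones, ones, acq)).ravel()[0] == 20.0
        zero = np.zeros(acq.n_frames)
        assert compute_pyr_auc(_series_from_signals(zero, zero, acq)).ravel()[0] == 0.0
        sig = np.zeros(acq.n_frames)
        sig[:4] = [0, 2, 1, 0]
        assert compute_pyr_auc(_series_from_signals(sig, sig, acq)).ravel()[0] == 3.0

    def test_auc_linearity(self, noiseless_acq, rng):
        sig = rng.uniform(0, 1, noiseless_acq.n_frames)
        a1 = compute_pyr_auc(_series_from_signals(sig, sig, noiseless_acq)).ravel()[0]
        a2 = compute_pyr_auc(_series_from_signals(3 * sig, sig, noiseless_acq)).ravel()[0]
        assert a2 == pytest.approx(3 * a1, rel=1e-12)

    @pytest.mark.parametrize(
        "sig4, expected",
        [([0, 1, 0, 0], 3.0), ([1, 1, 1, 1], 4.5), ([1, 3, 0, 0], 2.25)],
    )
    def test_mean_time_center_of_mass(self, sig4, expected):
        acq = AcquisitionConfig(n_frames=4, noise_sigma=0.0)
        mt = compute_mean_time(
            _series_from_signals(np.array(sig4, float), np.zeros(4), acq)
        )
        assert mt.ravel()[0] == pytest.approx(expected)

    def test_mean_time_scale_invariant(self, noiseless_acq, rng):
        sig = rng.uniform(0.1, 1, noiseless_acq.n_frames)
        m1 = compute_mean_time(_series_from_signals(sig, sig, noiseless_acq)).ravel()[0]
        m2 = compute_mean_time(
            _series_from_signals(5.5 * sig, sig, noiseless_acq)
        ).ravel()[0]
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_zero_signal_mean_time_is_zero(self, noiseless_acq):
        z = np.zeros(noiseless_acq.n_frames)
        assert compute_mean_time(_series_from_signals(z, z, noiseless_acq)).ravel()[0] == 0.0


def _map_set(value, shape=(4, 4, 4), voxel=10.0, mask_value=1):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    arr = np.full(shape, float(value))
    mask = np.full(shape, mask_value, dtype=np.int16)
    return ParametricMapSet(arr, arr.copy(), arr.copy(), mask, aff)


class TestResampling:
    def test_constant_map_stays_constant(self):
        maps = _map_set(3.5)
        out = resample_maps(maps)
        assert out.voxel_mm == pytest.approx((5.0, 5.0, 5.0))
        inner = out.kpl_map[1:-1, 1:-1, 1:-1]
        assert np.allclose(inner, 3.5)

    def test_identity_when_already_isotropic_5mm(self):
        aff = np.diag([5.0, 5.0, 5.0, 1.0])
        arr = np.arange(64, dtype=float).reshape(4, 4, 4)
        maps = ParametricMapSet(arr, arr, arr, np.ones((4, 4, 4), np.int16), aff)
        out = resample_maps(maps)
        assert np.allclose(out.kpl_map[:4, :4, :4], arr, atol=1e-9)

    def test_cube_mask_volume_preserved(self):
        """20 mm cube at 10 mm native voxels -> ~8 mL at 5 mm."""
        aff = np.diag([10.0, 10.0, 10.0, 1.0])
        mask = np.zeros((6, 6, 6), np.int16)
        mask[2:4, 2:4, 2:4] = 1
        kpl = mask.astype(float) * 20.0
        maps = ParametricMapSet(kpl, kpl, kpl, mask, aff)
        out = resample_maps(maps)
        vol_ml = (out.mask > 0).sum() * out.voxel_volume_ml
        assert abs(vol_ml - 8.0) <= 0.125 * ((out.mask > 0).sum() ** (2 / 3) * 6) ** 0.5 + 1.0

    def test_centroid_preserved_within_half_native_voxel(self):
        aff = np.diag([10.0, 10.0, 10.0, 1.0])
        mask = np.zeros((8, 8, 8), np.int16)
        mask[2:5, 3:6, 1:4] = 1
        maps = ParametricMapSet(
            mask.astype(float), mask.astype(float), mask.astype(float), mask, aff
        )
        out = resample_maps(maps)

        def centroid(m, a):
            idx = np.argwhere(m > 0)
            return idx.mean(axis=0) @ a[:3, :3].T + a[:3, 3]

        d = centroid(mask, aff) - centroid(out.mask, out.affine)
        assert np.all(np.abs(d) <= 5.0)

    def test_singular_affine_rejected(self):
        maps = _map_set(1.0)
        maps.affine = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singular"):
            resample_maps(maps)


def test_compute_maps_on_simulated_patient(small_cohort):
    pt = small_cohort.patients[0]
    native = compute_maps(DynamicSeries.from_patient(pt), pt.mask)
    assert (native.kpl_map >= 0).all()
    assert native.mean_time_map.max() <= (pt.acq.n_frames - 1) * pt.acq.tr_seconds
    inmask = pt.mask > 0
    truth_med = pt.truth["kpl_median"]
    fit_med = np.median(native.kpl_map[inmask])
    assert abs(fit_med - truth_med) / truth_med < 0.15
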