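import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placfbv import (
    AcquisitionParams,
    ContrastState,
    Modality,
    PipelineError,
    VFASignalSet,
    ernst_angle_deg,
    fit_t1_roi,
    fit_t1_vfa,
    fit_t1_voxelwise,
    gre_signal,
    linearize_vfa,
    roi_mean_signal,
    simulate_vfa_series,
)

# frozen by direct evaluation of the steady-state equation:
# E1 = exp(-20/1300) = 0.9847332, S = 1000*(1-E1)*sin(25deg)/(1-cos(25deg)*E1)
S_25DEG_T1300 = 60.00315059829063


def _signal_set(t1_ms, m0=1.0, acq=None, angles=None):
    acq = acq or AcquisitionParams()
    angles = angles or acq.flip_angles_deg
    sigs = [gre_signal(m0, t1_ms, acq, a) for a in angles]
    return VFASignalSet(angles, sigs, acq)


class TestGreSignal:
    def test_hand_evaluated_value(self, acq):
        assert gre_signal(1000.0, 1300.0, acq, 25.0) == pytest.approx(
            S_25DEG_T1300, rel=1e-12
        )

    def test_full_recovery_limit(self):
        acq = AcquisitionParams(tr_ms=1e6, te_ms=0.0, flip_angles_deg=(30.0, 60.0))
        for a in (10.0, 40.0, 80.0):
            assert gre_signal(2.0, 100.0, acq, a) == pytest.approx(
                2.0 * math.sin(math.radians(a)), rel=1e-9
            )

    def test_t2_factor_is_flip_angle_independent_scale(self, acq):
        ratio = None
        for a in acq.flip_angles_deg:
            full = gre_signal(1000.0, 1300.0, acq, a, t2_ms=50.0)
            approx = gre_signal(1000.0, 1300.0, acq, a)
            r = full / approx
            if ratio is None:
                ratio = r
            assert r == pytest.approx(ratio, rel=1e-12)
        assert ratio == pytest.approx(math.exp(-3.5 / 50.0), rel=1e-12)

    def test_rejects_nonpositive_t1(self, acq):
        with pytest.raises(PipelineError):
            gre_signal(1.0, 0.0, acq, 25.0)

    def test_ernst_angle_is_the_maximum(self, acq):
        t1 = 1300.0
        a_e = ernst_angle_deg(t1, acq.tr_ms)
        assert a_e == pytest.approx(10.0246, abs=0.05)
        s_e = gre_signal(1.0, t1, acq, a_e)
        grid = np.linspace(0.01, 90.0, 5000)
        assert np.all(s_e >= gre_signal(1.0, t1, acq, grid))


class TestLinearize:
    def test_direct_evaluation(self, acq):
        sset = VFASignalSet((30.0, 90.0), (1.0, 1.0), acq)
        pairs = linearize_vfa(sset)
        assert pairs[0] == pytest.approx(
            (1.0 / math.tan(math.radians(30.0)), 2.0), rel=1e-12
        )
        # tan(90 deg) pole handled exactly: x = S*cos/sin = 0
        assert pairs[1] == (0.0, 1.0)

    def test_zero_signal_maps_to_origin(self, acq):
        sset = VFASignalSet((30.0, 60.0), (0.0, 0.0), acq)
        assert linearize_vfa(sset) == [(0.0, 0.0), (0.0, 0.0)]

    def test_noiseless_pairs_are_collinear(self, acq):
        pairs = linearize_vfa(_signal_set(900.0, m0=500.0))
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        coeffs = np.polyfit(x, y, 1)
        assert np.allclose(y, np.polyval(coeffs, x), rtol=1e-10)


class TestFitT1:
    # the 12 cohort-mean T1 cells (placenta and IVC, pre/post, 3 ages)
    TABLE_T1S = (1300.0, 890.0, 1020.0, 690.0,
                 1240.0, 860.0, 1150.0, 600.0,
                 1200.0, 720.0, 1060.0, 480.0)

    @pytest.mark.parametrize("t1", TABLE_T1S)
    def test_noiseless_round_trip(self, t1):
        fit = fit_t1_vfa(_signal_set(t1, m0=1.0))
        assert fit.valid
        assert fit.t1_ms == pytest.approx(t1, rel=1e-9)
        assert fit.m0 == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_slope(self):
        # slope must equal exp(-TR/T1) = exp(-20/720) = 0.9726044771163483
        fit = fit_t1_vfa(_signal_set(720.0, m0=3.0))
        assert fit.slope == pytest.approx(0.9726044771163483, rel=1e-12)
        assert fit.t1_ms == pytest.approx(720.0, rel=1e-9)

    def test_all_zero_signals_invalid_not_raising(self, acq):
        sset = VFASignalSet(acq.flip_angles_deg, (0.0,) * 5, acq)
        fit = fit_t1_vfa(sset)
        assert not fit.valid
        assert fit.reason is not None

    def test_slope_out_of_unit_interval_flagged(self, acq):
        # signal rising with flip angle faster than any T1 allows -> slope > 1
        sset = VFASignalSet((8.0, 45.0), (0.1, 1.0), acq)
        fit = fit_t1_vfa(sset)
        assert not fit.valid
        assert "slope" in fit.reason

    @given(
        t1=st.floats(100.0, 5000.0),
        m0=st.floats(0.01, 1e4),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance_and_exact_recovery(self, t1, m0, scale):
        """Multiplying all signals by c > 0 leaves T1 unchanged, scales M0."""
        acq = AcquisitionParams()
        base = _signal_set(t1, m0=m0)
        fit = fit_t1_vfa(base)
        assert fit.valid and fit.t1_ms == pytest.approx(t1, rel=1e-6)
        scaled = VFASignalSet(
            base.flip_angles_deg, tuple(s * scale for s in base.signals), acq
        )
        fit_s = fit_t1_vfa(scaled)
        assert fit_s.t1_ms == pytest.approx(fit.t1_ms, rel=1e-9)
        assert fit_s.m0 == pytest.approx(fit.m0 * scale, rel=1e-6)

    def test_finite_t2_bias_below_half_percent(self, acq):
        """Fitting TE=3.5 ms, T2=50 ms signals under the TE<<T2 assumption."""
        angles = acq.flip_angles_deg
        sigs = [gre_signal(1000.0, 1300.0, acq, a, t2_ms=50.0) for a in angles]
        fit = fit_t1_vfa(VFASignalSet(angles, sigs, acq))
        assert abs(fit.t1_ms - 1300.0) / 1300.0 < 0.005


class TestRoiAndVoxelwise:
    def test_roi_mean(self, small_phantom, acq):
        from placfbv import ImageVolume

        mask, _ = small_phantom
        data = np.zeros(mask.labels.shape)
        sel = mask.labels == mask.ivc_label()
        data[sel] = 7.0
        vol = ImageVolume(data, mask.voxel_size_mm, Modality.MR_SIGNAL,
                          flip_angle_deg=8.0)
        assert roi_mean_signal(vol, mask, mask.ivc_label()) == 7.0
        idx = np.argwhere(sel)[:2]
        data[tuple(idx[0])] = 10.0
        data[tuple(idx[1])] = 20.0
        # replacing two voxels changes the mean accordingly
        expected = data[sel].mean()
        assert roi_mean_signal(vol, mask, mask.ivc_label()) == expected

    def test_empty_label_errors(self, small_phantom, acq):
        from placfbv import ImageVolume

        mask, _ = small_phantom
        vol = ImageVolume(np.zeros(mask.labels.shape), mask.voxel_size_mm,
                          Modality.MR_SIGNAL)
        with pytest.raises(PipelineError, match="no voxels"):
            roi_mean_signal(vol, mask, 999)

    def test_homogeneous_roi_mean_equals_compartment_value(
        self, small_phantom, acq
    ):
        mask, truth = small_phantom
        series = simulate_vfa_series(mask, truth, acq, ContrastState.PRE)
        lbl = mask.placenta_labels()[0]
        props = truth.label_props[lbl]
        expected = gre_signal(props.m0, props.t1_pre_ms, acq, 25.0,
                              t2_ms=props.t2_ms)
        vol25 = next(v for v in series if v.flip_angle_deg == 25.0)
        assert roi_mean_signal(vol25, mask, lbl) == pytest.approx(expected, rel=1e-12)

    def test_voxelwise_map_matches_truth_and_sentinel(self, small_phantom, acq):
        mask, truth = small_phantom
        series = simulate_vfa_series(mask, truth, acq, ContrastState.PRE)
        t1_map = fit_t1_voxelwise(series, acq)
        assert t1_map.modality is Modality.T1_MAP
        for lbl in mask.placenta_labels():
            true_t1 = truth.label_props[lbl].t1_pre_ms
            vals = t1_map.data[mask.labels == lbl]
            assert np.allclose(vals, true_t1, rtol=1e-6)
        # air voxels (M0 = 0) carry the -1 sentinel
        assert np.all(t1_map.data[mask.labels == 0] == -1.0)

    def test_map_mean_matches_roi_fit_in_homogeneous_roi(self, small_phantom, acq):
        mask, truth = small_phantom
        series = simulate_vfa_series(mask, truth, acq, ContrastState.PRE)
        lbl = mask.placenta_labels()[1]
        t1_map = fit_t1_voxelwise(series, acq)
        roi_fit = fit_t1_roi(series, mask, lbl, acq)
        map_mean = float(t1_map.data[mask.labels == lbl].mean())
        assert map_mean == pytest.approx(roi_fit.t1_ms, rel=1e-6)

    def test_shape_mismatch_rejected(self, acq):
        from placfbv import ImageVolume

        vols = [
            ImageVolume(np.ones((4, 4, 4)), (0.5,) * 3, Modality.MR_SIGNAL,
                        flip_angle_deg=a)
            for a in acq.flip_angles_deg
        ]
        vols[0] = ImageVolume(np.ones((5, 4, 4)), (0.5,) * 3, Modality.MR_SIGNAL,
                              flip_angle_deg=8.0)
        with pytest.raises(PipelineError, match="shape"):
            fit_t1_voxelwise(vols, acq)
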