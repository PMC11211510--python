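"""Forward detection model, calibration solve, and trace inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfambend.pife_fret import (
    CalibrationClusters,
    CalibrationError,
    ChannelCalibration,
    PhotophysicsFrame,
    cluster_calibration_points,
    forward_model,
    forward_model_arrays,
    invert_trace,
    normalize_pife,
    solve_calibration,
    state_average_pife,
)

TRUE = ChannelCalibration(dbar_DD=1600.0, abar_DD=140.0, abar_AD=1750.0,
                          abar_AA=120.0, c_D=400.0, c_A=400.0)
F_H, F_L, U_L = 0.70, 0.25, 0.92

calib_st = st.builds(
    ChannelCalibration,
    dbar_DD=st.floats(500, 5000),
    abar_DD=st.floats(0, 500),
    abar_AD=st.floats(500, 5000),
    abar_AA=st.floats(0, 500),
    c_D=st.floats(0, 1000),
    c_A=st.floats(0, 1000),
)


def _exact_clusters(construct):
    """Noiseless cluster means straight from the forward model."""
    u = 1.0 if construct == "mid" else U_L
    f = F_H if construct == "mid" else F_L
    cc = CalibrationClusters(construct=construct)
    cc.means = {
        "both_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=0, q_A=0, f=0), TRUE),
        "donor_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=0, q_A=1, f=0), TRUE),
        "acceptor_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=1, q_A=0, f=0), TRUE),
        cc.live_label: forward_model(
            PhotophysicsFrame(u=u, q_D=1, q_A=1, f=f), TRUE),
    }
    return cc


def _cluster_points(construct, rng, n_per=200, sd=25.0):
    cc = _exact_clusters(construct)
    pts = [np.column_stack([rng.normal(d, sd, n_per), rng.normal(a, sd, n_per)])
           for d, a in cc.means.values()]
    return np.vstack(pts)


class TestForwardModel:
    def test_both_bleached_gives_offsets(self):
        d, a = forward_model(PhotophysicsFrame(q_D=0, q_A=0), TRUE)
        assert (d, a) == (TRUE.c_D, TRUE.c_A)

    def test_donor_only_no_fret(self):
        d, a = forward_model(PhotophysicsFrame(q_D=1, q_A=0, f=0), TRUE)
        assert d == TRUE.dbar_DD + TRUE.c_D
        assert a == TRUE.abar_DD + TRUE.c_A

    def test_linear_in_excitation_power(self):
        f1 = PhotophysicsFrame(u=1.0, q_D=2.0, q_A=1.0, f=0.4)
        f2 = PhotophysicsFrame(u=3.0, q_D=2.0, q_A=1.0, f=0.4)
        d1, a1 = forward_model(f1, TRUE)
        d2, a2 = forward_model(f2, TRUE)
        assert d2 - TRUE.c_D == pytest.approx(3 * (d1 - TRUE.c_D), rel=1e-12)
        assert a2 - TRUE.c_A == pytest.approx(3 * (a1 - TRUE.c_A), rel=1e-12)

    def test_array_form_matches_scalar(self):
        f = np.array([0.1, 0.5, 0.9])
        q = np.array([1.0, 2.0, 3.7])
        d, a = forward_model_arrays(f, q, TRUE)
        for i in range(3):
            ds, as_ = forward_model(PhotophysicsFrame(q_D=q[i], f=f[i]), TRUE)
            assert d[i] == pytest.approx(ds, rel=1e-12)
            assert a[i] == pytest.approx(as_, rel=1e-12)


class TestClustering:
    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        cc = cluster_calibration_points(_cluster_points("mid", rng), "mid")
        truth = _exact_clusters("mid")
        for label, mean in truth.means.items():
            got = cc.means[label]
            assert np.allclose(got, mean, rtol=0.01)

    def test_label_assignment_shuffle_invariant(self):
        rng = np.random.default_rng(1)
        pts = _cluster_points("end", rng)
        a = cluster_calibration_points(pts, "end", seed=0)
        b = cluster_calibration_points(
            np.random.default_rng(2).permutation(pts), "end", seed=0)
        for label in a.means:
            assert np.allclose(a.means[label], b.means[label], atol=1.0)

    def test_duplicated_blob_raises_degenerate_diagnostic(self):
        # three distinct event clusters plus a duplicate of one: asking
        # for four clusters must flag the coincident pair
        rng = np.random.default_rng(3)
        cc = _exact_clusters("mid")
        centers = [cc.means["both_bleached"], cc.means["acceptor_bleached"],
                   cc.means["live_high"], cc.means["both_bleached"]]
        pts = np.vstack([rng.normal(c, 25.0, (200, 2)) for c in centers])
        with pytest.raises(CalibrationError):
            cluster_calibration_points(pts, "mid")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_calibration_points(np.zeros((10, 2)), "mid")


class TestSolveCalibration:
    def test_exact_recovery_from_noiseless_clusters(self):
        calib, fH, fL, uL, rms = solve_calibration(
            _exact_clusters("mid"), _exact_clusters("end"))
        assert rms < 1e-8
        assert calib.dbar_DD == pytest.approx(TRUE.dbar_DD, rel=1e-6)
        assert calib.abar_DD == pytest.approx(TRUE.abar_DD, rel=1e-6)
        assert calib.abar_AD == pytest.approx(TRUE.abar_AD, rel=1e-6)
        assert calib.abar_AA == pytest.approx(TRUE.abar_AA, rel=1e-6)
        assert calib.c_D == pytest.approx(TRUE.c_D, rel=1e-6)
        assert calib.c_A == pytest.approx(TRUE.c_A, rel=1e-6)
        assert fH == pytest.approx(F_H, rel=1e-6)
        assert fL == pytest.approx(F_L, rel=1e-6)
        assert uL == pytest.approx(U_L, rel=1e-6)

    def test_graceful_degradation_with_noisy_clusters(self):
        rng = np.random.default_rng(4)
        cm, ce = _exact_clusters("mid"), _exact_clusters("end")
        for cc in (cm, ce):
            cc.means = {k: (d * (1 + rng.normal(0, 0.02)),
                            a * (1 + rng.normal(0, 0.02)))
                        for k, (d, a) in cc.means.items()}
        calib, fH, fL, uL, _ = solve_calibration(cm, ce)
        assert calib.dbar_DD == pytest.approx(TRUE.dbar_DD, rel=0.05)
        assert calib.abar_AD == pytest.approx(TRUE.abar_AD, rel=0.05)
        assert fH == pytest.approx(F_H, rel=0.05)

    def test_both_bleached_cluster_is_the_offsets(self):
        cc = _exact_clusters("mid")
        assert cc.means["both_bleached"] == (TRUE.c_D, TRUE.c_A)

    def test_swapped_constructs_warn_on_fret_ordering(self):
        # feeding the low-FRET construct as "mid" inverts f_H < f_L
        cm, ce = _exact_clusters("mid"), _exact_clusters("end")
        cm.means, ce.means = (
            {k.replace("live_high", "live_low"): v for k, v in ce.means.items()},
            {k.replace("live_low", "live_high"): v for k, v in cm.means.items()},
        )
        cm.means["live_high"] = cm.means.pop("live_low")
        ce.means["live_low"] = ce.means.pop("live_high")
        with pytest.warns(UserWarning, match="f_H <= f_L"):
            solve_calibration(cm, ce)


class TestInversion:
    @given(
        calib=calib_st,
        f=st.floats(0.0, 0.95),
        q=st.floats(0.1, 5.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, calib, f, q):
        d, a = forward_model(PhotophysicsFrame(q_D=q, f=f), calib)
        f_rec, q_rec, valid = invert_trace(np.array([d]), np.array([a]), calib)
        assert valid[0]
        assert f_rec[0] == pytest.approx(f, abs=1e-9)
        assert q_rec[0] == pytest.approx(q, abs=1e-9)

    def test_gauge_invariance_of_fret(self):
        # rescaling all composites with the counts leaves f unchanged
        scale = 2.5
        rng = np.random.default_rng(5)
        f = rng.uniform(0.05, 0.9, 50)
        q = rng.uniform(0.5, 4.0, 50)
        d, a = forward_model_arrays(f, q, TRUE)
        scaled = ChannelCalibration(
            dbar_DD=TRUE.dbar_DD * scale, abar_DD=TRUE.abar_DD * scale,
            abar_AD=TRUE.abar_AD * scale, abar_AA=TRUE.abar_AA * scale,
            c_D=TRUE.c_D, c_A=TRUE.c_A)
        d2 = (d - TRUE.c_D) * scale + TRUE.c_D
        a2 = (a - TRUE.c_A) * scale + TRUE.c_A
        f1, _, _ = invert_trace(d, a, TRUE)
        f2, _, _ = invert_trace(d2, a2, scaled)
        assert np.allclose(f1, f2, atol=1e-9)
        assert np.allclose(f1, f, atol=1e-9)

    def test_dark_donor_flagged_invalid(self):
        f, q, valid = invert_trace(np.array([TRUE.c_D - 5.0]),
                                   np.array([900.0]), TRUE)
        assert not valid[0]

    def test_out_of_range_fret_clamped_and_flagged(self):
        # acceptor counts below the direct-excitation floor imply f < -0.1
        d, _ = forward_model(PhotophysicsFrame(q_D=1, f=0.0), TRUE)
        f, q, valid = invert_trace(np.array([d]), np.array([TRUE.c_A]), TRUE)
        assert not valid[0]
        assert f[0] == pytest.approx(-0.1)

    def test_acceptor_bleached_frames_use_qA_zero(self):
        d, a = forward_model(PhotophysicsFrame(q_D=2.0, q_A=0.0, f=0.0), TRUE)
        f, q, valid = invert_trace(np.array([d]), np.array([a]), TRUE,
                                   acceptor_alive=np.array([0.0]))
        assert valid[0]
        assert f[0] == pytest.approx(0.0, abs=1e-9)
        assert q[0] == pytest.approx(2.0, abs=1e-9)

    def test_calibration_construct_traces_give_unit_qd(self):
        # control: traces rendered with q_D = 1 invert to q_D ~ 1 in both
        # FRET states once the solved calibration is applied
        rng = np.random.default_rng(6)
        calib, *_ = solve_calibration(_exact_clusters("mid"),
                                      _exact_clusters("end"))
        for f_true in (F_L, F_H):
            d, a = forward_model_arrays(
                np.full(2000, f_true), np.ones(2000), TRUE)
            d = d + rng.normal(0, 20, 2000)
            a = a + rng.normal(0, 20, 2000)
            f, q, valid = invert_trace(d, a, calib)
            assert np.mean(q[valid]) == pytest.approx(1.0, abs=0.05)

    def test_normalize_pife_reference(self):
        q = np.array([1.5, 3.0])
        assert np.allclose(normalize_pife(q, 1.5), [1.0, 2.0])
        with pytest.raises(ValueError):
            normalize_pife(q, 0.0)


class TestStateAveragePife:
    def test_recovers_state_enhancements(self):
        from tfambend.synthetic_data import (AcquisitionConfig, LSP_BENDING,
                                             NoiseModel, bin_to_frames,
                                             render_counts,
                                             simulate_state_path)
        acq = AcquisitionConfig(n_frames=2000, n_traces=12, seed=20)
        rng = np.random.default_rng(acq.seed)
        fs, qs = [], []
        for _ in range(acq.n_traces):
            path = simulate_state_path(LSP_BENDING,
                                       acq.duration * 1.001 + 1e-6, rng)
            frames = bin_to_frames(path, LSP_BENDING, acq)
            tr = render_counts(frames, TRUE, NoiseModel(), seed=rng)
            f, q, _ = invert_trace(tr.donor, tr.acceptor, TRUE)
            fs.append(f)
            qs.append(q)
        q_P, q_F = state_average_pife(fs, qs)
        assert q_P == pytest.approx(3.7, abs=0.2)
        assert q_F == pytest.approx(1.5, abs=0.1)
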