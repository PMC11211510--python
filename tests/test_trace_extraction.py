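"""Image pipeline: registration, detection, localization, drift, extraction."""

import numpy as np
import pytest

from tfambend.cli_io import fret_from_counts
from tfambend.synthetic_data import (
    FrameIdeal,
    NoiseModel,
    Trace,
    default_fret_calibration,
    render_counts,
    render_image_stack,
)
from tfambend.trace_extraction import (
    AffineTransform2D,
    DriftSeries,
    RegistrationError,
    detect_spots,
    estimate_drift,
    extract_traces,
    localize_spot,
    register_channels,
)

NO_NOISE = NoiseModel(read_sd=0.0)


def _static_trace(n_frames, donor_level=2000.0, acceptor_level=1200.0,
                  offset=400.0):
    return Trace(donor=np.full(n_frames, donor_level + offset),
                 acceptor=np.full(n_frames, acceptor_level + offset),
                 time=np.arange(n_frames) / 65.0)


def _spot_field(positions, n_frames=20, noise=None, drift=None, seed=0,
                field=(64, 64), donor_level=2000.0):
    traces = [_static_trace(n_frames, donor_level) for _ in positions]
    noise = noise or NO_NOISE
    return render_image_stack(np.asarray(positions, float), traces,
                              psf_sigma=1.2, drift=drift, field=field,
                              noise=noise, seed=seed,
                              add_noise=noise.read_sd > 0)


class TestLocalizeSpot:
    def _crop(self, x, y, amp=500.0, sigma=1.4, bg=100.0, noise_sd=0.0,
              seed=0):
        yy, xx = np.mgrid[0:11, 0:11]
        img = amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) /
                           (2 * sigma ** 2)) + bg
        if noise_sd:
            img = img + np.random.default_rng(seed).normal(0, noise_sd,
                                                           img.shape)
        return img

    def test_centered_noiseless_gaussian(self):
        c = localize_spot(self._crop(5.0, 5.0))
        assert c.ok
        assert (c.x, c.y) == pytest.approx((5.0, 5.0), abs=1e-6)

    def test_offset_spot_at_snr_20(self):
        c = localize_spot(self._crop(5.3, 4.7, amp=500.0, noise_sd=25.0))
        assert c.ok
        assert c.x == pytest.approx(5.3, abs=0.1)
        assert c.y == pytest.approx(4.7, abs=0.1)

    def test_flat_crop_flagged(self):
        c = localize_spot(np.full((11, 11), 50.0))
        assert not c.ok

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            localize_spot(np.zeros((9, 9)))


class TestDetectSpots:
    def test_blank_noisy_field_gives_no_candidates(self):
        rng = np.random.default_rng(1)
        stack = 400.0 + rng.normal(0, 10, (20, 64, 64))
        assert detect_spots(stack) == []

    def test_known_positions_recovered(self):
        rng = np.random.default_rng(2)
        xs = np.arange(10, 60, 11)
        positions = [(x, y) for x in xs for y in xs][:20]
        stack_D, _ = _spot_field(positions, noise=NoiseModel(read_sd=10.0),
                                 seed=3)
        cands = detect_spots(stack_D)
        assert len(cands) == len(positions)
        found = np.array([[c.x, c.y] for c in cands])
        for px, py in positions:
            dist = np.min(np.hypot(found[:, 0] - px, found[:, 1] - py))
            assert dist < 0.1

    def test_overlapping_pair_keeps_at_most_one(self):
        stack_D, _ = _spot_field([(30.0, 30.0), (32.0, 30.0), (45.0, 45.0)],
                                 noise=NoiseModel(read_sd=5.0), seed=4)
        cands = detect_spots(stack_D, reject_outliers=False)
        near = [c for c in cands if abs(c.y - 30) < 3 and 27 < c.x < 35]
        assert len(near) <= 1

    def test_translation_equivariance(self):
        positions = [(20.0, 22.0), (40.0, 35.0), (25.0, 45.0)]
        stack_a, _ = _spot_field(positions)
        stack_b, _ = _spot_field([(x + 3, y + 2) for x, y in positions])
        ca = sorted(detect_spots(stack_a), key=lambda c: (c.x, c.y))
        cb = sorted(detect_spots(stack_b), key=lambda c: (c.x, c.y))
        assert len(ca) == len(cb) == 3
        for a, b in zip(ca, cb):
            assert b.x - a.x == pytest.approx(3.0, abs=1e-3)
            assert b.y - a.y == pytest.approx(2.0, abs=1e-3)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.empty((0, 8, 8)))


class TestRegistration:
    def _beads(self, transform=None, n_frames=10):
        positions = np.array([[15.0, 15.0], [45.0, 18.0], [20.0, 44.0],
                              [48.0, 47.0], [32.0, 30.0]])
        stack_D, _ = _spot_field(positions, n_frames=n_frames)
        if transform is None:
            return stack_D, stack_D
        pos_A = transform.inverse().apply(positions)
        stack_A, _ = _spot_field(pos_A, n_frames=n_frames)
        return stack_D, stack_A

    def test_identical_images_give_identity(self):
        d, a = self._beads()
        t = register_channels(d, a)
        assert np.allclose(t.matrix, np.eye(2), atol=1e-3)
        assert np.allclose(t.offset, 0.0, atol=1e-2)
        assert t.residual_rms < 0.05

    def test_rotation_and_shift_recovered(self):
        th = np.deg2rad(2.0)
        R = ((np.cos(th), -np.sin(th)), (np.sin(th), np.cos(th)))
        # rotate about the field centre so beads stay in frame
        center = np.array([31.5, 31.5])
        b = center - np.asarray(R) @ center + np.array([1.5, 0.5])
        true = AffineTransform2D(R, tuple(b))
        d, a = self._beads(true)
        fit = register_channels(d, a)
        assert fit.residual_rms < 0.05
        probe = np.array([[20.0, 40.0], [40.0, 20.0]])
        assert np.allclose(fit.apply(probe), true.apply(probe), atol=0.05)

    def test_too_few_beads_raises(self):
        stack, _ = _spot_field([(30.0, 30.0)])
        with pytest.raises(RegistrationError):
            register_channels(stack, stack)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform2D(((1.0, 1.0), (1.0, 1.0)), (0.0, 0.0))


class TestEstimateDrift:
    def test_static_spots_give_zero_drift(self):
        stack, _ = _spot_field([(20.0, 20.0), (44.0, 40.0)], n_frames=100)
        drift = estimate_drift(stack, [(20.0, 20.0), (44.0, 40.0)])
        assert np.all(np.abs(drift.dxdy) < 0.05)

    def test_linear_drift_endpoint_recovered(self):
        n = 2000
        slope = 0.002  # px/frame
        drift_true = np.column_stack([slope * np.arange(n),
                                      np.zeros(n)])
        stack, _ = _spot_field([(15.0, 20.0), (40.0, 44.0)], n_frames=n,
                               drift=drift_true,
                               noise=NoiseModel(read_sd=5.0), seed=6)
        est = estimate_drift(stack, [(15.0, 20.0), (40.0, 44.0)])
        assert est.dxdy[-1, 0] == pytest.approx(slope * (n - 1), rel=0.1)
        assert abs(est.dxdy[-1, 1]) < 0.2

    def test_slow_sinusoidal_drift_tracked_pointwise(self):
        n = 1200
        drift_true = np.column_stack([
            0.8 * np.sin(2 * np.pi * np.arange(n) / 600.0), np.zeros(n)])
        stack, _ = _spot_field([(20.0, 20.0), (44.0, 40.0)], n_frames=n,
                               drift=drift_true)
        est = estimate_drift(stack, [(20.0, 20.0), (44.0, 40.0)])
        err = est.dxdy[:, 0] - (drift_true[:, 0] - drift_true[0, 0])
        assert np.max(np.abs(err)) < 0.2

    def test_lost_anchors_raise(self):
        stack = np.full((50, 32, 32), 400.0)
        with pytest.raises(RuntimeError):
            estimate_drift(stack, [(200.0, 200.0)])

    def test_drift_series_rebased_to_zero(self):
        d = DriftSeries(np.array([[1.0, 2.0], [1.5, 2.5]]))
        assert tuple(d.dxdy[0]) == (0.0, 0.0)


class TestExtractTraces:
    def test_counts_match_generated_intensities(self):
        positions = [(20.0, 20.0), (44.0, 40.0)]
        traces_in = [_static_trace(30, 2000.0, 1200.0) for _ in positions]
        stack_D, stack_A = render_image_stack(
            np.asarray(positions), traces_in, psf_sigma=1.2, field=(64, 64),
            noise=NO_NOISE, add_noise=False)
        ts = extract_traces(stack_D, stack_A, AffineTransform2D(),
                            [_cand(x, y) for x, y in positions])
        for tr in ts:
            # radius-3 aperture captures ~95% of a sigma=1.2 Gaussian
            assert np.allclose(tr.donor, 2000.0, rtol=0.06)
            assert np.mean(tr.donor) == pytest.approx(2000.0 * 0.956,
                                                      rel=0.01)
            assert np.allclose(tr.acceptor, 1200.0 * 0.956, rtol=0.01)

    def test_zero_intensity_molecule_reads_noise_floor(self):
        positions = [(30.0, 30.0)]
        traces_in = [_static_trace(20, 0.0, 0.0)]
        stack_D, stack_A = render_image_stack(
            np.asarray(positions), traces_in, field=(64, 64),
            noise=NoiseModel(read_sd=5.0), seed=7)
        ts = extract_traces(stack_D, stack_A, AffineTransform2D(),
                            [_cand(30.0, 30.0)])
        assert abs(np.mean(ts.traces[0].donor)) < 3 * 5.0 * np.sqrt(29)

    def test_drift_correction_reduces_intensity_scatter(self):
        n = 300
        drift_true = np.column_stack([0.01 * np.arange(n), np.zeros(n)])
        positions = [(20.0, 25.0)]
        traces_in = [_static_trace(n, 2000.0, 1200.0)]
        stack_D, stack_A = render_image_stack(
            np.asarray(positions), traces_in, drift=drift_true,
            field=(64, 64), noise=NO_NOISE, add_noise=False)
        cand = [_cand(20.0, 25.0)]
        corrected = extract_traces(stack_D, stack_A, AffineTransform2D(),
                                   cand, DriftSeries(drift_true))
        uncorrected = extract_traces(stack_D, stack_A, AffineTransform2D(),
                                     cand)
        assert np.std(corrected.traces[0].donor) < \
            np.std(uncorrected.traces[0].donor)

    def test_aperture_leaving_field_truncates_trace(self):
        n = 100
        drift_true = np.column_stack([0.5 * np.arange(n), np.zeros(n)])
        positions = [(50.0, 30.0)]
        traces_in = [_static_trace(n, 2000.0, 1200.0)]
        stack_D, stack_A = render_image_stack(
            np.asarray(positions), traces_in, field=(64, 64),
            noise=NO_NOISE, add_noise=False)
        ts = extract_traces(stack_D, stack_A, AffineTransform2D(),
                            [_cand(50.0, 30.0)], DriftSeries(drift_true))
        assert len(ts.traces[0]) < n
        assert 0 in ts.metadata["truncated"]


def _cand(x, y):
    from tfambend.trace_extraction import SpotCandidate

    return SpotCandidate(x=x, y=y, amplitude=1000.0, sigma=1.2,
                         background=400.0)


class TestEndToEndFret:
    def test_extracted_fret_matches_ground_truth(self):
        """Full image round trip: FRET from extracted traces tracks the
        framewise ground truth with RMS error < 0.05 at SNR ~ 20."""
        from tfambend.synthetic_data import (AcquisitionConfig, LSP_BENDING,
                                             bin_to_frames,
                                             simulate_state_path)

        calib = default_fret_calibration()
        acq = AcquisitionConfig(n_frames=400, seed=8)
        rng = np.random.default_rng(8)
        positions = np.array([[18.0, 18.0], [40.0, 22.0], [25.0, 44.0]])
        traces_in, truth = [], []
        for i in range(len(positions)):
            path = simulate_state_path(LSP_BENDING,
                                       acq.duration * 1.01 + 1e-6, rng)
            frames = bin_to_frames(path, LSP_BENDING, acq)
            traces_in.append(render_counts(frames, calib, NO_NOISE,
                                           add_noise=False))
            truth.append(frames.f)
        stack_D, stack_A = render_image_stack(
            positions, traces_in, field=(64, 64),
            noise=NoiseModel(read_sd=8.0), seed=9)
        ts = extract_traces(stack_D, stack_A, AffineTransform2D(),
                            [_cand(x, y) for x, y in positions])
        for tr, f_true in zip(ts, truth):
            f_obs = fret_from_counts(tr.donor, tr.acceptor)
            rms = np.sqrt(np.mean((f_obs - f_true) ** 2))
            assert rms < 0.05
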