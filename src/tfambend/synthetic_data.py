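"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate a TIRF single-molecule FRET/PIFE experiment on a
surface-immobilized DNA whose bound protein complex hops between a
partially bent (P, low FRET) and fully bent (F, high FRET) state:

- continuous-time two-state Markov trajectories with exponential dwells,
- framewise binning at 65 frames/s with 15 ms exposure-window averaging
  (sub-frame dynamics are averaged, not point-sampled, reproducing the
  mid-FRET blur real cameras produce),
- EMCCD-like camera counts around baselines of ~1600 counts, with
  signal-proportional Gaussian noise (excess factor ~ sqrt(2) as a proxy
  for EM-register excess noise) and exponential photobleaching,
- two-channel image stacks of Gaussian spots with drift, for the image
  pipeline,
- equilibrium titration curves with exact ligand depletion and
  stopped-flow double-exponential dissociation decays.

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .kinetic_core import (
    BindingKineticModel,
    TwoStateBendingModel,
    binding_occupancy,
    dissociation_curve,
)
from .pife_fret import ChannelCalibration, forward_model_arrays

__all__ = [
    "AcquisitionConfig",
    "NoiseModel",
    "ContinuousStatePath",
    "FrameIdeal",
    "Trace",
    "simulate_state_path",
    "bin_to_frames",
    "render_counts",
    "render_image_stack",
    "simulate_titration",
    "simulate_stopped_flow",
    "simulate_fret_traces",
    "default_fret_calibration",
    "default_pife_calibration",
    "LSP_BENDING",
    "HSP_BENDING",
    "NS_BENDING",
    "LSP_BINDING",
    "HSP_BINDING",
    "NS_BINDING",
    "BENDING_PRESETS",
    "BINDING_PRESETS",
]


# ---------------------------------------------------------------------------
# Study-condition presets
# ---------------------------------------------------------------------------
# Bending presets: exit rates are reciprocals of the mean state dwell times
# measured for the three 30-bp substrates (LSP/HSP promoters and a
# non-specific sequence); FRET means/SDs are the per-state values of the
# corresponding transition-density clusters.  PIFE factors are the
# state-averaged donor enhancements of the -12-labelled Cy3 construct.

LSP_BENDING = TwoStateBendingModel(
    rate_bend=24.0, rate_unbend=1.0,
    fret_mean_P=0.22, fret_mean_F=0.65, fret_sd_P=0.05, fret_sd_F=0.05,
    pife_P=3.7, pife_F=1.5,
)
HSP_BENDING = TwoStateBendingModel(
    rate_bend=1.0 / 0.05, rate_unbend=1.0 / 0.07,
    fret_mean_P=0.27, fret_mean_F=0.51, fret_sd_P=0.05, fret_sd_F=0.05,
)
NS_BENDING = TwoStateBendingModel(
    rate_bend=1.0 / 0.12, rate_unbend=1.0 / 0.07,
    fret_mean_P=0.21, fret_mean_F=0.48, fret_sd_P=0.05, fret_sd_F=0.05,
)

# Binding presets (per-minute / nM): pure off rates back-computed from the
# measured apparent off rates and the bending equilibrium constants K_{F/P}
# (24.6 / 1.7 / 0.6 for LSP / HSP / NS, from the unrounded dwell-time
# ratios) via k~ = k_off (1 + K); pure Kd likewise from the apparent Kd
# (9 / 43 / 44 nM).  Bending rates are per minute with k2/k_m2 = K_{F/P}.
LSP_BINDING = BindingKineticModel(
    k_on=12.8 / 230.4, pure_koff=12.8, k2=24.0 * 60.0, k_m2=24.0 * 60.0 / 24.6,
)
HSP_BINDING = BindingKineticModel(
    k_on=18.09 / 116.1, pure_koff=18.09, k2=20.4 * 60.0, k_m2=12.0 * 60.0,
)
NS_BINDING = BindingKineticModel(
    k_on=12.0 / 70.4, pure_koff=12.0, k2=500.0, k_m2=500.0 / 0.6,
)

BENDING_PRESETS = {"LSP": LSP_BENDING, "HSP": HSP_BENDING, "NS": NS_BENDING}
BINDING_PRESETS = {"LSP": LSP_BINDING, "HSP": HSP_BINDING, "NS": NS_BINDING}


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera acquisition settings (defaults: 65 fps, 15 ms exposure)."""

    frame_rate: float = 65.0
    exposure: float = 0.015
    n_frames: int = 4000
    n_traces: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0 < self.exposure <= 1.0 / self.frame_rate + 1e-12):
            raise ValueError("exposure must be positive and <= frame interval")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class NoiseModel:
    """EMCCD-like count noise and photobleaching parameters.

    The per-frame count noise is Gaussian with variance

        read_sd^2 + excess_factor^2 * scale * (ideal - offset)

    i.e. a read-noise floor plus shot noise amplified by the EM excess
    factor; adequate at the >100-count signals simulated here and keeps
    the downstream inversion unbiased.  Bleaching is an exponential
    first-passage time per dye; the bleached dye's q is set to 0.
    """

    camera_offset_D: float = 400.0
    camera_offset_A: float = 400.0
    scale: float = 1.0
    read_sd: float = 10.0
    excess_factor: float = 1.414
    bleach_rate_D: float = 0.0
    bleach_rate_A: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.read_sd < 0 or self.excess_factor < 1.0:
            raise ValueError("read_sd >= 0 and excess_factor >= 1 required")
        if self.bleach_rate_D < 0 or self.bleach_rate_A < 0:
            raise ValueError("bleach rates must be non-negative")


def default_fret_calibration(noise: NoiseModel | None = None) -> ChannelCalibration:
    """Balanced two-channel calibration for the plain FRET dye pair.

    No spectral crosstalk and no direct acceptor excitation, so the
    offset-subtracted proximity ratio a/(a + d) equals the FRET
    efficiency exactly; donor baselines fall in the 1200-2000 count range
    observed for surface-immobilized DNA.
    """
    noise = noise or NoiseModel()
    return ChannelCalibration(
        dbar_DD=1600.0, abar_DD=0.0, abar_AD=1600.0, abar_AA=0.0,
        c_D=noise.camera_offset_D, c_A=noise.camera_offset_A,
    )


def default_pife_calibration(noise: NoiseModel | None = None) -> ChannelCalibration:
    """Calibration for the Cy3/acceptor hybrid pair with donor-to-acceptor
    bleed-through and direct acceptor excitation (acceptor-to-donor
    bleed-through blocked by the donor pass band)."""
    noise = noise or NoiseModel()
    return ChannelCalibration(
        dbar_DD=1600.0, abar_DD=140.0, abar_AD=1750.0, abar_AA=120.0,
        c_D=noise.camera_offset_D, c_A=noise.camera_offset_A,
    )


# ---------------------------------------------------------------------------
# State trajectories
# ---------------------------------------------------------------------------


@dataclass
class ContinuousStatePath:
    """Piecewise-constant state trajectory.

    ``states`` holds the visited state indices (0 = P, 1 = F) and
    ``entry_times`` the strictly increasing entry time of each visit,
    starting at 0; the path is defined on [0, duration).
    """

    states: np.ndarray
    entry_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        if len(self.states) != len(self.entry_times):
            raise ValueError("states and entry_times differ in length")
        if len(self.entry_times) == 0 or self.entry_times[0] != 0.0:
            raise ValueError("path must start at time 0")
        if np.any(np.diff(self.entry_times) <= 0):
            raise ValueError("entry times must be strictly increasing")
        if self.duration <= self.entry_times[-1]:
            raise ValueError("duration must exceed the last entry time")

    def dwell_durations(self) -> np.ndarray:
        """Durations of all visits (last one truncated at ``duration``)."""
        bounds = np.append(self.entry_times, self.duration)
        return np.diff(bounds)

    def time_in_state(self, state: int) -> float:
        return float(self.dwell_durations()[self.states == state].sum())


def simulate_state_path(
    model: TwoStateBendingModel,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> ContinuousStatePath:
    """Simulate a two-state continuous-time Markov trajectory.

    Waiting times are exponential with the state exit rates; the initial
    state is drawn from the stationary distribution.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = np.array([model.rate_bend, model.rate_unbend])
    p_F = model.stationary_fraction_F
    state = 1 if rng.random() < p_F else 0

    states, entries = [state], [0.0]
    t = rng.exponential(1.0 / rates[state])
    while t < duration:
        state = 1 - state
        states.append(state)
        entries.append(t)
        t += rng.exponential(1.0 / rates[state])
    return ContinuousStatePath(np.array(states), np.array(entries), duration)


# ---------------------------------------------------------------------------
# Frame binning
# ---------------------------------------------------------------------------


@dataclass
class FrameIdeal:
    """Per-frame ideal photophysics from exposure-window averaging."""

    f: np.ndarray        # ideal FRET per frame
    q: np.ndarray        # ideal donor PIFE factor per frame
    fret_sd: np.ndarray  # occupancy-interpolated per-frame FRET SD
    frac_F: np.ndarray   # fraction of the exposure window spent in F
    time: np.ndarray     # frame start times, seconds


def bin_to_frames(
    path: ContinuousStatePath,
    model: TwoStateBendingModel,
    config: AcquisitionConfig,
) -> FrameIdeal:
    """Bin a continuous trajectory into per-frame ideal (FRET, PIFE).

    Each frame's value is the dwell-time-weighted average of the state
    values over that frame's exposure window [i/rate, i/rate + exposure).
    """
    if path.duration + 1e-12 < config.duration:
        raise ValueError(
            f"path duration {path.duration:.3f}s shorter than acquisition "
            f"{config.duration:.3f}s"
        )
    bounds = np.append(path.entry_times, path.duration)
    seg_dur = np.diff(bounds)
    # cumulative time spent in F up to each segment boundary
    cum_F = np.concatenate([[0.0], np.cumsum(seg_dur * (path.states == 1))])

    def F_occupancy_up_to(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(bounds, t, side="right") - 1
        idx = np.clip(idx, 0, len(seg_dur) - 1)
        partial = (t - bounds[idx]) * (path.states[idx] == 1)
        return cum_F[idx] + partial

    starts = np.arange(config.n_frames) / config.frame_rate
    ends = starts + config.exposure
    frac_F = (F_occupancy_up_to(ends) - F_occupancy_up_to(starts)) / config.exposure
    frac_F = np.clip(frac_F, 0.0, 1.0)

    f = model.fret_mean_P + frac_F * (model.fret_mean_F - model.fret_mean_P)
    q = model.pife_P + frac_F * (model.pife_F - model.pife_P)
    sd = model.fret_sd_P + frac_F * (model.fret_sd_F - model.fret_sd_P)
    return FrameIdeal(f=f, q=q, fret_sd=sd, frac_F=frac_F, time=starts)


# ---------------------------------------------------------------------------
# Count rendering
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Per-molecule two-channel camera-count time trace."""

    donor: np.ndarray
    acceptor: np.ndarray
    time: np.ndarray
    donor_alive: np.ndarray | None = None
    acceptor_alive: np.ndarray | None = None
    trace_id: int = 0

    def __len__(self) -> int:
        return len(self.donor)


def render_counts(
    frames: FrameIdeal,
    calib: ChannelCalibration,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    add_noise: bool = True,
    trace_id: int = 0,
) -> Trace:
    """Render ideal per-frame (f, q) into measured donor/acceptor counts.

    The mean counts follow the two-channel forward detection model with
    u = 1 and q_A = 1 until the simulated acceptor bleach time (then
    q_A = 0 and the FRET pathway disappears); after donor bleach q_D = 0.
    With ``add_noise`` the Gaussian EMCCD noise of :class:`NoiseModel` is
    added and the per-frame FRET is jittered by the state-interpolated
    ``fret_sd`` before rendering.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(frames.f)
    f = frames.f.astype(float).copy()
    q = frames.q.astype(float).copy()

    donor_alive = np.ones(n, dtype=bool)
    acceptor_alive = np.ones(n, dtype=bool)
    if add_noise and noise.bleach_rate_D > 0:
        t_bleach = rng.exponential(1.0 / noise.bleach_rate_D)
        donor_alive = frames.time < t_bleach
    if add_noise and noise.bleach_rate_A > 0:
        t_bleach = rng.exponential(1.0 / noise.bleach_rate_A)
        acceptor_alive = frames.time < t_bleach

    if add_noise:
        f = f + rng.normal(0.0, 1.0, n) * frames.fret_sd

    f = np.where(acceptor_alive, f, 0.0)  # no acceptor, no energy transfer
    qD = np.where(donor_alive, q, 0.0)
    qA = acceptor_alive.astype(float)
    d, a = forward_model_arrays(f, qD, calib, q_A=qA, u=1.0)

    if add_noise:
        var_d = noise.read_sd ** 2 + noise.excess_factor ** 2 * noise.scale \
            * np.maximum(d - calib.c_D, 0.0)
        var_a = noise.read_sd ** 2 + noise.excess_factor ** 2 * noise.scale \
            * np.maximum(a - calib.c_A, 0.0)
        d = d + rng.normal(0.0, 1.0, n) * np.sqrt(var_d)
        a = a + rng.normal(0.0, 1.0, n) * np.sqrt(var_a)

    return Trace(donor=d, acceptor=a, time=frames.time,
                 donor_alive=donor_alive, acceptor_alive=acceptor_alive,
                 trace_id=trace_id)


def simulate_fret_traces(
    model: TwoStateBendingModel,
    config: AcquisitionConfig,
    noise_sd: float | None = None,
) -> tuple[list[np.ndarray], list[ContinuousStatePath]]:
    """Convenience generator of per-frame FRET traces (no camera rendering).

    Each trace is the exposure-window-averaged ideal FRET plus Gaussian
    emission noise of the state-interpolated SD (or a fixed ``noise_sd``).
    Returns the traces together with the generating ground-truth paths.
    """
    rng = np.random.default_rng(config.seed)
    traces, paths = [], []
    for _ in range(config.n_traces):
        path = simulate_state_path(model, config.duration * 1.001 + 1e-6, rng)
        frames = bin_to_frames(path, model, config)
        sd = frames.fret_sd if noise_sd is None else noise_sd
        traces.append(frames.f + rng.normal(0.0, 1.0, config.n_frames) * sd)
        paths.append(path)
    return traces, paths


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def _gaussian_spot(shape, x, y, sigma, intensity):
    """Pixel-integrated symmetric Gaussian spot (exact erf integration)."""
    H, W = shape
    xs = np.arange(W)
    ys = np.arange(H)
    # pixel-center convention: pixel i spans [i - 0.5, i + 0.5]
    sx = np.sqrt(2.0) * sigma
    fx = 0.5 * (erf((xs + 0.5 - x) / sx) - erf((xs - 0.5 - x) / sx))
    fy = 0.5 * (erf((ys + 0.5 - y) / sx) - erf((ys - 0.5 - y) / sx))
    return intensity * np.outer(fy, fx)


def render_image_stack(
    positions: np.ndarray,
    traces: list[Trace],
    psf_sigma: float = 1.2,
    drift: np.ndarray | None = None,
    field: tuple[int, int] = (64, 64),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    add_noise: bool = True,
    margin: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render molecules as drifting 2-D Gaussian spots in both channels.

    Each molecule's spot has integrated intensity equal to its per-frame
    channel counts above the camera offset; the offset and read noise are
    added per pixel.  Returns (donor_stack, acceptor_stack) of shape
    (n_frames, H, W).
    """
    positions = np.asarray(positions, dtype=float)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    H, W = field
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2) [x, y] pairs")
    if len(positions) != len(traces):
        raise ValueError("one trace per position required")
    if np.any(positions[:, 0] < margin) or np.any(positions[:, 0] > W - 1 - margin) \
            or np.any(positions[:, 1] < margin) or np.any(positions[:, 1] > H - 1 - margin):
        raise ValueError(f"positions must lie inside the field with a "
                         f"{margin}-px margin")
    n_frames = len(traces[0]) if traces else \
        (len(drift) if drift is not None else 1)
    if drift is None:
        drift = np.zeros((n_frames, 2))
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_frames, 2):
        raise ValueError("drift must be (n_frames, 2)")

    stack_D = np.full((n_frames, H, W), noise.camera_offset_D, dtype=float)
    stack_A = np.full((n_frames, H, W), noise.camera_offset_A, dtype=float)
    for t in range(n_frames):
        dx, dy = drift[t]
        for (x, y), tr in zip(positions, traces):
            i_d = tr.donor[t] - noise.camera_offset_D
            i_a = tr.acceptor[t] - noise.camera_offset_A
            if i_d > 0:
                stack_D[t] += _gaussian_spot((H, W), x + dx, y + dy, psf_sigma, i_d)
            if i_a > 0:
                stack_A[t] += _gaussian_spot((H, W), x + dx, y + dy, psf_sigma, i_a)
    if add_noise and noise.read_sd > 0:
        stack_D += rng.normal(0.0, noise.read_sd, stack_D.shape)
        stack_A += rng.normal(0.0, noise.read_sd, stack_A.shape)
    return stack_D, stack_A


# ---------------------------------------------------------------------------
# Ensemble curves
# ---------------------------------------------------------------------------


def simulate_titration(
    model: BindingKineticModel,
    A0_grid: np.ndarray,
    D0: float = 5.0,
    r_free: float = 0.05,
    r_bound: float = 0.20,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium anisotropy titration with exact ligand depletion.

    r(A0) = r_free + (r_bound - r_free) * P_bound from the composite
    two-state occupancy, plus optional Gaussian noise.  Returns
    (A0_grid, r).
    """
    A0_grid = np.asarray(A0_grid, dtype=float)
    if np.any(A0_grid < 0) or np.any(np.diff(A0_grid) < 0):
        raise ValueError("A0 grid must be non-negative and ascending")
    if not r_bound > r_free:
        raise ValueError("r_bound must exceed r_free")
    p = np.array([
        binding_occupancy(D0, a0, model.pure_Kd, model.K2).p_bound
        for a0 in A0_grid
    ])
    r = r_free + (r_bound - r_free) * p
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        r = r + rng.normal(0.0, noise_sd, r.shape)
    return A0_grid, r


def simulate_stopped_flow(
    model: BindingKineticModel,
    times: np.ndarray,
    weights: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissociation decay after rapid mixing with excess competitor DNA.

    The complex starts at the pre-trap conformational equilibrium
    (N_F/N_P = K2) and decays through the P-state; the observable is the
    FRET-weighted acceptor signal w_P N_P(t) + w_F N_F(t) normalized to 1
    at t = 0.  Default weights are the state FRET means (0.22, 0.65) of
    the reference substrate, since the acceptor signal is FRET-weighted.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must ascend from 0")
    if weights is None:
        weights = (0.22, 0.65)
    w_P, w_F = weights
    K2 = model.K2
    N_P0 = 1.0 / (1.0 + K2)
    N_F0 = K2 / (1.0 + K2)
    N_P, N_F = dissociation_curve(N_P0, N_F0, model, times)
    signal = w_P * N_P + w_F * N_F
    signal = signal / signal[0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    return times, signal
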