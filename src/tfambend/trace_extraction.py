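"""TIRF image pipeline: registration, spot detection, drift, trace extraction.

Single molecules appear as diffraction-limited spots in a split-camera
two-channel (donor/acceptor) image stack.  The pipeline mirrors standard
practice for surface-immobilized smFRET movies:

1. map the acceptor channel onto the donor channel with an affine
   transform calibrated from multispectral bead images,
2. average a subset of frames, enhance contrast with a Laplacian of
   Gaussian filter, threshold local maxima against the robust background
   fluctuation level, and localize candidates with 11x11 2-D Gaussian
   fits (sub-pixel precision),
3. track bright anchor spots on 10-frame-averaged blocks to estimate the
   stage drift, interpolated/extrapolated to every frame,
4. extract per-frame aperture-summed, annulus-background-subtracted
   counts in both channels at the drift-corrected positions.

Coordinates are 0-based (x, y) with the pixel-center convention: integer
coordinates address pixel centers and pixel i spans [i - 0.5, i + 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .synthetic_data import Trace

__all__ = [
    "AffineTransform2D",
    "SpotCandidate",
    "DriftSeries",
    "TraceSet",
    "register_channels",
    "detect_spots",
    "localize_spot",
    "estimate_drift",
    "extract_traces",
]


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineTransform2D:
    """2-D affine map p -> M p + b (pixels), acceptor -> donor frame."""

    matrix: tuple = ((1.0, 0.0), (0.0, 1.0))
    offset: tuple = (0.0, 0.0)
    residual_rms: float = 0.0
    warning: bool = False

    def __post_init__(self) -> None:
        if abs(np.linalg.det(np.asarray(self.matrix))) <= 1e-6:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ np.asarray(self.matrix).T + np.asarray(self.offset)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform2D":
        Minv = np.linalg.inv(np.asarray(self.matrix))
        binv = -Minv @ np.asarray(self.offset)
        return AffineTransform2D(tuple(map(tuple, Minv)), tuple(binv),
                                 self.residual_rms, self.warning)


@dataclass
class SpotCandidate:
    """Sub-pixel spot localization result (0-based pixel-center coords)."""

    x: float
    y: float
    amplitude: float
    sigma: float
    background: float
    ok: bool = True
    flags: list = field(default_factory=list)


@dataclass
class DriftSeries:
    """Per-frame (dx, dy) stage drift in pixels, zero at frame 0."""

    dxdy: np.ndarray

    def __post_init__(self) -> None:
        self.dxdy = np.asarray(self.dxdy, dtype=float).reshape(-1, 2)
        self.dxdy = self.dxdy - self.dxdy[0]

    def __len__(self) -> int:
        return len(self.dxdy)


@dataclass
class TraceSet:
    """A set of per-molecule two-channel traces plus acquisition metadata."""

    traces: list
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# ---------------------------------------------------------------------------
# Gaussian localization
# ---------------------------------------------------------------------------


def localize_spot(crop: np.ndarray) -> SpotCandidate:
    """Fit a symmetric 2-D Gaussian + constant background to an 11x11 crop.

    Weighted least squares with shot-noise weights 1/sqrt(counts).
    Returns coordinates in the crop frame (center pixel at (5, 5));
    degenerate or non-convergent fits are returned flagged (``ok=False``)
    and are excluded downstream.
    """
    crop = np.asarray(crop, dtype=float)
    if crop.shape != (11, 11):
        raise ValueError("crop must be exactly 11x11")
    yy, xx = np.mgrid[0:11, 0:11]
    bg0 = float(np.median(np.concatenate([crop[0], crop[-1],
                                          crop[1:-1, 0], crop[1:-1, -1]])))
    amp0 = float(crop.max() - bg0)
    if amp0 <= 0:
        return SpotCandidate(5.0, 5.0, 0.0, 1.0, bg0, ok=False,
                             flags=["flat"])
    w = crop - bg0
    w = np.clip(w, 0, None)
    tot = w.sum()
    x0 = float((xx * w).sum() / tot) if tot > 0 else 5.0
    y0 = float((yy * w).sum() / tot) if tot > 0 else 5.0
    weights = 1.0 / np.sqrt(np.clip(crop, 1.0, None))

    def resid(p):
        A, x, y, s, b = p
        model = A * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s * s)) + b
        return ((model - crop) * weights).ravel()

    try:
        sol = least_squares(
            resid, [amp0, x0, y0, 1.5, bg0],
            bounds=([0, 0, 0, 0.3, -np.inf], [np.inf, 10, 10, 8, np.inf]),
            max_nfev=200,
        )
    except Exception:
        return SpotCandidate(x0, y0, amp0, 1.5, bg0, ok=False,
                             flags=["fit_error"])
    A, x, y, s, b = sol.x
    flags = []
    ok = sol.status > 0
    res_sd = np.std(sol.fun)
    if A < 3.0 * res_sd * np.median(np.sqrt(np.clip(crop, 1.0, None))):
        ok, flags = False, flags + ["low_amplitude"]
    if not sol.status > 0:
        flags.append("no_convergence")
    if s >= 7.9 or s <= 0.31:
        ok, flags = False, flags + ["sigma_bound"]
    return SpotCandidate(float(x), float(y), float(A), float(s), float(b),
                         ok=ok, flags=flags)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_spots(
    stack: np.ndarray,
    subset_fraction: float = 0.1,
    threshold_factor: float = 8.0,
    log_sigma: float = 1.2,
    min_distance: int = 3,
    reject_outliers: bool = True,
) -> list[SpotCandidate]:
    """Detect and localize single-molecule spots in an image stack.

    An evenly spaced subset of frames (default 10%) is averaged, the
    average is LoG-filtered, and local maxima exceeding
    ``threshold_factor`` times the robust (MAD-based) background SD of
    the filtered image are accepted; an 11x11 crop around each maximum is
    Gaussian-fitted for sub-pixel localization.  Candidates whose fitted
    sigma or amplitude falls outside median +- 3 MAD of the population
    are discarded as outliers.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.size == 0:
        raise ValueError("empty image stack")
    n = len(stack)
    step = max(1, int(round(1.0 / max(subset_fraction, 1e-6))))
    avg = stack[::step].mean(axis=0)

    filt = -gaussian_laplace(avg, sigma=log_sigma)
    mad = np.median(np.abs(filt - np.median(filt))) * 1.4826
    thresh = np.median(filt) + threshold_factor * max(mad, 1e-12)
    peaks = peak_local_max(filt, min_distance=min_distance,
                           threshold_abs=thresh, exclude_border=5)

    cands = []
    H, W = avg.shape
    for py, px in peaks:
        if not (5 <= px < W - 5 and 5 <= py < H - 5):
            continue
        crop = avg[py - 5:py + 6, px - 5:px + 6]
        c = localize_spot(crop)
        if not c.ok:
            continue
        c.x += px - 5
        c.y += py - 5
        cands.append(c)

    if reject_outliers and len(cands) >= 5:
        cands = _reject_outliers(cands)
    return cands


def _reject_outliers(cands: list[SpotCandidate]) -> list[SpotCandidate]:
    sig = np.array([c.sigma for c in cands])
    amp = np.array([c.amplitude for c in cands])

    def inliers(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad == 0:
            return np.ones(len(v), bool)
        return np.abs(v - med) <= 3.0 * mad

    keep = inliers(sig) & inliers(amp)
    return [c for c, k in zip(cands, keep) if k]


# ---------------------------------------------------------------------------
# Channel registration
# ---------------------------------------------------------------------------


def register_channels(
    bead_images_D: np.ndarray,
    bead_images_A: np.ndarray,
    max_match_distance: float = 5.0,
    rms_warn: float = 0.5,
    threshold_factor: float = 8.0,
) -> AffineTransform2D:
    """Least-squares affine map from acceptor onto donor coordinates.

    Beads visible in both channels are detected and matched by nearest
    neighbour (valid while the channel misalignment is smaller than the
    bead spacing); the affine parameters minimize the squared residuals
    over all matched pairs.  At least 3 non-collinear pairs are required;
    a residual RMS above ``rms_warn`` pixels sets the warning flag.
    """
    spots_D = detect_spots(np.asarray(bead_images_D),
                           threshold_factor=threshold_factor)
    spots_A = detect_spots(np.asarray(bead_images_A),
                           threshold_factor=threshold_factor)
    if len(spots_D) < 3 or len(spots_A) < 3:
        raise RegistrationError(
            f"too few beads detected (donor {len(spots_D)}, acceptor "
            f"{len(spots_A)}); need >= 3 matched pairs"
        )
    P_D = np.array([[c.x, c.y] for c in spots_D])
    P_A = np.array([[c.x, c.y] for c in spots_A])
    pairs = []
    for pa in P_A:
        dist = np.linalg.norm(P_D - pa, axis=1)
        j = np.argmin(dist)
        if dist[j] <= max_match_distance:
            pairs.append((pa, P_D[j]))
    if len(pairs) < 3:
        raise RegistrationError("fewer than 3 matched bead pairs")
    A = np.array([p[0] for p in pairs])
    D = np.array([p[1] for p in pairs])
    if np.linalg.matrix_rank(A - A.mean(axis=0)) < 2:
        raise RegistrationError("matched beads are collinear")

    # least squares for x' = m00 x + m01 y + bx (and same for y')
    G = np.column_stack([A, np.ones(len(A))])
    coef, *_ = np.linalg.lstsq(G, D, rcond=None)
    M = coef[:2].T
    b = coef[2]
    resid = D - (A @ M.T + b)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    warn = rms > rms_warn
    if warn:
        warnings.warn(f"channel registration residual RMS {rms:.3f} px "
                      f"exceeds {rms_warn} px", stacklevel=2)
    return AffineTransform2D(tuple(map(tuple, M)), tuple(b), rms, warn)


# ---------------------------------------------------------------------------
# Drift estimation
# ---------------------------------------------------------------------------


def estimate_drift(
    stack: np.ndarray,
    anchors: np.ndarray,
    block: int = 10,
) -> DriftSeries:
    """Estimate per-frame stage drift by tracking anchor spots.

    The stack is down-sampled by averaging every ``block`` frames to
    improve localization SNR; each anchor is re-localized on every block
    average and the robust (median) displacement across anchors gives the
    block drift, which is linearly interpolated between block centers and
    extrapolated to the trace ends.
    """
    stack = np.asarray(stack, dtype=float)
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    if len(anchors) < 1:
        raise ValueError("need at least one anchor spot")
    n = len(stack)
    n_blocks = max(1, n // block)
    centers = []
    disps = []
    prev = np.zeros(2)
    H, W = stack.shape[1:]
    for bi in range(n_blocks):
        avg = stack[bi * block:(bi + 1) * block].mean(axis=0)
        ds = []
        for ax, ay in anchors:
            cx = int(round(ax + prev[0]))
            cy = int(round(ay + prev[1]))
            if not (5 <= cx < W - 5 and 5 <= cy < H - 5):
                continue
            c = localize_spot(avg[cy - 5:cy + 6, cx - 5:cx + 6])
            if c.ok:
                ds.append([c.x + cx - 5 - ax, c.y + cy - 5 - ay])
        if ds:
            d = np.median(np.array(ds), axis=0)
            disps.append(d)
            centers.append(bi * block + (block - 1) / 2.0)
            prev = d
    if not disps:
        raise RuntimeError("all anchor spots lost; cannot estimate drift")
    centers = np.array(centers)
    disps = np.array(disps)

    frames = np.arange(n, dtype=float)
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = _interp_extrap(frames, centers, disps[:, k])
    return DriftSeries(out)


def _interp_extrap(x, xp, fp):
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:  # linear extrapolation beyond the block centers
        lo = x < xp[0]
        hi = x > xp[-1]
        s0 = (fp[1] - fp[0]) / (xp[1] - xp[0])
        s1 = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[lo] = fp[0] + s0 * (x[lo] - xp[0])
        y[hi] = fp[-1] + s1 * (x[hi] - xp[-1])
    return y


# ---------------------------------------------------------------------------
# Trace extraction
# ---------------------------------------------------------------------------


def _disc_offsets(radius: int):
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    m = xx ** 2 + yy ** 2 <= radius ** 2
    return xx[m], yy[m]


def _annulus_offsets(r_in: int, r_out: int):
    yy, xx = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1]
    r2 = xx ** 2 + yy ** 2
    m = (r2 > r_in ** 2) & (r2 <= r_out ** 2)
    return xx[m], yy[m]


def extract_traces(
    stack_D: np.ndarray,
    stack_A: np.ndarray,
    transform: AffineTransform2D,
    candidates: list[SpotCandidate],
    drift: DriftSeries | None = None,
    frame_interval: float = 1.0 / 65.0,
    aperture_radius: int = 3,
    annulus: tuple[int, int] = (4, 6),
) -> TraceSet:
    """Extract background-subtracted two-channel traces for each candidate.

    Candidates are given in donor-frame coordinates; the acceptor position
    is obtained through the inverse channel transform.  Per frame, counts
    are summed over a radius-``aperture_radius`` pixel disc at the
    drift-corrected position and the local background (median of an
    annulus, times the disc area) is subtracted.  Frames where the
    aperture leaves the field are truncated off the trace (flagged in the
    trace-set metadata).
    """
    stack_D = np.asarray(stack_D, dtype=float)
    stack_A = np.asarray(stack_A, dtype=float)
    n, H, W = stack_D.shape
    if drift is None:
        drift = DriftSeries(np.zeros((n, 2)))
    if len(drift) != n:
        raise ValueError("drift series length must match the stack")
    inv = transform.inverse()
    dxo, dyo = _disc_offsets(aperture_radius)
    axo, ayo = _annulus_offsets(*annulus)
    n_ap = len(dxo)
    times = np.arange(n) * frame_interval

    traces = []
    truncated = {}
    for tid, c in enumerate(candidates):
        pos_D = np.array([c.x, c.y])
        pos_A = inv.apply(pos_D)
        d_counts = np.full(n, np.nan)
        a_counts = np.full(n, np.nan)
        valid_until = n
        for t in range(n):
            ok = True
            for stack, pos, out in ((stack_D, pos_D, d_counts),
                                    (stack_A, pos_A, a_counts)):
                cx = int(round(pos[0] + drift.dxdy[t, 0]))
                cy = int(round(pos[1] + drift.dxdy[t, 1]))
                r_out = annulus[1]
                if not (r_out <= cx < W - r_out and r_out <= cy < H - r_out):
                    ok = False
                    break
                img = stack[t]
                ap = img[cy + dyo, cx + dxo]
                bg = np.median(img[cy + ayo, cx + axo])
                out[t] = ap.sum() - bg * n_ap
            if not ok:
                valid_until = t
                break
        if valid_until < n:
            truncated[tid] = valid_until
        traces.append(Trace(
            donor=d_counts[:valid_until],
            acceptor=a_counts[:valid_until],
            time=times[:valid_until],
            trace_id=tid,
        ))
    return TraceSet(traces, frame_interval,
                    metadata={"truncated": truncated,
                              "n_candidates": len(candidates)})
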