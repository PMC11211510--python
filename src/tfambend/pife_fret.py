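"""Hybrid PIFE-FRET decoupling: forward detection model, calibration, inversion.

A donor dye whose quantum yield responds to nearby protein (PIFE, modelled
as a factor q_D >= 1) and FRET to an acceptor both change the measured
donor/acceptor camera counts, but differently: PIFE scales the total
emission while FRET redistributes it between channels.  With a calibrated
two-channel detection model the two effects can be separated frame by
frame.

The forward model for measured counts (d, a) is

    d = u q_D [d_DD (1-f) + d_AD f] + u q_A d_AA + c_D
    a = u q_D [a_DD (1-f) + a_AD f] + u q_A a_AA + c_A

where u is the normalized excitation power, q_D/q_A the normalized donor/
acceptor quantum efficiencies, f the FRET efficiency, the barred composites
fold detection efficiencies and reference emissions together, and c_D/c_A
are camera offsets.  When the acceptor-to-donor bleed-through vanishes
(sharp donor pass band), d_AD = d_AA = 0 and six calibration parameters
remain.  They are determined from the photobleaching-event clusters of two
calibration DNA constructs (donor dye internally vs. end labelled, giving a
high and a low FRET reference) and then used to invert measured traces into
per-frame (f, q_D).

For measurement traces the per-frame excitation power is fixed to u = 1:
each frame provides only two observables (d, a), so at most two of
(u, q_D, f) are identifiable; u only varied between sample mounts during
calibration (captured by u_L).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.mixture import GaussianMixture

__all__ = [
    "ChannelCalibration",
    "PhotophysicsFrame",
    "CalibrationClusters",
    "forward_model",
    "forward_model_arrays",
    "cluster_calibration_points",
    "solve_calibration",
    "invert_trace",
]

CLUSTER_LABELS = (
    "both_bleached",
    "donor_bleached",
    "acceptor_bleached",
    "live",
)


class CalibrationError(RuntimeError):
    """Raised when the calibration solve fails or clusters are degenerate."""


@dataclass(frozen=True)
class ChannelCalibration:
    """The composite detection parameters of the two-channel forward model.

    All in camera counts.  ``dbar_AD``/``dbar_AA`` are the acceptor-to-donor
    bleed-through composites, identically 0 when the donor pass band blocks
    acceptor emission (e_DA = 0), which is the default convention here.
    """

    dbar_DD: float
    abar_DD: float
    abar_AD: float
    abar_AA: float
    c_D: float
    c_A: float
    dbar_AD: float = 0.0
    dbar_AA: float = 0.0

    def __post_init__(self) -> None:
        if self.dbar_DD <= 0 or self.abar_AD <= 0:
            raise ValueError("dbar_DD and abar_AD must be positive")
        if min(self.abar_DD, self.abar_AA, self.c_D, self.c_A,
               self.dbar_AD, self.dbar_AA) < 0:
            raise ValueError("calibration parameters must be non-negative")

    def to_json(self, **extra) -> str:
        doc = {"units": "camera counts", "params": asdict(self)}
        doc.update(extra)
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ChannelCalibration":
        return cls(**json.loads(text)["params"])


@dataclass(frozen=True)
class PhotophysicsFrame:
    """Per-frame photophysical state: (u, q_D, q_A, f)."""

    u: float = 1.0
    q_D: float = 1.0
    q_A: float = 1.0
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")
        if self.q_D < 0 or self.q_A < 0:
            raise ValueError("quantum-yield factors must be non-negative")


@dataclass
class CalibrationClusters:
    """Labelled (donor mean, acceptor mean) pairs for one calibration construct.

    ``construct`` is "mid" (donor dye internal to the binding site, high
    FRET reference, u = 1 by convention) or "end" (donor dye at the DNA
    end, low FRET reference, u = u_L).
    """

    construct: str
    means: dict = field(default_factory=dict)  # label -> (d, a)

    def __post_init__(self) -> None:
        if self.construct not in ("mid", "end"):
            raise ValueError("construct must be 'mid' or 'end'")

    @property
    def live_label(self) -> str:
        return "live_high" if self.construct == "mid" else "live_low"


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def forward_model(
    frame: PhotophysicsFrame, calib: ChannelCalibration
) -> tuple[float, float]:
    """Ideal measured counts (d, a) for one photophysical frame."""
    u, qD, qA, f = frame.u, frame.q_D, frame.q_A, frame.f
    d = u * qD * (calib.dbar_DD * (1.0 - f) + calib.dbar_AD * f) \
        + u * qA * calib.dbar_AA + calib.c_D
    a = u * qD * (calib.abar_DD * (1.0 - f) + calib.abar_AD * f) \
        + u * qA * calib.abar_AA + calib.c_A
    return d, a


def forward_model_arrays(
    f: np.ndarray,
    q_D: np.ndarray,
    calib: ChannelCalibration,
    q_A: np.ndarray | float = 1.0,
    u: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward model over per-frame (f, q_D[, q_A]) arrays."""
    f = np.asarray(f, dtype=float)
    q_D = np.asarray(q_D, dtype=float)
    q_A = np.broadcast_to(np.asarray(q_A, dtype=float), f.shape)
    if f.shape != q_D.shape:
        raise ValueError("f and q_D must have the same length")
    d = u * q_D * (calib.dbar_DD * (1.0 - f) + calib.dbar_AD * f) \
        + u * q_A * calib.dbar_AA + calib.c_D
    a = u * q_D * (calib.abar_DD * (1.0 - f) + calib.abar_AD * f) \
        + u * q_A * calib.abar_AA + calib.c_A
    return d, a


# ---------------------------------------------------------------------------
# Calibration clustering and solve
# ---------------------------------------------------------------------------


def cluster_calibration_points(
    points: np.ndarray,
    construct: str,
    n_clusters: int = 4,
    seed: int | None = 0,
) -> CalibrationClusters:
    """Cluster (d, a) calibration points and label the photophysical events.

    A single construct's traces show four event clusters: both dyes
    bleached, donor-only bleached, acceptor-only bleached, and the live
    (both dyes active) FRET state.  Clusters are found by a 2-D Gaussian
    mixture and labelled by their geometry:

    - both_bleached: smallest total counts (offsets only),
    - donor_bleached: donor counts at offset, acceptor still lit,
    - acceptor_bleached: largest donor counts (no FRET loss),
    - live: the remaining cluster.

    Label assignment is a function of the fitted means only, hence
    invariant to point order.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2) donor/acceptor pairs")
    if len(points) < 50:
        raise ValueError("need at least 50 calibration points")
    gmm = GaussianMixture(
        n_components=n_clusters, covariance_type="full",
        random_state=seed, n_init=5,
    ).fit(points)
    means = gmm.means_.copy()

    # degenerate-cluster diagnostic: two components overlapping within a
    # few of their own SDs means fewer distinct clusters than requested
    scales = np.sqrt(np.trace(gmm.covariances_, axis1=1, axis2=2) / 2.0)
    for i in range(n_clusters):
        for j in range(i + 1, n_clusters):
            sep = np.linalg.norm(means[i] - means[j])
            if sep < 2.5 * 0.5 * (scales[i] + scales[j]):
                raise CalibrationError(
                    f"degenerate clusters {i} and {j}: means "
                    f"{means[i]} ~ {means[j]} (separation {sep:.1f})"
                )

    order = {}
    remaining = list(range(n_clusters))
    totals = means.sum(axis=1)
    i_bb = remaining[np.argmin(totals[remaining])]
    order["both_bleached"] = i_bb
    remaining.remove(i_bb)
    # donor bleached: donor coordinate closest to the both-bleached donor level
    i_db = remaining[np.argmin(np.abs(means[remaining, 0] - means[i_bb, 0]))]
    order["donor_bleached"] = i_db
    remaining.remove(i_db)
    i_ab = remaining[np.argmax(means[remaining, 0])]
    order["acceptor_bleached"] = i_ab
    remaining.remove(i_ab)
    (i_live,) = remaining

    cc = CalibrationClusters(construct=construct)
    cc.means = {
        "both_bleached": tuple(means[i_bb]),
        "donor_bleached": tuple(means[i_db]),
        "acceptor_bleached": tuple(means[i_ab]),
        cc.live_label: tuple(means[i_live]),
    }
    return cc


def _cluster_frames(cc: CalibrationClusters, f_key: str, u_key: str):
    """(q_D, q_A, f symbol, u symbol, observed d, a) rows for one construct.

    f and u are referenced symbolically by key ('one' for u = 1, 'fH'/'fL',
    'uL') so that the same row builder serves both constructs.
    """
    rows = []
    lab = cc.live_label
    m = cc.means
    rows.append((0.0, 0.0, None, None, m["both_bleached"]))
    rows.append((0.0, 1.0, None, u_key, m["donor_bleached"]))
    rows.append((1.0, 0.0, "zero", u_key, m["acceptor_bleached"]))
    rows.append((1.0, 1.0, f_key, u_key, m[lab]))
    return rows


def solve_calibration(
    clusters_mid: CalibrationClusters,
    clusters_end: CalibrationClusters,
) -> tuple[ChannelCalibration, float, float, float, float]:
    """Solve the stacked forward-model system for the calibration.

    Conventions: bleached dyes have q = 0, live dyes q = 1; the mid
    construct defines u = 1 and FRET f_H, the end construct has u = u_L
    and FRET f_L; acceptor-to-donor bleed-through is absent (e_DA = 0 so
    dbar_AD = dbar_AA = 0).  The 16 cluster-mean coordinates (4 clusters x
    2 channels x 2 constructs) over-determine the 9 unknowns
    (dbar_DD, abar_DD, abar_AD, abar_AA, c_D, c_A, f_H, f_L, u_L); the
    system is solved by damped least squares from closed-form initial
    guesses.

    Returns
    -------
    (calibration, f_H, f_L, u_L, residual_rms)
    """
    if clusters_mid.construct != "mid" or clusters_end.construct != "end":
        raise ValueError("pass the mid-labelled construct first, end second")

    rows = _cluster_frames(clusters_mid, "fH", "one") + \
        _cluster_frames(clusters_end, "fL", "uL")

    def unpack(x):
        dDD, aDD, aAD, aAA, cD, cA, fH, fL, uL = x
        fmap = {"zero": 0.0, "fH": fH, "fL": fL, None: 0.0}
        umap = {"one": 1.0, "uL": uL, None: 1.0}
        return dDD, aDD, aAD, aAA, cD, cA, fmap, umap

    def residuals(x):
        dDD, aDD, aAD, aAA, cD, cA, fmap, umap = unpack(x)
        res = []
        for qD, qA, fkey, ukey, (d_obs, a_obs) in rows:
            f = fmap[fkey]
            u = umap[ukey]
            d = u * qD * dDD * (1.0 - f) + cD
            a = u * qD * (aDD * (1.0 - f) + aAD * f) + u * qA * aAA + cA
            res.extend((d - d_obs, a - a_obs))
        return np.array(res)

    x0 = _initial_guess(clusters_mid, clusters_end)
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    dDD, aDD, aAD, aAA, cD, cA, fH, fL, uL = sol.x
    if min(dDD, aAD, uL) <= 0 or min(aDD, aAA) < -1e-6:
        raise CalibrationError(
            f"calibration solve produced non-physical parameters: {sol.x}"
        )
    if not fH > fL:
        import warnings

        warnings.warn(
            "solved f_H <= f_L: mid-labelled construct should be the "
            "high-FRET reference", stacklevel=2,
        )
    rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
    calib = ChannelCalibration(
        dbar_DD=dDD, abar_DD=max(aDD, 0.0), abar_AD=aAD,
        abar_AA=max(aAA, 0.0), c_D=cD, c_A=cA,
    )
    return calib, float(fH), float(fL), float(uL), rms


def _initial_guess(cm: CalibrationClusters, ce: CalibrationClusters) -> np.ndarray:
    """Closed-form starting point, exact for noiseless cluster means."""
    m, e = cm.means, ce.means
    cD, cA = m["both_bleached"]
    aAA = m["donor_bleached"][1] - cA
    dDD = m["acceptor_bleached"][0] - cD
    aDD = m["acceptor_bleached"][1] - cA
    uL = (e["acceptor_bleached"][0] - cD) / dDD if dDD > 0 else 1.0
    fH = 1.0 - (m["live_high"][0] - cD) / dDD if dDD > 0 else 0.7
    fL = 1.0 - (e["live_low"][0] - cD) / (uL * dDD) if dDD > 0 else 0.2
    fH = float(np.clip(fH, 0.01, 0.99))
    fL = float(np.clip(fL, 0.01, 0.99))
    aAD = (m["live_high"][1] - cA - aAA - aDD * (1.0 - fH)) / fH
    aAD = max(aAD, 1.0)
    return np.array([dDD, max(aDD, 0.0), aAD, max(aAA, 0.0), cD, cA,
                     fH, fL, max(uL, 0.1)])


# ---------------------------------------------------------------------------
# Trace inversion
# ---------------------------------------------------------------------------


def invert_trace(
    donor: np.ndarray,
    acceptor: np.ndarray,
    calib: ChannelCalibration,
    acceptor_alive: np.ndarray | None = None,
    u: float = 1.0,
    f_bounds: tuple[float, float] = (-0.1, 1.1),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert measured counts into per-frame (f, q_D).

    With dbar_AD = dbar_AA = 0 the forward model gives, per frame,

        X := d - c_D             = u q_D dbar_DD (1 - f)
        Y := a - c_A - u q_A a_AA = u q_D [a_DD (1 - f) + a_AD f]

    whose ratio is independent of q_D, yielding

        f = (Y dbar_DD - X abar_DD) / (X abar_AD + Y dbar_DD - X abar_DD)
        q_D = X / (u dbar_DD (1 - f))

    q_A is binary (1 alive, 0 bleached) via ``acceptor_alive``.

    Returns
    -------
    (f, q_D, valid) arrays; frames with a dark donor (d <= c_D) or f out
    of ``f_bounds`` are flagged invalid (f clamped to the bounds).
    """
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    if d.shape != a.shape:
        raise ValueError("donor and acceptor traces differ in length")
    if acceptor_alive is None:
        qA = np.ones_like(d)
    else:
        qA = np.asarray(acceptor_alive, dtype=float)

    X = d - calib.c_D
    Y = a - calib.c_A - u * qA * calib.abar_AA
    valid = X > 0
    Xs = np.where(valid, X, 1.0)

    denom = Xs * calib.abar_AD + Y * calib.dbar_DD - Xs * calib.abar_DD
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    f = (Y * calib.dbar_DD - Xs * calib.abar_DD) / denom
    in_range = (f >= f_bounds[0]) & (f <= f_bounds[1])
    valid &= in_range
    f = np.clip(f, f_bounds[0], f_bounds[1])

    one_minus_f = np.where(np.abs(1.0 - f) < 1e-9, np.nan, 1.0 - f)
    q_D = X / (u * calib.dbar_DD * one_minus_f)
    valid &= np.isfinite(q_D)
    return f, q_D, valid


def normalize_pife(q_D: np.ndarray, reference_mean: float) -> np.ndarray:
    """Report PIFE relative to a reference condition's mean q_D."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(q_D, dtype=float) / reference_mean


def state_average_pife(
    f_traces: list[np.ndarray],
    q_traces: list[np.ndarray],
    hmm_params=None,
    min_segment: int = 3,
) -> tuple[float, float]:
    """State-averaged donor enhancement (q_D) per FRET state.

    FRET traces are segmented with a two-state HMM (fitted here unless
    ``hmm_params`` is supplied) and q_D is averaged per state over the
    interior frames of each decoded segment: the first and last frame of
    a segment integrate emission from both states whenever the transition
    falls inside the exposure window, so they are excluded (segments
    shorter than ``min_segment`` frames contribute no interior frames).

    Returns (mean q_D in the low-FRET state, mean q_D in the high-FRET
    state).
    """
    from .hmm_segmentation import fit_hmm, viterbi_path

    if len(f_traces) != len(q_traces):
        raise ValueError("need one q_D trace per FRET trace")
    if hmm_params is None:
        hmm_params = fit_hmm(f_traces, n_states=2)
    pooled: dict[int, list] = {0: [], 1: []}
    for f, q in zip(f_traces, q_traces):
        path = viterbi_path(hmm_params, f)
        for state, s, e in path.segments:
            if e - s >= min_segment:
                seg = q[s + 1:e - 1]
                pooled[min(state, 1)].extend(seg[np.isfinite(seg)])
    if not pooled[0] or not pooled[1]:
        raise RuntimeError("one of the states has no interior frames")
    return float(np.mean(pooled[0])), float(np.mean(pooled[1]))
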