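"""Two-state Gaussian-emission HMM segmentation of single-molecule traces.

FRET traces of a protein-DNA complex hopping between a partially and a
fully bent conformation are modelled as a hidden Markov chain with
Gaussian emissions per state.  This module fits the chain by Baum-Welch
EM (log-domain forward-backward, via hmmlearn), decodes maximum a
posteriori state paths with Viterbi, and locates the photobleaching
boundaries that delimit the analyzable region of each trace.

Initialization is a deterministic quantile split of the data, so fitting
is bit-reproducible; states are always reported in ascending order of
emission mean (state 0 = low FRET = partially bent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

__all__ = [
    "GaussianHmmParams",
    "StatePath",
    "fit_hmm",
    "viterbi_path",
    "posterior_probabilities",
    "log_likelihood",
    "detect_valid_region",
    "transition_prob_to_rate",
]

VARIANCE_FLOOR = 1e-4  # FRET-units variance floor against collapse


@dataclass
class GaussianHmmParams:
    """Fitted Gaussian-emission HMM parameters (states ordered by mean)."""

    means: np.ndarray        # (n_states,) emission means
    sds: np.ndarray          # (n_states,) emission SDs
    transmat: np.ndarray     # (n_states, n_states) per-frame, row-stochastic
    startprob: np.ndarray    # (n_states,)
    log_likelihood: float = np.nan
    converged: bool = True
    variance_floored: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("states must be ordered by ascending mean")

    @property
    def n_states(self) -> int:
        return len(self.means)

    def to_hmmlearn(self) -> GaussianHMM:
        hm = GaussianHMM(n_components=self.n_states, covariance_type="diag",
                         init_params="", params="")
        hm.means_ = self.means.reshape(-1, 1)
        hm.covars_ = np.maximum(self.sds.reshape(-1, 1) ** 2, VARIANCE_FLOOR)
        hm.transmat_ = self.transmat
        hm.startprob_ = self.startprob
        return hm


@dataclass
class StatePath:
    """Decoded per-frame state labels plus run-length segments.

    ``segments`` are (state, start, end) with half-open frame ranges that
    partition [offset, offset + len(labels)); ``offset`` is the first
    frame of the valid region within the original trace.
    """

    labels: np.ndarray
    offset: int = 0
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.segments and len(self.labels):
            self.segments = _segments_from_labels(self.labels, self.offset)

    def __len__(self) -> int:
        return len(self.labels)


def _segments_from_labels(labels: np.ndarray, offset: int) -> list:
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(s + offset), int(e + offset))
            for s, e in zip(starts, ends)]


def _stack(values) -> tuple[np.ndarray, list[int]]:
    """Concatenate one trace or a list of traces for hmmlearn."""
    if isinstance(values, (list, tuple)):
        lengths = [len(v) for v in values]
        X = np.concatenate([np.asarray(v, dtype=float) for v in values])
    else:
        X = np.asarray(values, dtype=float)
        lengths = [len(X)]
    return X.reshape(-1, 1), lengths


# ---------------------------------------------------------------------------
# Fitting and decoding
# ---------------------------------------------------------------------------


def fit_hmm(
    values,
    n_states: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> GaussianHmmParams:
    """Fit a Gaussian-emission HMM by Baum-Welch EM.

    ``values`` is a single trace or a list of traces (fit jointly).
    Emission means are initialized at the interior quantiles of the
    pooled data (a deterministic split, so the fit is reproducible
    independent of ``seed``); the per-iteration log-likelihood is
    non-decreasing and iteration stops when its gain drops below ``tol``.
    Collapsing variances are floored at 1e-4 (FRET units squared) and
    flagged.
    """
    X, lengths = _stack(values)
    if len(X) < 10 * n_states:
        raise ValueError(f"need at least {10 * n_states} points to fit "
                         f"{n_states} states")
    qs = (2 * np.arange(n_states) + 1) / (2 * n_states)
    means0 = np.quantile(X[:, 0], qs)
    # nudge coincident quantiles apart so EM can separate them
    for i in range(1, n_states):
        if means0[i] - means0[i - 1] < 1e-6:
            means0[i] = means0[i - 1] + 1e-6
    sd0 = max(np.std(X[:, 0]) / n_states, 1e-3)

    hm = GaussianHMM(
        n_components=n_states, covariance_type="diag",
        n_iter=max_iter, tol=tol, min_covar=VARIANCE_FLOOR,
        init_params="", params="stmc", random_state=seed,
    )
    hm.means_ = means0.reshape(-1, 1)
    hm.covars_ = np.full((n_states, 1), sd0 ** 2)
    hm.transmat_ = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1)) \
        + np.eye(n_states) * (0.9 - 0.1 / max(n_states - 1, 1))
    hm.transmat_ /= hm.transmat_.sum(axis=1, keepdims=True)
    hm.startprob_ = np.full(n_states, 1.0 / n_states)
    hm.fit(X, lengths)

    order = np.argsort(hm.means_[:, 0])
    covars = np.asarray(hm.covars_).reshape(n_states, -1)[:, 0]
    floored = bool(np.any(covars <= VARIANCE_FLOOR * 1.5))
    params = GaussianHmmParams(
        means=hm.means_[order, 0],
        sds=np.sqrt(np.maximum(covars[order], VARIANCE_FLOOR)),
        transmat=hm.transmat_[np.ix_(order, order)],
        startprob=hm.startprob_[order],
        log_likelihood=float(hm.score(X, lengths)),
        converged=bool(hm.monitor_.converged),
        variance_floored=floored,
    )
    return params


def viterbi_path(params: GaussianHmmParams, values: np.ndarray,
                 offset: int = 0) -> StatePath:
    """Maximum a posteriori state path (Viterbi decoding)."""
    X, lengths = _stack(values)
    _, labels = params.to_hmmlearn().decode(X, lengths, algorithm="viterbi")
    return StatePath(labels=labels, offset=offset)


def posterior_probabilities(params: GaussianHmmParams,
                            values: np.ndarray) -> np.ndarray:
    """Per-frame posterior state probabilities (forward-backward)."""
    X, lengths = _stack(values)
    return params.to_hmmlearn().predict_proba(X, lengths)


def log_likelihood(params: GaussianHmmParams, values) -> float:
    """Marginal log-likelihood of the data under the fitted chain."""
    X, lengths = _stack(values)
    return float(params.to_hmmlearn().score(X, lengths))


def bic(params: GaussianHmmParams, values) -> float:
    """Bayesian information criterion of a fitted chain (diagnostic only).

    Used to sanity-check the fixed two-state assumption against
    alternatives; model selection over state numbers is deliberately not
    part of the pipeline.  Free parameters: K means, K SDs, K(K-1)
    transition terms, K-1 start terms.
    """
    X, _ = _stack(values)
    K = params.n_states
    k_free = 2 * K + K * (K - 1) + (K - 1)
    return float(-2.0 * log_likelihood(params, values)
                 + k_free * np.log(len(X)))


def transition_prob_to_rate(p: float, frame_interval: float) -> float:
    """Convert a per-frame transition probability to a rate, k = -ln(1-p)/dt.

    Dwell-based rate estimates are the primary route; this conversion is
    provided for reporting the HMM transition matrix on a rate scale.
    """
    if not 0 <= p < 1:
        raise ValueError("transition probability must be in [0, 1)")
    return -np.log1p(-p) / frame_interval


# ---------------------------------------------------------------------------
# Bleach / validity segmentation
# ---------------------------------------------------------------------------


def detect_valid_region(
    donor: np.ndarray,
    acceptor: np.ndarray,
    offset_D: float | None = None,
    offset_A: float | None = None,
    separation_factor: float = 4.0,
    low_fret_ceiling: float = 0.15,
    min_fret_drop: float = 0.15,
) -> tuple[int, int, list[str]]:
    """Locate the prefix of a trace where both fluorophores are active.

    Donor bleaching is found by fitting a two-level step model (two-state
    HMM) to the donor+acceptor-summed intensity: a trailing low-total
    segment whose level is separated from the high level by more than
    ``separation_factor`` pooled SDs marks the donor bleach.  Acceptor
    bleaching is flagged as a trailing low-FRET segment (proximity ratio
    below ``low_fret_ceiling``) preceded by distinctly higher FRET.  When
    the camera offsets are supplied they are subtracted before the
    proximity ratio is formed (so a bleached acceptor reads FRET ~ 0),
    and traces whose total signal never rises above the offset noise are
    reported empty.

    Returns (start, end, reason_codes) with a half-open frame range.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor traces differ in length")
    n = len(donor)
    total = donor + acceptor
    reasons: list[str] = []
    c_D = 0.0 if offset_D is None else offset_D
    c_A = 0.0 if offset_A is None else offset_A

    if offset_D is not None or offset_A is not None:
        if np.mean(total - c_D - c_A) < 4.0 * np.std(total):
            return 0, 0, ["dark"]

    end = n
    try:
        p_tot = fit_hmm(total, n_states=2, max_iter=50, tol=1e-3)
        sep = (p_tot.means[1] - p_tot.means[0]) / np.mean(p_tot.sds)
        if sep > separation_factor:
            path = viterbi_path(p_tot, total)
            last_state, last_start, _ = path.segments[-1]
            if last_state == 0 and last_start > 0:
                end = last_start
                reasons.append("donor_bleach")
    except ValueError:
        pass

    if end >= 20:  # enough frames to judge acceptor bleaching
        with np.errstate(divide="ignore", invalid="ignore"):
            fret = (acceptor[:end] - c_A) \
                / np.maximum(total[:end] - c_D - c_A, 1e-9)
        try:
            p_fret = fit_hmm(fret, n_states=2, max_iter=50, tol=1e-3)
            if (p_fret.means[0] < low_fret_ceiling
                    and p_fret.means[1] - p_fret.means[0] > min_fret_drop):
                path = viterbi_path(p_fret, fret)
                last_state, last_start, _ = path.segments[-1]
                if last_state == 0 and last_start > 0:
                    end = last_start
                    reasons.append("acceptor_bleach")
        except ValueError:
            pass

    if end == 0:
        reasons.append("dark")
    return 0, end, reasons
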