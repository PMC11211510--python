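"""Closed-form two-conformational-state kinetics and thermodynamics.

Protein–DNA complexes that interconvert between a partially bent (P) and a
fully bent (F) conformation obey a linear two-state scheme

    D + A  <=[k1]=[k~-1]=>  (DA)_P  <=[k2]=[k-2]=>  (DA)_F

in which only the P-state can dissociate.  This module collects the exact
algebra of that scheme: dwell-time/rate conversions, the bending equilibrium
constant K_{F/P}, apparent (composite) dissociation constants and off rates,
the double-exponential dissociation decay, and equilibrium binding occupancy
with exact ligand depletion.

All closed forms are unit-agnostic: any consistent time/concentration unit
pair may be used.  :class:`BindingKineticModel` stores the per-minute / nM
convention used at I/O boundaries and exposes per-second accessors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TwoStateBendingModel",
    "BindingKineticModel",
    "OccupancySolution",
    "mean_dwell_times",
    "equilibrium_constant_KFP",
    "apparent_kd",
    "apparent_koff",
    "decay_rates",
    "dissociation_curve",
    "binding_occupancy",
]


class InvalidModelError(ValueError):
    """Raised when kinetic model parameters violate their invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStateBendingModel:
    """Kinetic and photophysical description of the P <-> F bending process.

    Parameters
    ----------
    rate_bend : float
        Bending rate k_{P->F} in s^-1 (exit rate of the P-state).
    rate_unbend : float
        Unbending rate k_{F->P} in s^-1 (exit rate of the F-state).
    fret_mean_P, fret_mean_F : float
        State FRET efficiencies; states are labelled so that P is the
        low-FRET (partially bent) and F the high-FRET (fully bent) state.
    fret_sd_P, fret_sd_F : float
        Per-frame FRET standard deviations of the two states.
    pife_P, pife_F : float
        Donor quantum-yield enhancement factors q_D per state
        (dimensionless; 1 means no enhancement).
    """

    rate_bend: float
    rate_unbend: float
    fret_mean_P: float = 0.22
    fret_mean_F: float = 0.65
    fret_sd_P: float = 0.05
    fret_sd_F: float = 0.05
    pife_P: float = 1.0
    pife_F: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rate_bend > 0 and self.rate_unbend > 0):
            raise InvalidModelError("bending/unbending rates must be positive")
        if not (0.0 <= self.fret_mean_P < self.fret_mean_F <= 1.0):
            raise InvalidModelError(
                "state FRET means must satisfy 0 <= P < F <= 1 "
                f"(got P={self.fret_mean_P}, F={self.fret_mean_F})"
            )
        if self.fret_sd_P <= 0 or self.fret_sd_F <= 0:
            raise InvalidModelError("state FRET SDs must be positive")

    @property
    def mean_dwell_P(self) -> float:
        """Mean P-state dwell time <T_P> = 1/k_{P->F} in seconds."""
        return 1.0 / self.rate_bend

    @property
    def mean_dwell_F(self) -> float:
        """Mean F-state dwell time <T_F> = 1/k_{F->P} in seconds."""
        return 1.0 / self.rate_unbend

    @property
    def K_FP(self) -> float:
        """Bending equilibrium constant K_{F/P} = k_{P->F}/k_{F->P}."""
        return self.rate_bend / self.rate_unbend

    @property
    def stationary_fraction_F(self) -> float:
        """Equilibrium occupancy of the F-state, K/(1+K)."""
        k = self.K_FP
        return k / (1.0 + k)

    def to_json(self) -> str:
        doc = {"units": {"rate_bend": "1/s", "rate_unbend": "1/s",
                         "fret": "efficiency", "pife": "fold"},
               "params": asdict(self)}
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TwoStateBendingModel":
        doc = json.loads(text)
        return cls(**doc["params"])


@dataclass(frozen=True)
class BindingKineticModel:
    """Two-conformational-state binding scheme D + A <-> (DA)_P <-> (DA)_F.

    Rates are stored in the per-minute / nM convention used for ensemble
    titration and stopped-flow experiments.

    Parameters
    ----------
    k_on : float
        Association rate constant k1, nM^-1 min^-1.
    pure_koff : float
        Pure dissociation rate of the P-state, k~_-1, min^-1.
    k2, k_m2 : float
        Bending (P->F) and unbending (F->P) rates of the bound complex,
        min^-1.
    """

    k_on: float
    pure_koff: float
    k2: float
    k_m2: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.pure_koff, self.k2, self.k_m2) <= 0:
            # k2 = k_m2 = 0 (single-state limit) is allowed as a pair
            if not (self.k2 == 0.0 and self.k_m2 == 0.0
                    and self.k_on > 0 and self.pure_koff > 0):
                raise InvalidModelError("all binding rates must be positive "
                                        "(k2 = k_m2 = 0 allowed jointly)")

    @property
    def pure_Kd(self) -> float:
        """Pure dissociation constant K~_d = k~_-1/k1 of the P-state, nM."""
        return self.pure_koff / self.k_on

    @property
    def K2(self) -> float:
        """Conformational equilibrium constant K2 = k2/k_-2 (== K_{F/P})."""
        if self.k2 == 0.0 and self.k_m2 == 0.0:
            return 0.0
        return self.k2 / self.k_m2

    @property
    def apparent_Kd(self) -> float:
        """Composite dissociation constant K_d = K~_d/(1 + K2), nM."""
        return apparent_kd(self.pure_Kd, self.K2)

    @property
    def apparent_koff(self) -> float:
        """Rapid-equilibrium apparent off rate k~_-1/(1 + K2), min^-1."""
        return apparent_koff(self.pure_koff, self.K2)

    @property
    def rates_per_second(self) -> tuple[float, float, float]:
        """(pure_koff, k2, k_m2) converted to s^-1."""
        return self.pure_koff / 60.0, self.k2 / 60.0, self.k_m2 / 60.0

    def to_json(self) -> str:
        doc = {"units": {"k_on": "1/(nM*min)", "pure_koff": "1/min",
                         "k2": "1/min", "k_m2": "1/min"},
               "params": asdict(self)}
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BindingKineticModel":
        doc = json.loads(text)
        return cls(**doc["params"])


@dataclass(frozen=True)
class OccupancySolution:
    """Equilibrium concentrations for the two-state binding scheme (nM)."""

    free_dna: float
    free_protein: float
    complex_P: float
    complex_F: float
    p_bound: float

    @property
    def complex_total(self) -> float:
        return self.complex_P + self.complex_F


# ---------------------------------------------------------------------------
# Dwell/rate conversions and apparent constants
# ---------------------------------------------------------------------------


def mean_dwell_times(model: TwoStateBendingModel) -> tuple[float, float]:
    """Mean state dwell times (<T_P>, <T_F>) in seconds.

    The exit of each state is a single Poisson process, so the mean dwell
    time is the reciprocal exit rate.
    """
    return model.mean_dwell_P, model.mean_dwell_F


def equilibrium_constant_KFP(T_P: float, T_F: float) -> float:
    """Bending equilibrium constant from mean dwell times, K = <T_F>/<T_P>."""
    if T_P <= 0 or T_F <= 0:
        raise ValueError("dwell times must be positive")
    return T_F / T_P


def apparent_kd(pure_Kd: float, K2: float) -> float:
    """Composite (apparent) dissociation constant K~_d / (1 + K2).

    Because only the P-state dissociates, the bound population is enriched
    by the F-state reservoir and the observed affinity tightens by the
    factor 1/(1 + K2).
    """
    if pure_Kd <= 0 or K2 < 0:
        raise ValueError("pure_Kd must be > 0 and K2 >= 0")
    return pure_Kd / (1.0 + K2)


def apparent_koff(pure_koff: float, K2: float) -> float:
    """Apparent off rate k~_-1/(1 + K2).

    Valid in the rapid-equilibrium limit k2 + k_-2 >> k~_-1, where the
    P/F split equilibrates between dissociation events and the complex
    dissociates only from the P-state fraction 1/(1 + K2).  For the exact
    slow decay rate use :func:`decay_rates`.
    """
    if pure_koff <= 0 or K2 < 0:
        raise ValueError("pure_koff must be > 0 and K2 >= 0")
    return pure_koff / (1.0 + K2)


# ---------------------------------------------------------------------------
# Dissociation decay
# ---------------------------------------------------------------------------


def decay_rates(pure_koff: float, k2: float, k_m2: float) -> tuple[float, float]:
    """Exact double-exponential decay rates (r_plus, r_minus).

    These are the eigenvalue magnitudes of the dissociation rate matrix

        d/dt [N_P, N_F] = [[-(k~ + k2), k_m2], [k2, -k_m2]] [N_P, N_F]

    computed from the quadratic formula

        r_pm = (s +- sqrt(s^2 - 4 k~ k_m2)) / 2,   s = k~ + k2 + k_m2

    rather than a general eigensolver, for exact reproducibility.  Vieta:
    r_plus * r_minus = k~ * k_m2 and r_plus + r_minus = s.
    """
    if pure_koff <= 0 or k2 < 0 or k_m2 <= 0:
        raise ValueError("rates must be positive (k2 >= 0)")
    s = pure_koff + k2 + k_m2
    disc = s * s - 4.0 * pure_koff * k_m2
    root = math.sqrt(max(disc, 0.0))
    r_plus = 0.5 * (s + root)
    # the subtractive root cancels catastrophically when r_plus >> r_minus;
    # the Vieta product r_plus * r_minus = k~ * k_m2 is exact and stable
    r_minus = pure_koff * k_m2 / r_plus
    return r_plus, r_minus


def dissociation_curve(
    N_P0: float,
    N_F0: float,
    model: BindingKineticModel,
    times: np.ndarray,
    per_minute: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form populations (N_P(t), N_F(t)) after a dissociation trap.

    Rebinding is blocked (excess unlabeled competitor), so the complex
    decays through the P-state only.  The solution is the eigen-expansion
    of the 2x2 rate matrix; both populations are sums of exp(-r_plus t)
    and exp(-r_minus t).

    Parameters
    ----------
    times : array
        Ascending time grid, minutes if ``per_minute`` (the model's native
        convention), otherwise seconds.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid is empty")
    if N_P0 < 0 or N_F0 < 0:
        raise ValueError("initial populations must be non-negative")
    if per_minute:
        kt, k2, km2 = model.pure_koff, model.k2, model.k_m2
    else:
        kt, k2, km2 = model.rates_per_second

    if k2 == 0.0 and km2 == 0.0:
        # single-state limit: pure exponential from P, frozen F
        return N_P0 * np.exp(-kt * times), np.full_like(times, N_F0)

    r_plus, r_minus = decay_rates(kt, k2, km2)
    if (r_plus - r_minus) < 1e-12 * r_plus:
        # degenerate eigenvalues: fall back to the matrix exponential
        from scipy.linalg import expm

        M = np.array([[-(kt + k2), km2], [k2, -km2]])
        out = np.array([expm(M * t) @ [N_P0, N_F0] for t in times])
        return out[:, 0], out[:, 1]

    # eigenvector of eigenvalue -r: (km2, kt + k2 - r) up to scale
    v_p = np.array([km2, kt + k2 - r_plus])
    v_m = np.array([km2, kt + k2 - r_minus])
    V = np.column_stack([v_p, v_m])
    c = np.linalg.solve(V, np.array([N_P0, N_F0]))
    e_p = np.exp(-r_plus * times)
    e_m = np.exp(-r_minus * times)
    N_P = c[0] * v_p[0] * e_p + c[1] * v_m[0] * e_m
    N_F = c[0] * v_p[1] * e_p + c[1] * v_m[1] * e_m
    return N_P, N_F


# ---------------------------------------------------------------------------
# Equilibrium occupancy
# ---------------------------------------------------------------------------


def binding_occupancy(
    D0: float, A0: float, pure_Kd: float, K2: float = 0.0
) -> OccupancySolution:
    """Exact equilibrium occupancy with ligand depletion.

    Solves the mass-conservation system for total DNA ``D0`` and total
    protein ``A0`` (both nM) with the composite dissociation constant
    K_d = pure_Kd/(1 + K2); no weak-depletion approximation is made.  The
    bound complex is split between the P- and F-states in the ratio 1:K2.
    """
    if D0 < 0 or A0 < 0:
        raise ValueError("total concentrations must be non-negative")
    Kd = apparent_kd(pure_Kd, K2)

    # [DA] solves [DA]^2 - (D0 + A0 + Kd) [DA] + D0 A0 = 0 (smaller root).
    b = D0 + A0 + Kd
    disc = b * b - 4.0 * D0 * A0
    DA = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    DA = min(DA, D0, A0)  # numerical safety at extreme depletion
    free_D = D0 - DA
    free_A = A0 - DA
    frac_F = K2 / (1.0 + K2)
    p_bound = free_A / (Kd + free_A) if (Kd + free_A) > 0 else 0.0
    return OccupancySolution(
        free_dna=free_D,
        free_protein=free_A,
        complex_P=DA * (1.0 - frac_F),
        complex_F=DA * frac_F,
        p_bound=p_bound,
    )
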