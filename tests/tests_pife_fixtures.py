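"""Shared synthetic calibration fixtures for the PIFE decoupling chain.

A ground-truth channel calibration plus the two calibration constructs'
event-cluster geometry (mid-labelled donor = high-FRET reference at unit
excitation, end-labelled donor = low-FRET reference at power u_L).
"""

import numpy as np

from tfambend.pife_fret import (
    CalibrationClusters,
    ChannelCalibration,
    PhotophysicsFrame,
    forward_model,
)

TRUE_CALIB = ChannelCalibration(dbar_DD=1600.0, abar_DD=140.0,
                                abar_AD=1750.0, abar_AA=120.0,
                                c_D=400.0, c_A=400.0)
F_H, F_L, U_L = 0.70, 0.25, 0.92


def exact_clusters(construct: str) -> CalibrationClusters:
    """Noiseless cluster means straight from the forward model."""
    u = 1.0 if construct == "mid" else U_L
    f = F_H if construct == "mid" else F_L
    cc = CalibrationClusters(construct=construct)
    cc.means = {
        "both_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=0, q_A=0, f=0), TRUE_CALIB),
        "donor_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=0, q_A=1, f=0), TRUE_CALIB),
        "acceptor_bleached": forward_model(
            PhotophysicsFrame(u=u, q_D=1, q_A=0, f=0), TRUE_CALIB),
        cc.live_label: forward_model(
            PhotophysicsFrame(u=u, q_D=1, q_A=1, f=f), TRUE_CALIB),
    }
    return cc


def noisy_cluster_points(construct: str, rng: np.random.Generator,
                         n_per: int = 200, sd: float = 25.0) -> np.ndarray:
    """Scattered (donor, acceptor) points around each event cluster."""
    cc = exact_clusters(construct)
    return np.vstack([
        np.column_stack([rng.normal(d, sd, n_per), rng.normal(a, sd, n_per)])
        for d, a in cc.means.values()
    ])
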