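"""Evaluation metrics: correlation, relative error, activation maps,
pacing-site localization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantom import HeartMesh, TMPSequence

__all__ = [
    "MetricsReport",
    "correlation_coefficient",
    "relative_error",
    "per_frame_metrics",
    "evaluate",
    "activation_time_map",
    "localization_error",
]

#: minimum peak-to-peak excursion (mV) for a node to count as activated
ACTIVATION_PTP_MV = 10.0


@dataclass
class MetricsReport:
    """Summary of reconstruction quality for one case."""

    cc: float
    re: float
    scope: str = "sequence"  # "sequence" (flattened) or "per-frame" (mean)
    cc_per_frame: Optional[np.ndarray] = None
    re_per_frame: Optional[np.ndarray] = None
    activation_times: Optional[np.ndarray] = None
    localization_error_mm: Optional[float] = None


def correlation_coefficient(x_r: np.ndarray, x_t: np.ndarray) -> float:
    """Pearson correlation Cov(x_r, x_t) / (std(x_r) std(x_t)), on the
    flattened arrays."""
    x_r = np.asarray(x_r, dtype=float).ravel()
    x_t = np.asarray(x_t, dtype=float).ravel()
    if x_r.shape != x_t.shape:
        raise ValueError("inputs must have the same length")
    if np.std(x_r) == 0 or np.std(x_t) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(x_r, x_t)[0, 1])


def relative_error(x_r: np.ndarray, x_t: np.ndarray) -> float:
    """Relative L2 error  ||x_r - x_t|| / ||x_t||  on the flattened arrays."""
    x_r = np.asarray(x_r, dtype=float).ravel()
    x_t = np.asarray(x_t, dtype=float).ravel()
    if x_r.shape != x_t.shape:
        raise ValueError("inputs must have the same length")
    denom = np.linalg.norm(x_t)
    if denom == 0:
        raise ValueError("relative error undefined for a zero ground truth")
    return float(np.linalg.norm(x_r - x_t) / denom)


def per_frame_metrics(U_r: np.ndarray, U_t: np.ndarray):
    """CC and RE computed independently for each frame (column)."""
    U_r, U_t = np.atleast_2d(U_r), np.atleast_2d(U_t)
    cc = np.array(
        [correlation_coefficient(U_r[:, s], U_t[:, s]) for s in range(U_t.shape[1])]
    )
    re = np.array(
        [relative_error(U_r[:, s], U_t[:, s]) for s in range(U_t.shape[1])]
    )
    return cc, re


def evaluate(U_r: np.ndarray, U_t: np.ndarray, scope: str = "sequence") -> MetricsReport:
    """Whole-sequence (flattened; the default) or per-frame-averaged CC/RE."""
    if scope == "sequence":
        return MetricsReport(
            cc=correlation_coefficient(U_r, U_t),
            re=relative_error(U_r, U_t),
            scope=scope,
        )
    if scope == "per-frame":
        cc, re = per_frame_metrics(U_r, U_t)
        return MetricsReport(
            cc=float(cc.mean()),
            re=float(re.mean()),
            scope=scope,
            cc_per_frame=cc,
            re_per_frame=re,
        )
    raise ValueError(f"unknown scope {scope!r}")


def activation_time_map(
    tmp: TMPSequence, ptp_threshold: float = ACTIVATION_PTP_MV
) -> np.ndarray:
    """Per-node activation time (ms): the frame of maximum forward
    difference dU/dt, i.e. the steepest point of the depolarisation
    upstroke.  Nodes whose trace stays flat (peak-to-peak below
    ``ptp_threshold`` mV) never activate and are flagged NaN.
    """
    U = np.atleast_2d(tmp.U)
    if U.shape[1] < 3:
        raise ValueError("activation mapping needs at least 3 frames")
    diffs = np.diff(U, axis=1)
    at = np.argmax(diffs, axis=1).astype(float) * tmp.dt
    flat = np.ptp(U, axis=1) < ptp_threshold
    at[flat] = np.nan
    return at


def _earliest_point(at: np.ndarray, mesh: HeartMesh) -> np.ndarray:
    """Coordinates of the earliest-activated node; ties -> centroid of the
    tied nodes."""
    if np.all(np.isnan(at)):
        raise ValueError("no activated nodes in the activation map")
    t_min = np.nanmin(at)
    tied = np.flatnonzero(at == t_min)
    return mesh.node_coords[tied].mean(axis=0)


def localization_error(
    at_recon: np.ndarray, at_true: np.ndarray, mesh: HeartMesh
) -> float:
    """Distance (mm) between the earliest points of the reconstructed and
    true activation maps — the pacing-origin localization error."""
    p_r = _earliest_point(np.asarray(at_recon, float), mesh)
    p_t = _earliest_point(np.asarray(at_true, float), mesh)
    return float(np.linalg.norm(p_r - p_t))
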