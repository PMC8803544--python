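"""Framewise displacement, DVARS and grayplot-style QC summaries.

FD is the scalar head-motion index used for frame censoring: the sum of
absolute frame-to-frame changes of the six rigid-body parameters, with
rotations converted to arc length at a configurable head radius.  The
default radius of 35 mm is appropriate for infant/toddler head sizes;
50 mm is the usual adult convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import FDTrace, MotionTrace, ParcelTimeseries

#: default rotation-to-arc-length radius for an infant/toddler head, mm
DEFAULT_RADIUS_MM = 35.0
#: adult-convention radius, mm
ADULT_RADIUS_MM = 50.0


def compute_fd(trace: MotionTrace, radius_mm: float = DEFAULT_RADIUS_MM) -> FDTrace:
    """Framewise displacement of a motion trace.

    ``fd[t] = sum_i |trans_i[t] - trans_i[t-1]|
              + radius_mm * sum_j |rot_j[t] - rot_j[t-1]|`` for t >= 1,
    with ``fd[0] = 0`` by convention.

    Parameters
    ----------
    trace
        Rigid-body parameters (mm / radians).
    radius_mm
        Head radius converting rotation angles to displacement arc length.
    """
    if not (radius_mm > 0):
        raise ValueError("radius_mm must be positive")
    d = np.abs(np.diff(trace.params, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return FDTrace(
        fd_mm=fd,
        tr_s=trace.tr_s,
        filtered=trace.filtered,
        radius_mm=radius_mm,
        subject_id=trace.subject_id,
        run_id=trace.run_id,
    )


def compute_dvars(ts: ParcelTimeseries) -> np.ndarray:
    """DVARS: spatial root-mean-square of the temporal derivative.

    ``dvars[t] = sqrt(mean_p (x[t, p] - x[t-1, p])^2)``, ``dvars[0] = 0``.
    Computed here on parcel timeseries in their native (unnormalized) units.
    """
    if ts.n_parcels == 0:
        raise ValueError("timeseries has no parcels")
    d = np.diff(ts.data, axis=0)
    dvars = np.sqrt(np.mean(d * d, axis=1))
    return np.concatenate([[0.0], dvars])


@dataclass
class QCPanel:
    """Arrays backing a grayplot-style QC figure for one run.

    ``gray_matrix`` holds per-parcel z-scored signals as a P x T image;
    real head motion shows up as a vertical stripe co-located with an FD
    spike and a DVARS excursion, whereas respiratory pseudo-motion raises
    FD without any corresponding signal disruption.
    """

    fd: FDTrace
    dvars: np.ndarray
    global_signal: np.ndarray
    gray_matrix: np.ndarray
    parcel_ids: list[str]

    def __post_init__(self) -> None:
        t = self.fd.n_frames
        if not (self.dvars.size == t == self.global_signal.size == self.gray_matrix.shape[1]):
            raise ValueError("QC panel arrays disagree on the number of frames")
        if self.gray_matrix.shape[0] != len(self.parcel_ids):
            raise ValueError("gray_matrix rows must match parcel_ids")


def build_qc_panel(
    ts: ParcelTimeseries,
    trace: MotionTrace,
    radius_mm: float = DEFAULT_RADIUS_MM,
) -> QCPanel:
    """Assemble FD, DVARS, global signal and a z-scored parcel image.

    Zero-variance parcels cannot be z-scored; their rows are set to zero
    and a warning is emitted.
    """
    if ts.n_frames != trace.n_frames:
        raise ValueError(
            f"timeseries has {ts.n_frames} frames but motion trace has {trace.n_frames}"
        )
    mu = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0)
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(ts.data).max(axis=0))
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance parcel(s); gray rows set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    z = (ts.data - mu) / safe_sd
    z[:, flat] = 0.0
    return QCPanel(
        fd=compute_fd(trace, radius_mm),
        dvars=compute_dvars(ts),
        global_signal=ts.data.mean(axis=1),
        gray_matrix=z.T,
        parcel_ids=list(ts.parcel_ids),
    )
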