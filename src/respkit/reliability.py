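"""Split-half reliability of connectivity across FD thresholds.

For each subject, the usable frames (FD at or below a threshold) across
all runs are split into a first and a second half of equal size, a
connectivity matrix is computed from each half, and the two matrices are
spatially correlated over their off-diagonal upper triangles.  Sweeping
the threshold for both the unfiltered and the notch-filtered FD trace
shows how much reliability is bought by retaining the respiratory
pseudo-motion frames that unfiltered censoring throws away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import DEFAULT_THRESHOLD_MM
from .connectivity import DEFAULT_MIN_FRAMES, ConnectivityMatrix, fc_matrix
from .io import FDTrace, ParcelTimeseries

#: default FD threshold grid for reliability sweeps, mm
DEFAULT_THRESHOLD_GRID_MM = np.round(np.arange(0.05, 0.5001, 0.05), 10)


class InsufficientUsableData(ValueError):
    """Raised when a subject lacks usable frames for two half-matrices."""


@dataclass
class SplitHalf:
    """Disjoint equal-sized halves of a subject's usable frames.

    Indices are global positions in the temporal concatenation of the
    subject's runs (acquisition order).  ``run_of_frame`` maps each global
    frame to its source-run index, so each half can be traced back to the
    runs it draws on.
    """

    idx_half1: np.ndarray
    idx_half2: np.ndarray
    run_of_frame: np.ndarray
    threshold_mm: float

    def __post_init__(self) -> None:
        if self.idx_half1.size != self.idx_half2.size:
            raise ValueError("halves must be equal-sized")
        if np.intersect1d(self.idx_half1, self.idx_half2).size:
            raise ValueError("halves must be disjoint")

    @property
    def frames_per_half(self) -> int:
        return self.idx_half1.size

    def runs_in_half(self, half: int) -> set[int]:
        idx = self.idx_half1 if half == 1 else self.idx_half2
        return set(self.run_of_frame[idx].tolist())


def concat_runs(
    runs: list[tuple[ParcelTimeseries, FDTrace]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, ParcelTimeseries]:
    """Concatenate runs in acquisition order.

    Returns (data, fd, run_of_frame, template_ts); the template carries
    parcel ids and network map for building half-matrices.
    """
    if not runs:
        raise ValueError("no runs supplied")
    ref = runs[0][0]
    datas, fds, run_ids = [], [], []
    for i, (ts, fd) in enumerate(runs):
        if ts.n_frames != fd.n_frames:
            raise ValueError(f"run {i}: timeseries and FD trace lengths differ")
        if list(ts.parcel_ids) != list(ref.parcel_ids):
            raise ValueError("runs must share the same parcels")
        datas.append(ts.data)
        fds.append(fd.fd_mm)
        run_ids.append(np.full(ts.n_frames, i))
    return (
        np.concatenate(datas, axis=0),
        np.concatenate(fds),
        np.concatenate(run_ids),
        ref,
    )


def split_half(
    runs: list[tuple[ParcelTimeseries, FDTrace]],
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    *,
    min_frames_per_half: int = DEFAULT_MIN_FRAMES,
    alternating: bool = False,
) -> SplitHalf:
    """Split a subject's usable frames into two equal, disjoint halves.

    Usable frames (FD <= threshold) are enumerated in temporal order
    across the concatenated runs; the first floor(U/2) form half 1 and the
    next floor(U/2) form half 2 (an odd last frame is dropped), so both
    half-matrices rest on identical amounts of data.  With two
    equal-length fully-usable runs this reduces to run 1 vs run 2.

    ``alternating=True`` instead assigns usable frames odd/even — a
    sensitivity variant that mixes runs within each half.
    """
    _, fd, run_of_frame, _ = concat_runs(runs)
    usable = np.flatnonzero(fd <= threshold_mm)
    if alternating:
        a, b = usable[0::2], usable[1::2]
        h = min(a.size, b.size)
        idx1, idx2 = a[:h], b[:h]
    else:
        h = usable.size // 2
        idx1, idx2 = usable[:h], usable[h : 2 * h]
    if idx1.size < min_frames_per_half:
        raise InsufficientUsableData(
            f"{usable.size} usable frames at {threshold_mm} mm; need at least "
            f"{2 * min_frames_per_half} for two half-matrices"
        )
    return SplitHalf(
        idx_half1=idx1, idx_half2=idx2, run_of_frame=run_of_frame, threshold_mm=threshold_mm
    )


def spatial_correlation(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    """Pearson correlation of two matrices' off-diagonal upper triangles."""
    va, vb = a.upper_triangle(), b.upper_triangle()
    if va.size != vb.size:
        raise ValueError("matrices have different sizes")
    if np.array_equal(va, vb):
        return 1.0  # identical halves correlate exactly, no float round-off
    return float(np.corrcoef(va, vb)[0, 1])


def split_half_reliability(
    runs: list[tuple[ParcelTimeseries, FDTrace]],
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    *,
    min_frames_per_half: int = DEFAULT_MIN_FRAMES,
    alternating: bool = False,
) -> float:
    """One subject's split-half spatial correlation at one threshold."""
    data, _, _, ref = concat_runs(runs)
    sh = split_half(
        runs,
        threshold_mm,
        min_frames_per_half=min_frames_per_half,
        alternating=alternating,
    )
    halves = []
    for idx in (sh.idx_half1, sh.idx_half2):
        ts = ParcelTimeseries(
            data=data[idx],
            parcel_ids=list(ref.parcel_ids),
            network_of=dict(ref.network_of),
            tr_s=ref.tr_s,
            subject_id=ref.subject_id,
        )
        halves.append(fc_matrix(ts, mask=None, min_frames=min_frames_per_half))
    return spatial_correlation(halves[0], halves[1])


@dataclass
class ReliabilityCurve:
    """Cohort mean split-half correlation per FD threshold for one arm.

    Thresholds with fewer than two surviving subjects are reported as NaN.
    Both SD and SE across subjects are emitted; plots conventionally shade
    about two of either around the mean.
    """

    thresholds_mm: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    se_r: np.ndarray
    n_subjects: np.ndarray
    arm: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds_mm) <= 0):
            raise ValueError("thresholds must be ascending")
        ok = np.isfinite(self.mean_r)
        if np.any(np.abs(self.mean_r[ok]) > 1 + 1e-9):
            raise ValueError("mean_r outside [-1, 1]")


def reliability_curve(
    subjects: list[list[tuple[ParcelTimeseries, FDTrace]]],
    thresholds_mm: np.ndarray | None = None,
    arm: str = "unfiltered",
    *,
    min_frames_per_half: int = DEFAULT_MIN_FRAMES,
    alternating: bool = False,
) -> ReliabilityCurve:
    """Sweep FD thresholds and average split-half reliability over a cohort.

    ``subjects`` is a list of per-subject run lists ``(timeseries, fd)``;
    the FD traces passed in define the arm (unfiltered or notch-filtered).
    A subject contributes at a threshold only when both halves meet the
    minimum-frames floor.
    """
    if thresholds_mm is None:
        thresholds_mm = DEFAULT_THRESHOLD_GRID_MM
    thresholds_mm = np.asarray(thresholds_mm, dtype=float)
    means, sds, ses, counts = [], [], [], []
    for thr in thresholds_mm:
        rs = []
        for runs in subjects:
            try:
                rs.append(
                    split_half_reliability(
                        runs,
                        thr,
                        min_frames_per_half=min_frames_per_half,
                        alternating=alternating,
                    )
                )
            except InsufficientUsableData:
                continue
        if len(rs) < 2:
            means.append(np.nan)
            sds.append(np.nan)
            ses.append(np.nan)
            counts.append(len(rs))
        else:
            arr = np.asarray(rs)
            means.append(arr.mean())
            sds.append(arr.std(ddof=1))
            ses.append(arr.std(ddof=1) / np.sqrt(arr.size))
            counts.append(arr.size)
    return ReliabilityCurve(
        thresholds_mm=thresholds_mm,
        mean_r=np.asarray(means),
        sd_r=np.asarray(sds),
        se_r=np.asarray(ses),
        n_subjects=np.asarray(counts),
        arm=arm,
    )
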