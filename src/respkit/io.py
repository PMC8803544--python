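"""Domain containers and plain-text I/O.

Everything downstream operates on four small containers: rigid-body
realignment parameters (:class:`MotionTrace`), per-frame framewise
displacement (:class:`FDTrace`), parcel-averaged BOLD signals
(:class:`ParcelTimeseries`) and frame retention masks (:class:`FrameMask`).

Canonical internal units are millimetres for translations, radians for
rotations and seconds for time; all unit conversion happens once, at ingest.
File formats are deliberately plain: whitespace-delimited numeric text for
motion parameters (compatible with common realignment outputs), TSV for
timeseries and network maps, newline-delimited 0/1 for masks and JSON for
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of rigid-body parameters
PARAM_NAMES = ("trans_x", "trans_y", "trans_z", "rot_pitch", "rot_yaw", "rot_roll")

#: translation column index for each phase-encode axis label
PHASE_AXIS_COLUMN = {"x": 0, "y": 1, "z": 2}


class MotionFileError(ValueError):
    """Raised when a realignment-parameter file cannot be parsed."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class MotionTrace:
    """T x 6 rigid-body realignment parameters for one BOLD run.

    Columns are fixed as ``(trans_x, trans_y, trans_z, rot_pitch, rot_yaw,
    rot_roll)`` with translations in mm and rotations in radians.  The
    phase-encode axis matters because respiration-induced B0 perturbations
    manifest as apparent translation along it (y for typical acquisitions).
    """

    params: np.ndarray
    tr_s: float
    phase_axis: str = "y"
    subject_id: str | None = None
    run_id: str | None = None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.params = _as_float_array(self.params, "params")
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"params must be a T x 6 array, got shape {self.params.shape}"
            )
        if self.params.shape[0] < 2:
            raise ValueError("a motion trace needs at least 2 frames")
        if not (self.tr_s > 0):
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.phase_axis not in PHASE_AXIS_COLUMN:
            raise ValueError(f"phase_axis must be one of x/y/z, got {self.phase_axis!r}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz (1/TR)."""
        return 1.0 / self.tr_s

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    @property
    def phase_column(self) -> int:
        """Index of the phase-encode translation column."""
        return PHASE_AXIS_COLUMN[self.phase_axis]

    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def replace_params(self, params: np.ndarray, *, filtered: bool | None = None) -> "MotionTrace":
        """New trace with identical metadata but different parameter values."""
        return MotionTrace(
            params=params,
            tr_s=self.tr_s,
            phase_axis=self.phase_axis,
            subject_id=self.subject_id,
            run_id=self.run_id,
            filtered=self.filtered if filtered is None else filtered,
        )


@dataclass
class FDTrace:
    """Per-frame framewise displacement in mm.

    ``fd_mm[0] == 0`` by convention: the first frame has no predecessor, so
    it is always eligible for retention on FD grounds alone.
    """

    fd_mm: np.ndarray
    tr_s: float
    filtered: bool = False
    radius_mm: float = 35.0
    subject_id: str | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        self.fd_mm = _as_float_array(self.fd_mm, "fd_mm")
        if self.fd_mm.ndim != 1:
            raise ValueError("fd_mm must be one-dimensional")
        if self.fd_mm.size and self.fd_mm[0] != 0.0:
            raise ValueError("fd_mm[0] must be 0 (no predecessor frame)")
        if np.any(self.fd_mm < 0):
            raise ValueError("fd_mm entries must be non-negative")
        if not (self.tr_s > 0):
            raise ValueError("tr_s must be positive")
        if not (self.radius_mm > 0):
            raise ValueError("radius_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.fd_mm.size

    def mean(self) -> float:
        return float(np.mean(self.fd_mm))


@dataclass
class ParcelTimeseries:
    """T x P parcel-averaged BOLD signals with a parcel-to-network map.

    Every parcel must carry a network assignment; an explicit label such as
    ``"Usp"`` (unspecified) is permitted and passed through.
    """

    data: np.ndarray
    parcel_ids: Sequence[str]
    network_of: Mapping[str, str]
    tr_s: float
    subject_id: str | None = None
    run_id: str | None = None

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data")
        if self.data.ndim != 2:
            raise ValueError("data must be a T x P array")
        self.parcel_ids = [str(p) for p in self.parcel_ids]
        if len(self.parcel_ids) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.parcel_ids)} parcel ids for {self.data.shape[1]} columns"
            )
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be unique")
        missing = [p for p in self.parcel_ids if p not in self.network_of]
        if missing:
            raise ValueError(
                "parcels missing from network map: " + ", ".join(missing)
            )
        if not (self.tr_s > 0):
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def networks(self) -> list[str]:
        """Network labels in order of first appearance over parcels."""
        seen: list[str] = []
        for p in self.parcel_ids:
            lab = self.network_of[p]
            if lab not in seen:
                seen.append(lab)
        return seen

    def network_labels(self) -> np.ndarray:
        """Length-P array of network labels aligned with columns."""
        return np.asarray([self.network_of[p] for p in self.parcel_ids])


@dataclass
class FrameMask:
    """Boolean retention mask aligned index-for-index with frames."""

    keep: np.ndarray
    threshold_mm: float
    source: str = "unfiltered"

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 1:
            raise ValueError("keep must be one-dimensional")
        if not (self.threshold_mm > 0):
            raise ValueError("threshold_mm must be positive")
        if self.source not in ("unfiltered", "filtered"):
            raise ValueError("source must be 'unfiltered' or 'filtered'")

    @property
    def n_frames(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))

    def minutes_kept(self, tr_s: float) -> float:
        return self.n_kept * tr_s / 60.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_motion(
    path,
    tr_s: float,
    *,
    dialect: str = "radians",
    rotation_columns: str = "last3",
    phase_axis: str = "y",
    subject_id: str | None = None,
    run_id: str | None = None,
) -> MotionTrace:
    """Read a realignment-parameter file into a :class:`MotionTrace`.

    Parameters
    ----------
    path
        Whitespace- or comma-delimited numeric text, one row per volume,
        at least 6 columns.  Extra columns are ignored with a warning.
    tr_s
        Sampling interval in seconds (not stored in the file format).
    dialect
        ``"radians"`` or ``"degrees"`` — unit of the rotation columns.
        Silent unit mis-parses corrupt FD by a factor of ~57, so the unit
        is never guessed.
    rotation_columns
        ``"last3"`` (translations first, the canonical order) or
        ``"first3"`` (rotation-first files are re-ordered at ingest).
    """
    if dialect not in ("radians", "degrees"):
        raise ValueError("dialect must be 'radians' or 'degrees'")
    if rotation_columns not in ("last3", "first3"):
        raise ValueError("rotation_columns must be 'last3' or 'first3'")

    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.replace(",", " ").split()
            try:
                values = [float(v) for v in fields]
            except ValueError as exc:
                raise MotionFileError(
                    f"{path}: malformed row at line {lineno}: {stripped!r}"
                ) from exc
            if ncols is None:
                ncols = len(values)
                if ncols < 6:
                    raise MotionFileError(
                        f"{path}: expected >= 6 columns, found {ncols}"
                    )
                if ncols > 6:
                    logger.warning(
                        "%s: %d columns found; ignoring the last %d",
                        path, ncols, ncols - 6,
                    )
            elif len(values) != ncols:
                raise MotionFileError(
                    f"{path}: line {lineno} has {len(values)} columns, expected {ncols}"
                )
            rows.append(values[:6])

    if len(rows) < 2:
        raise MotionFileError(f"{path}: need at least 2 data rows, found {len(rows)}")

    params = np.asarray(rows, dtype=float)
    if rotation_columns == "first3":
        params = params[:, [3, 4, 5, 0, 1, 2]]
    if dialect == "degrees":
        params[:, 3:] *= np.pi / 180.0
    return MotionTrace(
        params=params,
        tr_s=tr_s,
        phase_axis=phase_axis,
        subject_id=subject_id,
        run_id=run_id,
    )


def write_motion(trace: MotionTrace, path) -> None:
    """Write canonical 6-column whitespace text (mm / radians).

    Round-trips with :func:`read_motion` to full float precision.
    """
    np.savetxt(path, trace.params, fmt="%.17g")


def read_timeseries(
    path,
    network_map_path,
    tr_s: float,
    *,
    subject_id: str | None = None,
    run_id: str | None = None,
) -> ParcelTimeseries:
    """Read a parcel-timeseries TSV plus its parcel-to-network map.

    The timeseries file carries a header row of parcel ids; the map is a
    two-column TSV ``(parcel_id, network)``.  Parcels absent from the map
    raise a validation error listing the offending ids.
    """
    df = pd.read_csv(path, sep="\t")
    net = read_network_map(network_map_path)
    return ParcelTimeseries(
        data=df.to_numpy(dtype=float),
        parcel_ids=list(df.columns),
        network_of=net,
        tr_s=tr_s,
        subject_id=subject_id,
        run_id=run_id,
    )


def write_timeseries(ts: ParcelTimeseries, path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: network map needs 2 columns (parcel_id, network)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_network_map(network_of: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"parcel_id": list(network_of.keys()), "network": list(network_of.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_mask(path, threshold_mm: float, source: str = "unfiltered") -> FrameMask:
    keep = np.loadtxt(path, dtype=int)
    return FrameMask(keep=keep.astype(bool), threshold_mm=threshold_mm, source=source)


def write_mask(mask: FrameMask, path) -> None:
    np.savetxt(path, mask.keep.astype(int), fmt="%d")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_report(obj, path) -> None:
    """Serialize a report object (dataclass / dict / arrays) to JSON."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_ReportEncoder)
        fh.write("\n")


def read_report(path):
    with open(path) as fh:
        return json.load(fh)
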