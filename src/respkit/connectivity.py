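"""Censoring-aware parcel connectivity and network-block summaries.

Pearson correlations between parcel timeseries are computed over retained
frames only.  Parcel-pair matrices are reduced to network blocks (mean
correlation of all parcel pairs within or between resting-state
networks), and filtered-vs-unfiltered arms are compared with paired
t-tests on Fisher-z values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io import FrameMask, ParcelTimeseries

#: default infra-slow BOLD bandpass edges, Hz
DEFAULT_BANDPASS_HZ = (0.008, 0.09)

#: minimum retained frames for a correlation estimate
DEFAULT_MIN_FRAMES = 10

_Z_CLIP = 1.0 - 1e-12


@dataclass
class ConnectivityMatrix:
    """P x P Pearson correlation matrix over retained frames."""

    r: np.ndarray
    n_frames_used: int
    parcel_ids: list[str]
    network_of: dict[str, str]

    def __post_init__(self) -> None:
        p = len(self.parcel_ids)
        if self.r.shape != (p, p):
            raise ValueError("r must be P x P aligned with parcel_ids")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("r must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("diagonal must be exactly 1")

    def network_labels(self) -> np.ndarray:
        return np.asarray([self.network_of[p] for p in self.parcel_ids])

    def networks(self) -> list[str]:
        seen: list[str] = []
        for p in self.parcel_ids:
            lab = self.network_of[p]
            if lab not in seen:
                seen.append(lab)
        return seen

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        iu = np.triu_indices(len(self.parcel_ids), k=1)
        return self.r[iu]


@dataclass
class NetworkBlockMatrix:
    """K x K mean within/between-network correlations.

    Within-network cells average the off-diagonal parcel pairs inside the
    network (self-correlations excluded); a singleton network has no such
    pair and its within cell is NaN.
    """

    blocks: np.ndarray
    network_labels: list[str]

    def __post_init__(self) -> None:
        k = len(self.network_labels)
        if self.blocks.shape != (k, k):
            raise ValueError("blocks must be K x K aligned with network_labels")
        finite = np.isfinite(self.blocks)
        if not np.allclose(
            np.where(finite, self.blocks, 0.0),
            np.where(finite.T, self.blocks.T, 0.0),
        ):
            raise ValueError("blocks must be symmetric")


def bandpass_interp(
    ts: ParcelTimeseries,
    mask: FrameMask,
    lo_hz: float = DEFAULT_BANDPASS_HZ[0],
    hi_hz: float = DEFAULT_BANDPASS_HZ[1],
    order: int = 2,
) -> ParcelTimeseries:
    """Interpolate censored frames, then zero-phase Butterworth bandpass.

    Dropping frames before filtering would alias; instead censored frames
    are replaced by linear interpolation between the nearest retained
    neighbours (edge frames take the nearest retained value), the bandpass
    is applied to the gap-free series, and the censoring mask is
    re-imposed downstream by whatever consumes the result.
    """
    nyq = 0.5 / ts.tr_s
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"need 0 < lo < hi < Nyquist ({nyq:.3f} Hz), got ({lo_hz}, {hi_hz})"
        )
    if mask.n_frames != ts.n_frames:
        raise ValueError("mask length does not match timeseries")
    kept = np.flatnonzero(mask.keep)
    if kept.size < 2:
        raise ValueError("need at least 2 retained frames to interpolate")
    t_all = np.arange(ts.n_frames)
    data = np.empty_like(ts.data)
    for j in range(ts.n_parcels):
        data[:, j] = np.interp(t_all, kept, ts.data[kept, j])
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=1.0 / ts.tr_s, output="sos")
    filtered = sps.sosfiltfilt(sos, data, axis=0)
    return ParcelTimeseries(
        data=filtered,
        parcel_ids=list(ts.parcel_ids),
        network_of=dict(ts.network_of),
        tr_s=ts.tr_s,
        subject_id=ts.subject_id,
        run_id=ts.run_id,
    )


def fc_matrix(
    ts: ParcelTimeseries,
    mask: FrameMask | None = None,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> ConnectivityMatrix:
    """Pearson correlation across retained frames only.

    Zero-variance parcels (on the retained frames) cannot be correlated;
    their rows/columns are set to 0 with diagonal 1 and a warning.
    """
    if mask is None:
        data = ts.data
    else:
        if mask.n_frames != ts.n_frames:
            raise ValueError("mask length does not match timeseries")
        data = ts.data[mask.keep]
    n = data.shape[0]
    if n < min_frames:
        raise ValueError(
            f"only {n} retained frames; at least {min_frames} required for a "
            "correlation estimate"
        )
    sd = data.std(axis=0)
    # relative tolerance: a constant column's std is float noise, not 0
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=0))
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance parcel(s) on retained frames; "
            "rows/columns set to 0",
            stacklevel=2,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(data.T)
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    else:
        r = np.corrcoef(data.T)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(
        r=r,
        n_frames_used=n,
        parcel_ids=list(ts.parcel_ids),
        network_of=dict(ts.network_of),
    )


def _block_means(mat: np.ndarray, labels: np.ndarray, networks: list[str]) -> np.ndarray:
    """K x K pairwise block means of a symmetric parcel matrix.

    Within-network cells average off-diagonal pairs only; NaN when the
    network is a singleton.
    """
    k = len(networks)
    out = np.full((k, k), np.nan)
    idx = {n: np.flatnonzero(labels == n) for n in networks}
    for a in range(k):
        ia = idx[networks[a]]
        for b in range(a, k):
            ib = idx[networks[b]]
            if a == b:
                if ia.size < 2:
                    continue  # singleton: within-cell undefined
                sub = mat[np.ix_(ia, ia)]
                iu = np.triu_indices(ia.size, k=1)
                out[a, a] = sub[iu].mean()
            else:
                out[a, b] = out[b, a] = mat[np.ix_(ia, ib)].mean()
    return out


def network_blocks(cm: ConnectivityMatrix) -> NetworkBlockMatrix:
    """Reduce a parcel matrix to mean within/between-network blocks."""
    networks = cm.networks()
    blocks = _block_means(cm.r, cm.network_labels(), networks)
    for i, n in enumerate(networks):
        if np.isnan(blocks[i, i]):
            warnings.warn(
                f"network {n!r} is a singleton; within-network cell undefined",
                stacklevel=2,
            )
    return NetworkBlockMatrix(blocks=blocks, network_labels=networks)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform with clipping to keep |r| < 1 finite."""
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


@dataclass
class PairedTTestResult:
    """Per-edge (or per-block) paired t-statistics across subjects."""

    t: np.ndarray
    p: np.ndarray
    df: int
    level: str
    labels: list[str]
    p_fdr: np.ndarray | None = None


def paired_ttest(
    mats_a: list[ConnectivityMatrix],
    mats_b: list[ConnectivityMatrix],
    level: str = "parcel_pair",
    fdr: bool = False,
) -> PairedTTestResult:
    """Paired t-test of condition A vs B connectivity across subjects.

    Correlations are Fisher-z transformed per subject before differencing
    (standard for inference on correlations).  ``level="parcel_pair"``
    tests every edge of the P x P matrix (diagonal left NaN);
    ``level="network_block"`` first reduces each subject's z-matrix to
    network blocks and tests each block cell.  Positive t means A > B.
    Raw p-values are reported by default; ``fdr=True`` additionally
    emits Benjamini-Hochberg adjusted values over the unique cells.
    """
    if len(mats_a) != len(mats_b):
        raise ValueError("paired lists must have equal length")
    n = len(mats_a)
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    if level not in ("parcel_pair", "network_block"):
        raise ValueError("level must be 'parcel_pair' or 'network_block'")

    ref = mats_a[0]
    for m in (*mats_a, *mats_b):
        if m.parcel_ids != ref.parcel_ids:
            raise ValueError("all matrices must share the same parcel ids")

    if level == "parcel_pair":
        za = np.stack([fisher_z(m.r) for m in mats_a])
        zb = np.stack([fisher_z(m.r) for m in mats_b])
        labels = list(ref.parcel_ids)
    else:
        networks = ref.networks()
        lab_arr = ref.network_labels()
        za = np.stack([_block_means(fisher_z(m.r), lab_arr, networks) for m in mats_a])
        zb = np.stack([_block_means(fisher_z(m.r), lab_arr, networks) for m in mats_b])
        labels = networks

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(za, zb, axis=0)
    if level == "parcel_pair":
        np.fill_diagonal(t, np.nan)
        np.fill_diagonal(p, np.nan)
    p_fdr = None
    if fdr:
        iu = np.triu_indices(p.shape[0], k=1 if level == "parcel_pair" else 0)
        flat = p[iu]
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
        p_fdr = np.full_like(p, np.nan)
        p_fdr[iu] = adj
        p_fdr.T[iu] = adj
    return PairedTTestResult(t=t, p=p, df=n - 1, level=level, labels=labels, p_fdr=p_fdr)
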