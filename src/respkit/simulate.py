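"""Synthetic motion traces and parcel BOLD with known ground truth.

The generator encodes the identifiability premise that makes respiratory
notch filtering sensible in the first place: breathing perturbs the
*motion estimates* (a narrow-band oscillation concentrated on the
phase-encode translation, leaking into the other axes and rotations)
without disrupting the BOLD signal, whereas spontaneous movements
(sparse, large displacement steps) corrupt both.  Every pipeline stage
can therefore be validated against recorded ground truth — the
instantaneous respiratory frequency, the spike frames and their
amplitudes, and the target network covariance — with no scan data.

Defaults emulate a multiband infant/toddler acquisition: 420 frames at
TR 0.8 s per run, respiratory rates of 0.40 +/- 0.05 Hz between subjects
(24 +/- 3 breaths/min, sleeping-toddler range) with slow within-run
wander, ~0.15 mm apparent respiratory displacement on the phase axis and
roughly two spontaneous movements per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import (
    MotionTrace,
    ParcelTimeseries,
    write_motion,
    write_network_map,
    write_report,
    write_timeseries,
)

#: an assumed infant head radius used to express rotational components, mm
_ROT_RADIUS_MM = 35.0


@dataclass
class MotionSimParams:
    """Parameters of the rigid-body motion simulator (units in names).

    ``resp_amp_mm`` is the peak apparent displacement of the respiratory
    oscillation on the phase-encode axis; ``leak_frac`` scales its leak
    into the two other translations and ``rot_leak_frac`` the (arc-length
    equivalent at 35 mm) leak into the three rotations.  Spikes model
    gross spontaneous movements as instantaneous repositioning steps
    whose total FD contribution is drawn from a floored log-normal.  The
    1 mm floor makes every spike unambiguously censorable even after
    band-stop filtering: the widest plausible stopband retains only
    ~50% of a step's at-frame FD, and respiration surviving at a band
    edge can cancel up to ~0.25 mm more, so the floor must exceed
    (0.2 + 0.25) / 0.5 = 0.9 mm for the identifiability premise (spikes
    are the frames censoring must remove) to hold by construction.
    """

    t_frames: int = 420
    tr_s: float = 0.8
    resp_hz_mean: float = 0.40
    resp_hz_sd: float = 0.05  # between-subject
    resp_hz_jitter: float = 0.01  # within-run slow wander SD
    resp_amp_mm: float = 0.15
    leak_frac: float = 0.3
    rot_leak_frac: float = 0.1
    spike_rate_per_min: float = 2.0
    spike_amp_mm_median: float = 1.2
    spike_amp_mm_sigma: float = 0.3
    spike_amp_mm_min: float = 1.0
    drift_mm_per_min: float = 0.02
    noise_sd_mm: float = 0.005
    phase_axis: str = "y"

    def __post_init__(self) -> None:
        nyq = 0.5 / self.tr_s
        lo = self.resp_hz_mean - 3 * self.resp_hz_sd
        hi = self.resp_hz_mean + 3 * self.resp_hz_sd
        if not (0 < lo and hi < nyq):
            raise ValueError(
                f"respiratory band {lo:.3f}-{hi:.3f} Hz must lie within "
                f"(0, Nyquist={nyq:.3f}); at this TR the oscillation would be "
                "aliased — model that explicitly with spectral.alias_frequency()"
            )
        for name in ("resp_amp_mm", "leak_frac", "rot_leak_frac", "noise_sd_mm",
                     "spike_rate_per_min", "drift_mm_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.t_frames < 2:
            raise ValueError("t_frames must be >= 2")


@dataclass
class GroundTruth:
    """What the generator actually injected into one run."""

    resp_hz: float  # subject's mean respiratory frequency
    resp_hz_series: np.ndarray  # instantaneous frequency per frame
    spike_frames: np.ndarray
    spike_amps_mm: np.ndarray
    tr_s: float
    t_frames: int


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_motion(
    params: MotionSimParams,
    seed=None,
    *,
    resp_hz: float | None = None,
    subject_id: str | None = None,
    run_id: str | None = None,
) -> tuple[MotionTrace, GroundTruth]:
    """Simulate one run of 6-DOF realignment parameters.

    The trace is the sum of slow drift, a frequency-wandering respiratory
    sinusoid (phase axis, with partially incoherent leak into the other
    translations and rotations), sparse displacement-step spikes and
    white noise.  ``resp_hz`` fixes the subject's mean breathing rate
    (used by the cohort generator so runs of one subject share it);
    otherwise it is drawn from the between-subject distribution.
    """
    rng = _rng(seed)
    t, tr = params.t_frames, params.tr_s
    time_min = np.arange(t) * tr / 60.0

    if resp_hz is None:
        resp_hz = float(
            np.clip(
                rng.normal(params.resp_hz_mean, params.resp_hz_sd),
                params.resp_hz_mean - 3 * params.resp_hz_sd,
                params.resp_hz_mean + 3 * params.resp_hz_sd,
            )
        )

    # instantaneous frequency: slow wander around the subject mean
    wander = gaussian_filter1d(rng.standard_normal(t), sigma=12.5, mode="nearest")
    sd = wander.std()
    if sd > 0 and params.resp_hz_jitter > 0:
        wander *= params.resp_hz_jitter / sd
    else:
        wander[:] = 0.0
    f_inst = resp_hz + wander
    phase = 2 * np.pi * np.cumsum(f_inst) * tr + rng.uniform(0, 2 * np.pi)

    pcol = {"x": 0, "y": 1, "z": 2}[params.phase_axis]
    p = np.zeros((t, 6))

    # respiration: phase axis at full amplitude, leak elsewhere
    amp = params.resp_amp_mm
    p[:, pcol] += amp * np.sin(phase)
    for c in range(3):
        if c != pcol:
            p[:, c] += params.leak_frac * amp * np.sin(phase + rng.uniform(0, 2 * np.pi))
    rot_amp_rad = params.rot_leak_frac * amp / _ROT_RADIUS_MM
    for c in range(3, 6):
        p[:, c] += rot_amp_rad * np.sin(phase + rng.uniform(0, 2 * np.pi))

    # slow drift: random linear slope per parameter
    slopes = rng.normal(0.0, params.drift_mm_per_min, size=6)
    slopes[3:] /= _ROT_RADIUS_MM
    p += np.outer(time_min, slopes)

    # spikes: instantaneous repositioning steps with total FD == amplitude;
    # distinct movement events are kept >= 5 frames apart
    n_spikes = rng.poisson(params.spike_rate_per_min * t * tr / 60.0)
    if n_spikes > 0:
        candidates = rng.permutation(np.arange(2, t))
        frames_list: list[int] = []
        for c in candidates:
            if len(frames_list) >= n_spikes:
                break
            if all(abs(c - f) >= 5 for f in frames_list):
                frames_list.append(int(c))
        frames = np.sort(np.asarray(frames_list, dtype=int))
        amps = np.exp(rng.normal(np.log(params.spike_amp_mm_median),
                                 params.spike_amp_mm_sigma, size=frames.size))
        amps = np.maximum(amps, params.spike_amp_mm_min)
        for k, a in zip(frames, amps):
            w = rng.dirichlet(np.ones(6))
            s = rng.choice([-1.0, 1.0], size=6)
            delta = s * w * a
            delta[3:] /= _ROT_RADIUS_MM
            p[k:] += delta  # head stays in the new position
    else:
        frames = np.empty(0, dtype=int)
        amps = np.empty(0)

    # white measurement noise on the parameter estimates
    if params.noise_sd_mm > 0:
        noise = rng.normal(0.0, params.noise_sd_mm, size=(t, 6))
        noise[:, 3:] /= _ROT_RADIUS_MM
        p += noise

    trace = MotionTrace(
        params=p,
        tr_s=tr,
        phase_axis=params.phase_axis,
        subject_id=subject_id,
        run_id=run_id,
    )
    truth = GroundTruth(
        resp_hz=resp_hz,
        resp_hz_series=f_inst,
        spike_frames=frames,
        spike_amps_mm=amps,
        tr_s=tr,
        t_frames=t,
    )
    return trace, truth


@dataclass
class BoldSimParams:
    """Parameters of the parcel-BOLD simulator.

    Signals are network-structured Gaussian draws (target correlation
    ``within_r`` inside a network, ``between_r`` across networks),
    temporally smoothed with a Gaussian kernel of FWHM
    ``hemo_fwhm_s`` seconds to mimic hemodynamic autocorrelation.
    Spike frames inject a global artifact: the spike indicator convolved
    with a short decaying kernel, multiplied by zero-mean random parcel
    weights and ``corruption_gain``.  Respiration does **not** enter the
    BOLD signal — respiratory head-motion estimates are factitious, which
    is exactly why those frames are worth rescuing.
    ``resp_coupling_gain`` (default 0) can inject a respiration-locked
    BOLD component for sensitivity experiments.
    """

    p_parcels: int = 50
    networks: dict[str, int] | None = None
    within_r: float = 0.35
    between_r: float = 0.05
    corruption_gain: float = 1.5
    corruption_kernel: tuple[float, ...] = (1.0, 0.6, 0.3)
    corruption_amp_ref_mm: float = 1.2  # spike amplitude mapping to unit artifact
    hemo_fwhm_s: float = 4.0
    resp_coupling_gain: float = 0.0

    def resolve_networks(self) -> dict[str, int]:
        if self.networks is not None:
            if sum(self.networks.values()) != self.p_parcels:
                raise ValueError("network sizes must sum to p_parcels")
            return dict(self.networks)
        base = ["DMN", "Mot", "Vis", "FP", "Temp"]
        k = min(len(base), max(1, self.p_parcels // 10))
        sizes = np.full(k, self.p_parcels // k)
        sizes[: self.p_parcels % k] += 1
        return {name: int(s) for name, s in zip(base, sizes)}

    def target_correlation(self) -> np.ndarray:
        """The P x P block correlation matrix the generator aims for."""
        nets = self.resolve_networks()
        labels = np.concatenate([[n] * s for n, s in nets.items()])
        c = np.full((self.p_parcels, self.p_parcels), self.between_r)
        for n in nets:
            idx = np.flatnonzero(labels == n)
            c[np.ix_(idx, idx)] = self.within_r
        np.fill_diagonal(c, 1.0)
        return c

    def target_blocks(self) -> np.ndarray:
        """K x K ground-truth block matrix (within on diagonal)."""
        k = len(self.resolve_networks())
        b = np.full((k, k), self.between_r)
        np.fill_diagonal(b, self.within_r)
        return b


def gen_bold(
    params: BoldSimParams,
    truth: GroundTruth,
    seed=None,
    *,
    subject_id: str | None = None,
    run_id: str | None = None,
) -> ParcelTimeseries:
    """Simulate parcel BOLD for the run described by ``truth``."""
    rng = _rng(seed)
    t = truth.t_frames
    c = params.target_correlation()
    eig = np.linalg.eigvalsh(c)
    if eig.min() < -1e-10:
        raise ValueError(
            "target block covariance is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g}); check within_r/between_r"
        )
    l = np.linalg.cholesky(c + 1e-12 * np.eye(params.p_parcels))
    x = rng.standard_normal((t, params.p_parcels)) @ l.T

    # hemodynamic-like temporal smoothing (does not alter correlations)
    sigma = params.hemo_fwhm_s / (2.354820045 * truth.tr_s)
    if sigma > 0:
        x = gaussian_filter1d(x, sigma=sigma, axis=0, mode="nearest")
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    # spike-locked global corruption with random parcel weights; artifact
    # amplitude scales with the size of the movement (normalized to the
    # median spike amplitude)
    if truth.spike_frames.size and params.corruption_gain != 0:
        ind = np.zeros(t)
        ind[truth.spike_frames] = truth.spike_amps_mm / params.corruption_amp_ref_mm
        kern = np.asarray(params.corruption_kernel, dtype=float)
        c_t = np.convolve(ind, kern)[:t]
        w = rng.standard_normal(params.p_parcels)
        x = x + params.corruption_gain * c_t[:, None] * w[None, :]

    if params.resp_coupling_gain != 0:
        phase = 2 * np.pi * np.cumsum(truth.resp_hz_series) * truth.tr_s
        w = rng.standard_normal(params.p_parcels)
        x = x + params.resp_coupling_gain * np.sin(phase)[:, None] * w[None, :]

    nets = params.resolve_networks()
    parcel_ids = [f"p{i:03d}" for i in range(params.p_parcels)]
    labels = np.concatenate([[n] * s for n, s in nets.items()])
    network_of = {pid: lab for pid, lab in zip(parcel_ids, labels)}
    return ParcelTimeseries(
        data=x,
        parcel_ids=parcel_ids,
        network_of=network_of,
        tr_s=truth.tr_s,
        subject_id=subject_id,
        run_id=run_id,
    )


@dataclass
class SimulatedRun:
    motion: MotionTrace
    bold: ParcelTimeseries
    truth: GroundTruth


@dataclass
class SimulatedSubject:
    subject_id: str
    resp_hz: float
    runs: list[SimulatedRun]


@dataclass
class Cohort:
    subjects: list[SimulatedSubject]
    motion_params: MotionSimParams
    bold_params: BoldSimParams
    seed: int

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def gen_cohort(
    n_subjects: int,
    motion_params: MotionSimParams | None = None,
    bold_params: BoldSimParams | None = None,
    seed: int = 0,
    *,
    n_runs: int = 2,
    with_bold: bool = True,
    out_dir=None,
) -> Cohort:
    """Simulate a cohort of subjects with shared generator settings.

    Each subject draws one mean respiratory frequency (between-subject
    variability) shared by all of their runs; wander, spikes, noise and
    BOLD are drawn fresh per run.  Fully deterministic under a fixed
    ``seed``.  With ``out_dir`` set, motion files, timeseries, the
    network map, per-run ground truth JSON and a cohort manifest TSV are
    written in the package's plain-text formats.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    motion_params = motion_params or MotionSimParams()
    bold_params = bold_params or BoldSimParams()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)

    subjects = []
    for i, sseq in enumerate(subject_seeds):
        sid = f"sub{i:03d}"
        rng = np.random.default_rng(sseq)
        resp_hz = float(
            np.clip(
                rng.normal(motion_params.resp_hz_mean, motion_params.resp_hz_sd),
                motion_params.resp_hz_mean - 3 * motion_params.resp_hz_sd,
                motion_params.resp_hz_mean + 3 * motion_params.resp_hz_sd,
            )
        )
        runs = []
        for r in range(n_runs):
            rid = f"run{r + 1}"
            motion, truth = gen_motion(
                motion_params, rng, resp_hz=resp_hz, subject_id=sid, run_id=rid
            )
            bold = (
                gen_bold(bold_params, truth, rng, subject_id=sid, run_id=rid)
                if with_bold
                else None
            )
            runs.append(SimulatedRun(motion=motion, bold=bold, truth=truth))
        subjects.append(SimulatedSubject(subject_id=sid, resp_hz=resp_hz, runs=runs))

    cohort = Cohort(
        subjects=subjects,
        motion_params=motion_params,
        bold_params=bold_params,
        seed=seed,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to disk; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_path = None
    rows = ["subject_id\trun_id\tresp_hz\tmotion_file\tbold_file\ttruth_file"]
    for sub in cohort.subjects:
        for run in sub.runs:
            stem = f"{sub.subject_id}_{run.motion.run_id}"
            mpath = out / f"{stem}_motion.par"
            write_motion(run.motion, mpath)
            bpath = ""
            if run.bold is not None:
                bpath = out / f"{stem}_bold.tsv"
                write_timeseries(run.bold, bpath)
                if net_path is None:
                    net_path = out / "network_map.tsv"
                    write_network_map(run.bold.network_of, net_path)
                bpath = bpath.name
            tpath = out / f"{stem}_truth.json"
            write_report(
                {
                    "resp_hz": run.truth.resp_hz,
                    "spike_frames": run.truth.spike_frames,
                    "spike_amps_mm": run.truth.spike_amps_mm,
                    "tr_s": run.truth.tr_s,
                    "t_frames": run.truth.t_frames,
                },
                tpath,
            )
            rows.append(
                f"{sub.subject_id}\t{run.motion.run_id}\t{sub.resp_hz:.12g}\t"
                f"{mpath.name}\t{bpath}\t{tpath.name}"
            )
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
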