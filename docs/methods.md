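# Methods

This note documents the models, numerical choices and limitations behind
`respkit`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Framewise displacement

FD is the sum of absolute frame-to-frame changes of the six rigid-body
realignment parameters, with rotations converted to arc length at a head
radius. The radius is configurable because the same angular excursion
displaces a smaller head less: the default 35 mm suits infants/toddlers,
50 mm is the adult convention. `fd[0] = 0` by convention, so the first
frame is never censored on FD grounds alone. FD is absolutely homogeneous
in the parameters and invariant to constant offsets; both properties are
enforced by tests.

DVARS (spatial RMS of the temporal derivative) is computed on parcel
timeseries in native units; no voxel data or mode-1000 normalization is in
scope. The grayplot QC panel z-scores each parcel over time; zero-variance
parcels are detected with a relative tolerance (a constant column's
floating-point std is ~1e-15, not 0) and rendered as zero rows.

## Spectral estimation and peak detection

Motion-parameter spectra use a Welch periodogram: Hann window, 50%
overlap, segment length `min(T, 128)`. On a 420-frame run this averages
about six segments; the resulting grid spacing (~0.01 Hz at TR 0.8 s) is
comfortably below the ±0.02 Hz accuracy the peak-recovery tests demand,
and the segment averaging keeps single noise bins from masquerading as
respiratory peaks (the false-alarm rate of the 5×-median in-band criterion
on white noise is held to ≤5%, verified by simulation). Linear detrending
per segment (default) stops slow drift from leaking across the spectrum.

A subject's respiratory peak is the median, over the selected parameter
axes, of the frequency of maximum power inside a search band (default
0.2–0.6 Hz, the range where sleeping infants and toddlers breathe). By
default only the phase-encode translation is used — the artifact is
strongest there; pooling all six axes is supported. A peak whose power is
less than 3× the in-band median is flagged `low_prominence`; flagged
subjects are excluded from cohort cutoff derivation (their count is
logged). Spectra of multiple runs of one subject are averaged on a common
grid before peak detection.

`alias_frequency` implements the sampling fold
`f_alias = |f − fs·round(f/fs)|`: at TR ≥ 1.25 s a 0.4 Hz breath rate is
at/above Nyquist and folds to low frequency, which is why respiration was
invisible as a distinct band in older single-band acquisitions. Generator
configurations whose respiratory band would alias are rejected with a
pointer to this function.

## Notch design and application

Cohort cutoffs are derived from the distribution of per-subject peaks:
median → center, 25th/75th percentiles (linear-interpolation definition)
→ stopband edges. This is the only reading of "quartile-based bandwidth"
that yields an interior band around the median. Homogeneous cohorts are
widened symmetrically to a minimum width (default 0.06 Hz) to avoid
degenerate zero-width notches. The fixed recommendation for ages 8–24
months is 0.25–0.50 Hz, marginally wider than a single cohort's quartile
band so slower and faster breathers are covered.

Two filter families are implemented — a second-order IIR notch
(quality factor `center/(hi−lo)`) and a 2nd-order Butterworth band-stop on
the edges — because both are in institutional use and behave equivalently
here; the Butterworth band-stop is the default. Application is zero-phase
(forward–backward, odd-symmetric padding of 3× the tap count) so the
filtered FD trace stays aligned frame-for-frame with the censoring mask;
tests verify ≥20 dB attenuation at the center, ≤5% passband distortion at
0.05 Hz, exact DC invariance, linearity, and a lag-0 cross-correlation
peak. All six parameter columns are filtered identically, because the
artifact leaks from the phase-encode axis into every other parameter and
cannot be separated from real motion there. A band at or above Nyquist for
the trace's TR is rejected.

One collateral of any band-stop is worth noting: on a trace whose FD is
dominated by *broadband* noise rather than narrow-band respiration,
removing a 0.25 Hz-wide band necessarily removes a comparable share of
difference-series variance and lowers FD. The "filter is inert without
respiration" property therefore holds for slow-motion-dominated traces,
and is tested as such.

## Censoring and retention

Frames with FD ≤ threshold (default 0.2 mm) are retained; the
measure-zero boundary case is assigned to retention. Usable time is
`kept · TR / 60` exactly, with no rounding before display. No temporal
augmentation (censoring neighbours of bad frames) is performed; the flag
is reserved. Retention reports pair the unfiltered and filtered arms of
the same run.

## Connectivity

Correlation-based connectivity uses retained frames only. The
interpolation stage (`bandpass_interp`) replaces censored frames by
linear interpolation between the nearest retained neighbours before the
zero-phase 2nd-order Butterworth bandpass (default 0.008–0.09 Hz;
0.005–0.1 Hz available by argument) — dropping frames before an IIR
filter would alias artifact across the series. The censoring mask is then
re-imposed by the consumer. Pearson correlations are computed over ≥10
retained frames (configurable floor); zero-variance parcels yield zeroed
rows/columns with a warning.

Network blocks average parcel-pair correlations within/between networks;
within-network cells exclude the diagonal, and singleton networks report
a missing within cell. Paired inference across subjects uses Fisher-z
transformed values (standard for correlation inference; inverse-transform
for display). No multiple-comparison correction is applied by default.
Nuisance regression is out of scope: the generator emits pre-denoised
signals, and externally cleaned timeseries pass straight through.

## Split-half reliability

Usable frames at a threshold are enumerated in temporal order across a
subject's concatenated runs; the first ⌊U/2⌋ form half 1 and the next
⌊U/2⌋ half 2 (an odd frame is dropped), so both half-matrices rest on
identical amounts of data. With two equal, fully usable runs this
reduces to run 1 vs run 2. An alternating (odd/even) split is available
for sensitivity checks. Reliability is the Pearson correlation of the two
halves' off-diagonal upper triangles; identical halves return exactly 1.
Cohort curves report mean, SD and SE across subjects per threshold; a
subject contributes only when both halves meet the frame floor, and
thresholds with fewer than two survivors are marked missing.

## The synthetic generator

`gen_motion` composes, per run: a frequency-wandering respiratory
sinusoid (subject mean drawn from 0.40 ± 0.05 Hz between subjects,
truncated at ±3 SD; within-run wander SD 0.01 Hz), amplitude 0.15 mm on
the phase-encode translation with a 0.3 fraction leaking into the other
translations and a 0.1 fraction (arc-length at 35 mm) into the rotations,
all with random relative phases; slow linear drift (0.02 mm/min SD);
white parameter noise (0.005 mm); and sparse spontaneous movements.
Movements are instantaneous repositioning steps at Poisson-distributed
frames (2/min), at least 5 frames apart, with total FD contribution drawn
from a log-normal (median 1.2 mm, σ 0.3) floored at 1.0 mm.

The floor is a deliberate identifiability choice, set by a worst-case
bound rather than by realism alone: the widest plausible stopband retains
only ~50% of a step's at-frame FD after zero-phase filtering, and a
subject whose breathing sits at a band edge can keep ~0.25 mm of
respiratory FD residual that may cancel against the step; for every spike
to remain censorable under every covering band the floor must exceed
(0.2 + 0.25)/0.5 = 0.9 mm. Steps of ≥1 mm also match the visible spike
amplitudes in single-subject FD traces. Note the *unfiltered* trace gives
no such guarantee — respiratory deltas can momentarily cancel a spike
there, which is precisely the conflation problem filtering addresses.

`gen_bold` draws network-structured Gaussian signals (default 50 parcels
in 5 networks; target correlations 0.35 within, 0.05 between; Cholesky of
the block matrix, which is checked for positive semi-definiteness),
smooths them with a Gaussian kernel of 4 s FWHM to mimic hemodynamic
autocorrelation (per-column re-standardization keeps the correlation
structure), and adds spike-locked corruption: the spike indicator,
weighted by movement amplitude (normalized at 1.2 mm) and convolved with
a short decaying kernel (1.0, 0.6, 0.3), multiplied by zero-mean random
parcel weights and a gain of 1.5. The gain is calibrated so DVARS at
spike frames exceeds the run median ~3–5×. Respiration does **not** enter
the BOLD signal — that asymmetry (breathing corrupts motion *estimates*,
movements corrupt *signal*) is the premise that makes rescuing
respiratory frames correct; a `resp_coupling_gain` flag can inject a
respiration-locked component for sensitivity experiments.

`gen_cohort` draws one breathing rate per subject (shared by their runs)
and is fully deterministic under a seed, including byte-identical written
manifests.

### What the generator does and does not emulate

It reproduces the statistical signatures the pipeline relies on:
narrow-band respiratory pseudo-motion with leak, spike-locked signal
disruption, block-structured connectivity, paper-like retention contrast
(a fraction of a run usable unfiltered vs nearly all of it filtered). It
does not model image-space physics (B0 perturbation, spin history,
distance-dependent artifact), real nuisance structure (cardiac,
vasomotion, scanner drift), non-Gaussian BOLD, or developmental
differences in hemodynamics. Passing tests therefore demonstrate the
*pipeline's* correctness and the *direction* of its benefits under the
stated premise, not effect sizes in real infant data.

### A note on the connectivity contrast

With corruption confined to (mostly censored) spike frames, the two
censoring arms differ mainly in how many frames they keep, so the
filtered-vs-unfiltered contrast of connectivity *estimates* is driven by
precision, not bias, when correlating raw retained frames — and the
small-sample positive bias of Fisher z can even tip the noisier
unfiltered arm slightly higher. The paper-style pipeline order matters:
after interpolation + bandpass, corrupted retained frames anchor the
interpolation of the unfiltered arm's many censored gaps and smear
artifact through its series, which attenuates its block estimates and
yields the expected positive within-network contrast for the filtered
arm. Even so, at 50 four-run sessions this direction statistic is weak
(mean within-block paired t in the tenths), while the RMSE advantage of
the filtered arm is robust. The acceptance machinery computes both.

## Problem sizes

Simulated studies use the acquisition geometry the defaults encode: 420
frames at TR 0.8 s per run (5.6 min), 4-run sessions (22.4 min) for
connectivity contrasts, 30-subject 2-run cohorts for reliability sweeps,
100 cohorts of 30 subjects for cutoff-recovery rates. A TR 0.72 s
configuration is available for replication across sampling rates.

## Known limitations

- Parcel timeseries are the atomic signal unit; no NIfTI/CIFTI I/O.
- Network assignments are inputs; no community detection.
- Individual-subject cutoffs are supported but not recommended as
  defaults; group-level bands are the intended use.
- The reliability protocol is within-session split-half, not
  test–retest; no ICCs.
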