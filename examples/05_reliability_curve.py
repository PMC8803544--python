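"""Split-half reliability of connectivity across FD thresholds.

For each subject, usable frames at a threshold are split into temporal
halves, a connectivity matrix is built per half, and the two are
spatially correlated.  Sweeping the threshold for both censoring arms
shows the reliability bought by rescuing respiratory frames.
"""

import numpy as np

import respkit as rk

band = rk.infant_toddler_notch()
cohort = rk.gen_cohort(15, seed=21, n_runs=2)

subs_u, subs_f = [], []
for sub in cohort:
    ru, rf = [], []
    for run in sub.runs:
        ru.append((run.bold, rk.compute_fd(run.motion)))
        rf.append((run.bold, rk.compute_fd(rk.apply_notch(run.motion, band))))
    subs_u.append(ru)
    subs_f.append(rf)

thresholds = np.round(np.arange(0.1, 0.41, 0.05), 10)
cu = rk.reliability_curve(subs_u, thresholds, arm="unfiltered")
cf = rk.reliability_curve(subs_f, thresholds, arm="filtered")

print("threshold  unfiltered (n)    filtered (n)")
for i, thr in enumerate(thresholds):
    print(f"  {thr:.2f}     {cu.mean_r[i]: .3f} ({cu.n_subjects[i]:2d})     "
          f"{cf.mean_r[i]: .3f} ({cf.n_subjects[i]:2d})")
print()
print("At strict thresholds the unfiltered arm has little usable data per")
print("half (few or no surviving subjects); the filtered arm keeps nearly")
print("all frames and yields higher split-half correlations.")
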