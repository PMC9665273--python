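"""Cohort-level comparison of RETROICOR against the 15-band filter grid.

Simulates a 10-subject cohort, computes group-mean Fisher-z per region
pair for the RETROICOR arm and each bandpass arm, and correlates the two
across the 3403 pairs — the correlation-versus-band curve.  Also runs the
per-pair paired t-test (with FDR correction) between RETROICOR and the
0.008-0.125 Hz band.
"""

import numpy as np

from physiofc import (SimParams, cross_pipeline_correlation, paired_t_map,
                      run_synthetic_study)

study = run_synthetic_study(n_subjects=10, seed=0,
                            params=SimParams(spike_rate=0.0))
mean_retro = study.arms["retroicor"].mean(axis=0)

print("band                    r(mean z, mean z)")
curve = {}
for band in study.bands:
    r, _ = cross_pipeline_correlation(mean_retro,
                                      study.band_arm(band).mean(axis=0))
    curve[band.label] = r
    print(f"{band.label:22s}  {r:.4f}")
best = max(curve, key=curve.get)
print(f"\nhighest correlation at: {best}")
# The curve peaks at the band that covers the neural range and excludes
# the aliased cardiorespiratory power — the 0.008-0.125 Hz filter.

ps = paired_t_map(study.arms["retroicor"],
                  study.arms["band:0.008–0.125 Hz"])
print(f"paired t, RETROICOR vs 0.008–0.125 Hz: "
      f"{int(ps['reject'].sum())} of {len(ps['p'])} pairs significant "
      f"at P_fdr < 0.05")
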