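"""Feasibility triage of the packaged 35-subject cohort tables.

Subjects are partitioned in precedence order: unusable fMRI (imaging
artefacts) -> incomplete physiological data (a channel absent) -> poor
quality (noisy or intermittent recordings) -> retained for the
physiologically corrected analysis.
"""

from physiofc import feasibility_triage, load_example_cohort

res = feasibility_triage(load_example_cohort())
print(res.summary.to_string(index=False))

s = res.summary.set_index("group")
print(f"\n{int(s.loc['overall', 'n_incomplete'])}/"
      f"{int(s.loc['overall', 'n_usable_fmri'])} subjects with usable "
      f"fMRI had incomplete physiological data "
      f"({s.loc['overall', 'pct_incomplete']:.0f}%); another "
      f"{int(s.loc['overall', 'n_poor_quality'])} had poor-quality "
      f"recordings.")
print(f"patients retained for correction: "
      f"{int(s.loc['patient', 'n_retained'])}/"
      f"{int(s.loc['patient', 'n_usable_fmri'])}; controls: "
      f"{int(s.loc['control', 'n_retained'])}/"
      f"{int(s.loc['control', 'n_usable_fmri'])} "
      f"({s.loc['control', 'pct_retained']:.0f}%)")
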