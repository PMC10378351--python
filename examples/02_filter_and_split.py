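"""Cohort screening and the age-stratified 70/30 split.

Reconstructs the three exclusion stages on an engineered raw cohort
(records missing clinical fields, survival-time tie groups, censored
records without a death date) and then splits the survivors of a synthetic
cohort at an age cutoff. The screening counts mirror a published breast
cancer screening flow: 1187 -> 1091 -> 807 -> 144.
"""

import survimage as sv

raw = sv.simulate_screening_cohort(
    n_total=1187, n_missing=96, n_tied=284, n_no_death=663
)
cohort, report = sv.filter_cohort(raw, require_death_date=True)
print("screening:", report.n_input, "->", " -> ".join(map(str, report.stage_survivors)))
print("excluded per stage:", report.excluded_missing_clinical,
      report.excluded_tied_survival, report.excluded_no_death_date)

# age-stratified split of a synthetic modeling cohort
sim, _ = sv.simulate_cohort(sv.SimConfig(n_patients=40, n_genes=36, seed=0))
modeling, _ = sv.filter_cohort(sim)
spec = sv.stratified_split(modeling, cutoff_age=61, train_frac=0.7, seed=0)
for stratum in ("YOUNG", "OLD"):
    print(f"{stratum}: train {len(spec.train_of(stratum))}, "
          f"test {len(spec.test_of(stratum))}")
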