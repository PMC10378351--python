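"""Five-bin survival-interval prediction against reference patients.

Trains a classifier on a synthetic cohort, scores per-age accuracy on the
held-out images, selects four reference patients with survival near the
182 / 365 / 1095 / 1825-day boundaries from well-predicted ages, and
brackets a new patient's survival interval from the four patient-vs-
reference difference-image calls.
"""

import survimage as sv

sim, truth = sv.simulate_cohort(sv.SimConfig(
    n_patients=60, n_genes=400, effect_size=2.0, seed=3,
    survival_range_days=(30, 4000),
))
cohort, _ = sv.filter_cohort(sim)
cohort = sv.Cohort(records=cohort.records,
                   expression=sv.fpkm_to_tpm(cohort.expression))

spec = sv.stratified_split(cohort, cutoff_age=61, seed=3)
train, test = [], []
for stratum in ("YOUNG", "OLD"):
    train += sv.build_image_set(cohort, spec.train_of(stratum))
    test += sv.build_image_set(cohort, spec.test_of(stratum))
model = sv.train_model(train, sv.TrainConfig(architecture="logreg", seed=3))
print(f"held-out accuracy: {sv.evaluate(model, test).accuracy:.3f}")

per_age = sv.evaluate_by_age(model, cohort, test)
refs = sv.select_references(cohort, per_age, accuracy_threshold=0.7)
print("references (survival near 6mo / 1y / 3y / 5y):",
      [(r.sample_id, r.survival_days) for r in refs.references])

query = spec.test_ids[0]
result = sv.predict_interval(cohort.expression.column(query), refs, model)
print(f"patient {query}: true survival {cohort.survival_of(query)} days "
      f"(bin {sv.survival_bin(cohort.survival_of(query))})")
print(f"  per-reference longer-survival calls: {result.per_reference_calls}")
print(f"  predicted interval: {result.interval} "
      f"(consistent={result.consistent})")
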