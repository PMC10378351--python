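"""Reference selection and five-bin survival-interval logic."""

import numpy as np
import pytest

import survimage as sv
from survimage.intervals import IntervalError, prediction_images

from conftest import make_manual_cohort


class OracleModel:
    """Labels patient-vs-reference images from known survival times.

    Substituting this for the learned classifier isolates the bin-bracketing
    logic from the learning problem.
    """

    def __init__(self, patient_survival, ref_survival):
        self.patient_survival = patient_survival
        self.ref_survival = ref_survival

    def predict_images(self, images):
        return [
            "TLS"
            if self.patient_survival > self.ref_survival[img.shorter_id]
            else "TSL"
            for img in images
        ]


class TestSurvivalBin:
    @pytest.mark.parametrize(
        "days,expected",
        [
            (0, "<6mo"), (181, "<6mo"), (182, "6mo-1y"), (364, "6mo-1y"),
            (365, "1-3y"), (1094, "1-3y"), (1095, "3-5y"), (1824, "3-5y"),
            (1825, ">5y"), (7455, ">5y"),
        ],
    )
    def test_bin_boundaries(self, days, expected):
        assert sv.survival_bin(days) == expected

    def test_bins_partition_time_axis(self):
        """Every non-negative day falls in exactly one of the five bins."""
        for days in range(0, 2500, 7):
            assert sv.survival_bin(days) in sv.BIN_LABELS
        with pytest.raises(IntervalError):
            sv.survival_bin(-1)


class TestSelectReferences:
    def accuracy_map(self, cohort, value=1.0):
        return {r.age_years: value for r in cohort.records}

    def test_nearest_to_boundary(self):
        cohort = make_manual_cohort([100, 200, 400, 1200, 2000])
        refs = sv.select_references(cohort, self.accuracy_map(cohort))
        assert [r.survival_days for r in refs.references] == [200, 400, 1200, 2000]
        assert [r.boundary for r in refs.references] == [182, 365, 1095, 1825]

    def test_equidistant_tie_breaks_lexically(self):
        # 150 and 214 are both 32 days from the 182-day boundary
        cohort = make_manual_cohort([150, 214, 400, 1100, 1900])
        refs = sv.select_references(cohort, self.accuracy_map(cohort))
        assert refs.references[0].sample_id == "P00"  # survival 150

    def test_threshold_excludes_low_accuracy_ages(self):
        cohort = make_manual_cohort(
            [150, 200, 400, 1100, 1900], ages=[40, 50, 60, 70, 80]
        )
        acc = {40: 0.2, 50: 0.9, 60: 0.9, 70: 0.9, 80: 0.9}
        refs = sv.select_references(cohort, acc)
        assert "P00" not in [r.sample_id for r in refs.references]

    def test_empty_eligibility_raises(self):
        cohort = make_manual_cohort([100, 400, 1100, 1900])
        with pytest.raises(IntervalError, match="boundary"):
            sv.select_references(cohort, self.accuracy_map(cohort, value=0.1))

    def test_reference_survivals_strictly_increase(self):
        cohort = make_manual_cohort([120, 250, 500, 900, 1300, 2200])
        refs = sv.select_references(cohort, self.accuracy_map(cohort))
        surv = [r.survival_days for r in refs.references]
        assert surv == sorted(surv) and len(set(surv)) == 4


class TestPredictInterval:
    def make_refs(self):
        cohort = make_manual_cohort([182, 365, 1095, 1825])
        return cohort, sv.ReferenceSet(
            references=tuple(
                sv.Reference(
                    sample_id=r.sample_id,
                    tpm=cohort.expression.column(r.sample_id),
                    survival_days=r.survival_days,
                    boundary=b,
                )
                for r, b in zip(cohort.records, sv.DEFAULT_BOUNDARIES)
            )
        )

    def test_call_patterns_bracket_bins(self):
        cohort, refs = self.make_refs()
        ref_surv = {r.sample_id: r.survival_days for r in refs.references}
        patient = cohort.expression.column("P00")
        cases = [(700, "1-3y"), (5000, ">5y"), (10, "<6mo"), (200, "6mo-1y")]
        for days, expected in cases:
            res = sv.predict_interval(patient, refs, OracleModel(days, ref_surv))
            assert res.interval == expected
            assert res.consistent

    def test_oracle_recovers_every_true_bin(self):
        """With an oracle classifier the predicted bin equals the true bin
        for every synthetic patient not used as a reference."""
        cohort, refs = self.make_refs()
        ref_surv = {r.sample_id: r.survival_days for r in refs.references}
        patient = cohort.expression.column("P00")
        rng = np.random.default_rng(0)
        for days in rng.integers(0, 4000, size=60):
            if days in ref_surv.values():
                continue
            res = sv.predict_interval(
                patient, refs, OracleModel(int(days), ref_surv)
            )
            assert res.interval == sv.survival_bin(int(days))
            assert res.consistent

    def test_non_monotone_calls_flagged(self):
        class Inconsistent:
            def predict_images(self, images):
                return ["TLS", "TSL", "TLS", "TSL"]

        cohort, refs = self.make_refs()
        res = sv.predict_interval(
            cohort.expression.column("P00"), refs, Inconsistent()
        )
        assert not res.consistent
        assert res.interval == "1-3y"  # two "longer" calls -> bin index 2

    def test_geometry_mismatch_raises(self):
        _, refs = self.make_refs()
        with pytest.raises(IntervalError, match="length"):
            prediction_images(np.ones(5), refs)

    def test_prediction_images_use_training_scaling(self):
        cohort, refs = self.make_refs()
        imgs = prediction_images(cohort.expression.column("P00"), refs)
        assert len(imgs) == 4
        assert all(img.label == "TLS" for img in imgs)
        assert all(img.side == sv.matrix_side(cohort.expression.n_genes) for img in imgs)


class TestEvaluateByAge:
    def test_keys_subset_of_cohort_ages_and_values_in_range(self, tpm_cohort):
        images = sv.build_image_set(tpm_cohort)
        model = sv.train_model(
            images, sv.TrainConfig(architecture="logreg", seed=0)
        )
        per_age = sv.evaluate_by_age(model, tpm_cohort, images)
        ages = {r.age_years for r in tpm_cohort.records}
        assert set(per_age) <= ages
        assert all(0.0 <= v <= 1.0 for v in per_age.values())

    def test_restricting_images_restricts_ages(self, tpm_cohort):
        ids = tpm_cohort.sample_ids[:3]
        images = sv.build_image_set(tpm_cohort, ids)
        model = sv.train_model(
            sv.build_image_set(tpm_cohort),
            sv.TrainConfig(architecture="logreg", seed=0),
        )
        per_age = sv.evaluate_by_age(model, tpm_cohort, images)
        involved_ages = {tpm_cohort.age_of(s) for s in ids}
        assert set(per_age) <= involved_ages
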