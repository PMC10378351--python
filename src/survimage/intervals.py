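"""Five-bin survival-interval prediction against reference patients.

A new patient is compared with four reference patients whose survival times
sit near the four interval boundaries — about 6 months, 1 year, 3 years and
5 years (182 / 365 / 1095 / 1825 days). Each comparison forms the patient −
reference difference image (the TLS orientation, scaled exactly as in
training) and asks the trained classifier whether the patient's pattern is
the longer-survival one. Four ordered binary calls bracket five bins:

    <6mo · 6mo-1y · 1-3y · 3-5y · >5y

The predicted bin is the count of "patient survives longer" calls; a call
pattern that is not monotone (longer … longer, shorter … shorter) is still
resolved by that count but flagged ``consistent=False``.

References are chosen from cohort members whose *age group* the model
predicts well: an age is eligible when its per-age test accuracy exceeds a
threshold (default 0.7), and for each boundary the eligible patient with
survival closest to the boundary is picked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .imaging import DifferenceImage, make_image
from .training import TrainedModel, evaluate, images_to_arrays

__all__ = [
    "DEFAULT_BOUNDARIES",
    "BIN_LABELS",
    "Reference",
    "ReferenceSet",
    "PredictionResult",
    "IntervalError",
    "survival_bin",
    "select_references",
    "evaluate_by_age",
    "predict_interval",
]

#: Interval boundaries in days: 6 months, 1 year, 3 years, 5 years.
DEFAULT_BOUNDARIES = (182, 365, 1095, 1825)

#: The five survival bins, shortest first.
BIN_LABELS = ("<6mo", "6mo-1y", "1-3y", "3-5y", ">5y")


class IntervalError(ValueError):
    """Raised when references cannot be selected or geometry mismatches."""


def survival_bin(days: float, boundaries=DEFAULT_BOUNDARIES) -> str:
    """Map a survival time to its bin; bins are [b_{k-1}, b_k) half-open.

    Every non-negative time falls in exactly one bin.
    """
    if days < 0:
        raise IntervalError(f"negative survival time {days}")
    k = int(np.searchsorted(np.asarray(boundaries), days, side="right"))
    return BIN_LABELS[k]


@dataclass(frozen=True)
class Reference:
    sample_id: str
    tpm: np.ndarray
    survival_days: int
    boundary: int


@dataclass(frozen=True)
class ReferenceSet:
    """Exactly four references, ordered by strictly increasing survival."""

    references: tuple[Reference, ...]
    boundaries: tuple[int, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        if len(self.references) != len(self.boundaries) or len(self.references) != 4:
            raise IntervalError("need exactly four references, one per boundary")
        surv = [r.survival_days for r in self.references]
        if any(b >= a for a, b in zip(surv[1:], surv[:-1])):
            raise IntervalError(
                f"reference survivals must strictly increase, got {surv}"
            )


@dataclass(frozen=True)
class PredictionResult:
    """Predicted bin plus the four per-reference comparison outcomes."""

    interval: str
    per_reference_calls: tuple[bool, ...]  # True = patient called longer-surviving
    consistent: bool


def evaluate_by_age(model: TrainedModel, c: Cohort, images: list[DifferenceImage] | None = None) -> dict[int, float]:
    """Per-age accuracy: images restricted to pairs involving that age.

    ``images`` defaults to the full pairwise image set of the cohort; pass a
    held-out subset to score on test images only. Ages with no images are
    omitted.
    """
    from .imaging import build_image_set  # local import to avoid cycle at module load

    if images is None:
        images = build_image_set(c)
    age_of = {r.sample_id: r.age_years for r in c.records}
    X, y = images_to_arrays(images)
    pred = model.predict(X)
    correct = pred == y
    out: dict[int, list[bool]] = {}
    for img, ok in zip(images, correct):
        for sid in (img.longer_id, img.shorter_id):
            age = age_of.get(sid)
            if age is not None:
                out.setdefault(age, []).append(bool(ok))
    return {age: float(np.mean(v)) for age, v in sorted(out.items())}


def select_references(
    c: Cohort,
    per_age_accuracy: dict[int, float],
    boundaries=DEFAULT_BOUNDARIES,
    accuracy_threshold: float = 0.7,
) -> ReferenceSet:
    """Pick, per boundary, the eligible patient with the nearest survival.

    A patient is eligible when their age's accuracy exceeds the threshold.
    Ties on |survival − boundary| break to the lexicographically smaller
    sample id; a patient already chosen for a lower boundary is not reused.

    Raises
    ------
    IntervalError
        If no eligible patient remains for some boundary, or the chosen
        references do not end up in strictly increasing survival order.
    """
    eligible = [
        r
        for r in c.records
        if r.age_years is not None
        and r.survival_days is not None
        and per_age_accuracy.get(r.age_years, 0.0) > accuracy_threshold
    ]
    chosen: list[Reference] = []
    used: set[str] = set()
    for b in boundaries:
        pool = [r for r in eligible if r.sample_id not in used]
        if not pool:
            raise IntervalError(
                f"no eligible reference patient for boundary {b} days"
            )
        best = min(pool, key=lambda r: (abs(r.survival_days - b), r.sample_id))
        used.add(best.sample_id)
        chosen.append(
            Reference(
                sample_id=best.sample_id,
                tpm=c.expression.column(best.sample_id),
                survival_days=best.survival_days,
                boundary=b,
            )
        )
    return ReferenceSet(references=tuple(chosen), boundaries=tuple(boundaries))


def prediction_images(
    patient_tpm: np.ndarray, refs: ReferenceSet, patient_id: str = "query"
) -> list[DifferenceImage]:
    """The four patient-vs-reference difference images, TLS orientation.

    Each image encodes ``patient − reference`` with the same per-image
    scaling used for training images; a TLS call on it means the patient is
    predicted to outlive that reference.
    """
    patient_tpm = np.asarray(patient_tpm, dtype=np.float64)
    images = []
    for ref in refs.references:
        if patient_tpm.shape != ref.tpm.shape:
            raise IntervalError(
                f"patient vector length {patient_tpm.size} does not match "
                f"reference {ref.sample_id!r} length {ref.tpm.size}"
            )
        images.append(
            make_image(patient_tpm, ref.tpm, "TLS", patient_id, ref.sample_id)
        )
    return images


def predict_interval(
    patient_tpm: np.ndarray, refs: ReferenceSet, model
) -> PredictionResult:
    """Classify the patient against each reference and bracket the bin.

    ``model`` is anything with a ``predict_images(list) -> list[str]``
    method (a :class:`~survimage.training.TrainedModel`, or an oracle in
    tests). The bin index is the number of references the patient is called
    longer-surviving than; a non-monotone call pattern is flagged.
    """
    images = prediction_images(patient_tpm, refs)
    labels = model.predict_images(images)
    calls = tuple(lab == "TLS" for lab in labels)
    k = sum(calls)
    # a monotone pattern is True^k followed by False^(4-k)
    consistent = calls == tuple([True] * k + [False] * (len(calls) - k))
    return PredictionResult(
        interval=BIN_LABELS[k],
        per_reference_calls=calls,
        consistent=consistent,
    )
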