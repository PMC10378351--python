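"""Synthetic cohorts with a controllable survival-correlated signature.

The generator emulates the structure the pipeline consumes — an FPKM
genes × samples table plus a clinical table with age, survival days, a
death-date flag and race — without imitating real RNA-seq count mechanics.

Expression model (per patient ``p``, gene ``g``, on the natural-log scale):

    log x[g, p] = mu_g + s_g * effect_size * noise_sd * t_p + eps,
    eps ~ N(0, noise_sd),  mu_g ~ N(baseline_log_mean, baseline_log_sd)

where ``s_g ∈ {−1, +1}`` is a fixed random sign for each *signature* gene
(``s_g = 0`` for the rest) and ``t_p`` drives the survival coupling:

* with no planted age break, ``t_p`` is the standardized rank of the
  patient's survival time for every patient, so pairwise expression
  differences are informative about which member of a pair survives longer;
* with a planted age break, patients at or below the break additionally get
  a constant ``age_break_offset`` (in rank-SD units) added to their
  signature activation: ``t_p = z_p + B * [age <= break]``. The offset
  models an age step in the baseline expression of the prognostic
  signature. Same-group pairwise differences cancel the step and stay
  survival-informative; cross-group differences are dominated by it, and
  because the longer survivor of a cross pair is equally likely to sit on
  either side of the step, cross pairs carry essentially no label
  information. Accuracy of the stratified pipeline therefore peaks exactly
  at the break, where neither stratum mixes the two groups. (Designs that
  simply silence or decouple the signature below the break do not produce
  this peak: any pair containing one survival-coupled patient still leaks
  that patient's own rank through the difference image, which rewards
  off-break cutoffs.)

``effect_size`` is therefore the slope of mean log-expression per unit of
standardized survival rank, in units of the residual SD.

Survival times are sampled without replacement (distinct by construction);
``tie_fraction`` then deliberately copies survival values between patients
to exercise the tie filter, ``missing_fraction`` blanks age or survival
fields, and ``death_date_fraction`` controls the censoring-artifact flag.
A ground-truth manifest (signature genes, signs, tie-group members, true
bins) accompanies every cohort for exact bookkeeping tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import ClinicalRecord, Cohort
from .expression import ExpressionMatrix
from .intervals import survival_bin

__all__ = ["SimConfig", "GroundTruth", "SimulationError", "simulate_cohort",
           "simulate_screening_cohort", "save_cohort"]


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort generator.

    Defaults are desk-scale: 40 patients × 400 genes (a 20 × 20 image), a
    quarter of genes carrying a strong (2 residual-SD per rank-SD) survival
    signature, everyone with a recorded death date and no deliberate data
    defects. ``n_genes=60483`` reproduces the full-scale image geometry.
    """

    n_patients: int = 40
    n_genes: int = 400
    frac_signal_genes: float = 0.25
    effect_size: float = 2.0
    noise_sd: float = 0.4
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    age_range: tuple[int, int] = (26, 90)
    survival_range_days: tuple[int, int] = (1, 3000)
    planted_age_break: int | None = None
    age_break_offset: float = 4.0
    tie_fraction: float = 0.0
    missing_fraction: float = 0.0
    death_date_fraction: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Generator-side truth for bookkeeping and oracle tests."""

    signal_genes: list[str]
    gene_signs: dict[str, int]
    tie_members: list[str]           # every sample involved in an injected tie
    missing_ids: list[str]           # samples with a blanked clinical field
    no_death_ids: list[str]
    survival: dict[str, int]         # pre-blanking survival of every sample
    true_bins: dict[str, str]
    below_break_ids: list[str]       # patients carrying the age-step offset


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a raw FPKM cohort plus its ground-truth manifest.

    Identical configs (including seed) give byte-identical cohorts.

    Raises
    ------
    SimulationError
        If the survival range cannot host ``n_patients`` distinct values,
        or fractions are out of range.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    lo, hi = cfg.survival_range_days
    if hi - lo + 1 < n:
        raise SimulationError(
            f"survival range {cfg.survival_range_days} cannot host "
            f"{n} distinct values"
        )
    for name in ("frac_signal_genes", "tie_fraction", "missing_fraction",
                 "death_date_fraction"):
        val = getattr(cfg, name)
        if not 0.0 <= val <= 1.0:
            raise SimulationError(f"{name} must be in [0, 1], got {val}")
    if n < 2 or cfg.n_genes < 1:
        raise SimulationError("need at least 2 patients and 1 gene")

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = sorted(f"G{i:05d}" for i in range(cfg.n_genes))

    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)
    survival = rng.choice(np.arange(lo, hi + 1), size=n, replace=False)

    # survival-rank coupling (computed before tie injection / blanking)
    ranks = survival.argsort().argsort().astype(np.float64)
    z = (ranks - ranks.mean()) / ranks.std()

    n_signal = int(round(cfg.frac_signal_genes * cfg.n_genes))
    signal_idx = np.sort(rng.choice(cfg.n_genes, size=n_signal, replace=False))
    signs = np.zeros(cfg.n_genes)
    signs[signal_idx] = rng.choice([-1.0, 1.0], size=n_signal)

    # signature activation: survival rank, plus the age-step offset if planted
    t = z.copy()
    below_break = np.zeros(n, dtype=bool)
    if cfg.planted_age_break is not None:
        below_break = ages <= cfg.planted_age_break
        t = t + cfg.age_break_offset * below_break

    mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    log_expr = (
        mu[:, None]
        + signs[:, None] * cfg.effect_size * cfg.noise_sd * t[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    )
    fpkm = np.exp(log_expr)

    # inject survival ties: each "copier" takes the survival of a distinct source
    survival = survival.astype(int)
    n_copiers = int(round(cfg.tie_fraction * n))
    tie_members: set[str] = set()
    if n_copiers:
        perm = rng.permutation(n)
        copiers, sources = perm[:n_copiers], perm[n_copiers : 2 * n_copiers]
        if len(sources) < n_copiers:
            raise SimulationError("tie_fraction too large to pair copiers with sources")
        for c, s in zip(copiers, sources):
            survival[c] = survival[s]
            tie_members.add(sample_ids[c])
            tie_members.add(sample_ids[s])

    # blank clinical fields (alternating age / survival)
    n_missing = int(round(cfg.missing_fraction * n))
    candidates = [i for i in range(n) if sample_ids[i] not in tie_members]
    if n_missing > len(candidates):
        raise SimulationError(
            "missing_fraction overlaps injected ties; reduce one of them"
        )
    missing_sel = rng.permutation(np.array(candidates, dtype=int))[:n_missing] if n_missing else np.array([], dtype=int)
    has_death = rng.random(n) < cfg.death_date_fraction

    records = []
    missing_ids, no_death_ids = [], []
    for i, sid in enumerate(sample_ids):
        age: int | None = int(ages[i])
        surv: int | None = int(survival[i])
        if i in missing_sel:
            if len(missing_ids) % 2 == 0:
                age = None
            else:
                surv = None
            missing_ids.append(sid)
        if not has_death[i]:
            no_death_ids.append(sid)
        records.append(
            ClinicalRecord(
                sample_id=sid,
                age_years=age,
                survival_days=surv,
                has_death_date=bool(has_death[i]),
                race=None,
            )
        )

    cohort = Cohort(
        records=records,
        expression=ExpressionMatrix(
            gene_ids=gene_ids, sample_ids=sample_ids, values=fpkm, unit="FPKM"
        ),
    )
    truth = GroundTruth(
        signal_genes=[gene_ids[int(i)] for i in sorted(signal_idx)],
        gene_signs={gene_ids[int(i)]: int(signs[int(i)]) for i in sorted(signal_idx)},
        tie_members=sorted(tie_members),
        missing_ids=sorted(missing_ids),
        no_death_ids=sorted(no_death_ids),
        survival={sid: int(s) for sid, s in zip(sample_ids, survival)},
        true_bins={sid: survival_bin(int(s)) for sid, s in zip(sample_ids, survival)},
        below_break_ids=[sid for sid, b in zip(sample_ids, below_break) if b],
    )
    return cohort, truth


def simulate_screening_cohort(
    n_total: int = 1187,
    n_missing: int = 96,
    n_tied: int = 284,
    n_no_death: int = 663,
    n_genes: int = 4,
    seed: int = 0,
) -> Cohort:
    """A raw cohort engineered to hit exact screening-stage counts.

    Constructs ``n_total`` records of which exactly ``n_missing`` lack a
    clinical field, exactly ``n_tied`` (complete) records fall in survival
    tie groups of two (plus one group of three when odd), and exactly
    ``n_no_death`` of the remaining complete, untied records lack a death
    date. Defaults mirror the published screening flow
    1187 → 1091 → 807 → 144.
    """
    n_rest = n_total - n_missing - n_tied
    if min(n_missing, n_tied, n_no_death) < 0 or n_rest < n_no_death:
        raise SimulationError("inconsistent screening counts")
    rng = np.random.default_rng(seed)
    records = []
    next_surv = 10  # distinct survival values handed out sequentially
    sid = 0

    def new_id():
        nonlocal sid
        sid += 1
        return f"R{sid:05d}"

    for k in range(n_missing):
        records.append(
            ClinicalRecord(new_id(), None if k % 2 == 0 else 50,
                           None if k % 2 == 1 else 100 + k, True)
        )
    # tie groups of two (one group of three if n_tied is odd)
    remaining = n_tied
    while remaining > 0:
        size = 3 if remaining == 3 else 2
        shared = next_surv
        next_surv += 1
        for _ in range(size):
            records.append(ClinicalRecord(new_id(), int(rng.integers(30, 90)), shared, True))
        remaining -= size
    for k in range(n_rest):
        records.append(
            ClinicalRecord(new_id(), int(rng.integers(30, 90)), next_surv, k >= n_no_death)
        )
        next_surv += 1

    ids = [r.sample_id for r in records]
    expr = ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        sample_ids=ids,
        values=rng.random((n_genes, len(ids))),
        unit="FPKM",
    )
    return Cohort(records=records, expression=expr)


def save_cohort(cohort: Cohort, truth: GroundTruth | None, out_dir) -> None:
    """Write expression TSV, clinical TSV and the ground-truth manifest."""
    from .cohort import write_clinical
    from .expression import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv")
    write_clinical(cohort.records, out / "clinical.tsv")
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(asdict(truth), indent=1))
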