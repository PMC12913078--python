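"""Seeded synthetic-data generators for every pipeline stage.

Three generators emulate the data a small single-arm treatment study of
chronic actinic dermatitis produces, so the whole analysis chain is testable
without any clinical data:

* :func:`generate_cohort` -- region-level clinical assessments for a cohort
  whose computed CAS-CAD totals follow a target baseline distribution
  (default 23.65 +/- 7.86) and decay multiplicatively over follow-up visits
  (default down to ~10% of baseline by week 12).  Scores are generated
  bottom-up: per-region severities and affected areas are solved by greedy
  constrained rounding so that running them through the scoring engine
  reproduces the intended totals, exercising the engine itself.
* :func:`generate_ratings` -- a subjects x raters table under the classical
  one-way reliability model (true score + rater error) with a prescribed
  population ICC.
* :func:`generate_npx` -- a samples x proteins log2-NPX panel (default 6
  subjects x 3 timepoints x 92 proteins) with per-subject-and-protein random
  intercepts, Gaussian assay noise, optional correlated blocks via shared
  latent factors, and planted per-group mean shifts for a configurable set
  of differentially expressed proteins.  The default plants -1.5 NPX
  down-shifts at the late timepoint for the eight inflammation markers
  EN-RAGE, MCP-3, MCP-4, IL-13, FGF-21, TNFRSF9, OSM and CCL4, with earlier
  partial shifts for OSM and TNFRSF9.

All noise is Gaussian -- a documented simplification -- and every generator
is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import GenerationError, ValidationError
from .icc import RatingsMatrix
from .npx import NpxMatrix
from .scoring import (
    DEFAULT_REGION_MAP,
    ClothingType,
    LesionSeverity,
    PatientAssessment,
    RegionAssessment,
    RegionMap,
    cascad_total,
    classify_response,
    correction_coefficient,
    percent_improvement,
    region_weight,
)

__all__ = [
    "CohortSpec",
    "NpxSpec",
    "DEFAULT_DEP_SPEC",
    "generate_cohort",
    "generate_ratings",
    "generate_npx",
]

# Area-score bin -> (low, high) percent range to sample a representative
# affected-area percent from.
_AREA_BIN_RANGES = {
    0: (0.0, 0.0),
    1: (1.0, 9.9),
    2: (10.0, 29.9),
    3: (30.0, 49.9),
    4: (50.0, 69.9),
    5: (70.0, 89.9),
    6: (90.0, 100.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Targets for the synthetic clinical cohort.

    ``retention`` maps each follow-up week to the expected fraction of the
    baseline CAS-CAD still present at that visit; the defaults trace a
    trajectory from 23.65 at baseline to ~2.4 (10.2% retention) at week 12,
    with ~35% retained at week 1 so most patients sit in the partial-response
    tier early on.  ``retention_sigma`` is the SD of a per-patient-visit
    lognormal multiplier on the retention (larger at the final visit via
    ``final_retention_sigma`` so a minority of patients land in the good
    rather than excellent tier).
    """

    n_patients: int = 16
    visit_weeks: tuple[int, ...] = (0, 1, 4, 12)
    baseline_mean: float = 23.65
    baseline_sd: float = 7.86
    retention: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.65, 4: 0.35, 12: 0.102}
    )
    retention_sigma: float = 0.15
    final_retention_sigma: float = 0.5
    type2_fraction: float = 0.25
    rater_noise_sd: float = 1.0
    seed: int = 0

    def validate(self, region_map: RegionMap) -> None:
        if self.n_patients < 1:
            raise GenerationError("n_patients must be >= 1")
        if self.visit_weeks[0] != 0:
            raise GenerationError("visit_weeks must start at baseline week 0")
        for week in self.visit_weeks[1:]:
            if week not in self.retention:
                raise GenerationError(f"no retention factor for week {week}")
        if any(not 0 < r <= 1 for r in self.retention.values()):
            raise GenerationError("retention factors must be in (0, 1]")
        if self.baseline_sd < 0 or self.rater_noise_sd < 0:
            raise GenerationError("standard deviations must be >= 0")
        max_total = _max_uncorrected_total(region_map, ClothingType.TYPE1)
        if self.baseline_mean + self.baseline_sd > 0.9 * max_total:
            raise GenerationError(
                f"baseline targets infeasible: mean + sd = "
                f"{self.baseline_mean + self.baseline_sd:.1f} exceeds 90% of the "
                f"maximum attainable score {max_total:.1f}"
            )


def _max_uncorrected_total(region_map: RegionMap, clothing: ClothingType) -> float:
    return sum(
        region_weight(r.exposure(clothing)) * r.bsa_proportion * 6 * 12
        for r in region_map
    )


def _compose_severity(total: int, rng: np.random.Generator) -> LesionSeverity:
    """Random composition of a 0-12 severity sum into four 0-3 sign grades."""
    grades = [0, 0, 0, 0]
    for _ in range(total):
        open_signs = [i for i in range(4) if grades[i] < 3]
        grades[open_signs[rng.integers(len(open_signs))]] += 1
    return LesionSeverity(*grades)


def _solve_regions(
    uncorrected_target: float,
    clothing: ClothingType,
    region_map: RegionMap,
    rng: np.random.Generator,
) -> list[RegionAssessment]:
    """Greedy constrained rounding of a target total onto region assessments.

    Regions are visited in random order; each gets a jittered proportional
    share of the remaining target, realised as the feasible (area score,
    severity sum) product closest to that share.
    """
    order = list(region_map)
    rng.shuffle(order)
    unit = {
        r.region_id: region_weight(r.exposure(clothing)) * r.bsa_proportion
        for r in region_map
    }
    remaining = max(uncorrected_target, 0.0)
    caps_left = sum(unit[r.region_id] * 72 for r in order)
    grid_a = np.arange(7)
    grid_s = np.arange(13)
    products = np.outer(grid_a, grid_s)  # 7 x 13 feasible area x severity grid
    assessments = []
    for i, region in enumerate(order):
        cap = unit[region.region_id] * 72
        if i == len(order) - 1:
            desired = remaining
        else:
            share = cap / caps_left
            desired = remaining * share * rng.uniform(0.6, 1.4)
            desired = min(desired, cap, remaining)
        target_product = desired / unit[region.region_id]
        err = np.abs(products - target_product)
        best = np.argwhere(err == err.min())
        a_score, sev_sum = best[rng.integers(len(best))]
        low, high = _AREA_BIN_RANGES[int(a_score)]
        # 4-dp rounding keeps the value inside its bin and lets CSV output
        # round-trip exactly.
        area = round(float(rng.uniform(low, high)), 4) if a_score else 0.0
        if sev_sum == 0:  # zero severity zeroes the term; keep area coherent
            area = 0.0
        assessments.append(
            RegionAssessment(
                region.region_id,
                _compose_severity(int(sev_sum), rng),
                area,
            )
        )
        remaining = max(remaining - unit[region.region_id] * a_score * sev_sum, 0.0)
        caps_left -= cap
    return assessments


def _patient_reported(total: float, rng: np.random.Generator) -> tuple[int, int, tuple]:
    """Plausible NRS / IGA / EQ-5D-3L responses tied to the severity total."""
    nrs = int(np.clip(round(10 * total / 30 + rng.normal(0, 1.0)), 0, 10))
    if total < 1:
        iga = 0
    elif total < 5:
        iga = 1
    elif total < 10:
        iga = 2
    elif total < 18:
        iga = 3
    else:
        iga = 4
    iga = int(np.clip(iga + rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1]), 0, 4))
    s = float(np.clip(total / 30.0, 0.0, 1.0))
    q2 = np.clip(0.15 + 0.7 * s, 0.0, 0.95)
    q3 = 0.25 * s
    eq5d = tuple(
        1 + int(rng.random() < q2) + int(rng.random() < q3) for _ in range(5)
    )
    eq5d = tuple(min(level, 3) for level in eq5d)
    return nrs, iga, eq5d


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> tuple[list[PatientAssessment], pd.DataFrame]:
    """Synthesize a longitudinal cohort of region-level assessments.

    Baseline targets are drawn by stratified inverse-CDF sampling of the
    target normal distribution, so even a 16-patient cohort closely matches
    the intended mean and SD while remaining fully random given the seed.
    Returns the assessment records plus a ground-truth table with each
    patient-visit's intended and achieved CAS-CAD total, two noisy rater
    readings of it, and the end-of-study response category.
    """
    spec.validate(region_map)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    # Stratified normal draws: one uniform per equal-probability stratum.
    strata = (np.arange(n) + rng.uniform(size=n)) / n
    baselines = sps.norm.ppf(rng.permutation(strata)) * spec.baseline_sd
    baselines += spec.baseline_mean
    max_total = _max_uncorrected_total(region_map, ClothingType.TYPE1)
    baselines = np.clip(baselines, 2.0, 0.9 * max_total)

    assessments: list[PatientAssessment] = []
    truth_rows = []
    final_week = spec.visit_weeks[-1]
    for i in range(n):
        patient_id = f"P{i + 1:02d}"
        clothing = (
            ClothingType.TYPE2
            if rng.random() < spec.type2_fraction
            else ClothingType.TYPE1
        )
        coeff = correction_coefficient(clothing, region_map)
        targets = {0: float(baselines[i])}
        for week in spec.visit_weeks[1:]:
            sigma = (
                spec.final_retention_sigma
                if week == final_week
                else spec.retention_sigma
            )
            factor = spec.retention[week] * float(np.exp(rng.normal(0.0, sigma)))
            targets[week] = targets[0] * min(factor, 1.0)
        achieved: dict[int, float] = {}
        for week in spec.visit_weeks:
            regions = _solve_regions(targets[week] / coeff, clothing, region_map, rng)
            total = None
            nrs, iga, eq5d = 0, 0, (1, 1, 1, 1, 1)
            # Patient-reported scores keyed to the achieved total.
            partial = PatientAssessment(
                patient_id, week, clothing, tuple(regions), 0, 0
            )
            total = cascad_total(partial, region_map).total
            nrs, iga, eq5d = _patient_reported(total, rng)
            assessments.append(
                PatientAssessment(
                    patient_id, week, clothing, tuple(regions), nrs, iga, eq5d
                )
            )
            achieved[week] = total
            truth_rows.append(
                {
                    "patient_id": patient_id,
                    "visit_week": week,
                    "clothing_type": clothing.value,
                    "target_score": targets[week],
                    "achieved_score": total,
                    "rater_a": total + rng.normal(0.0, spec.rater_noise_sd),
                    "rater_b": total + rng.normal(0.0, spec.rater_noise_sd),
                }
            )
        final_improvement = percent_improvement(
            max(achieved[0], 1e-9), achieved[final_week]
        )
        category = classify_response(final_improvement).category.value
        for row in truth_rows[-len(spec.visit_weeks):]:
            row["final_response"] = category
    return assessments, pd.DataFrame(truth_rows)


def generate_ratings(
    n_subjects: int,
    n_raters: int = 2,
    true_icc: float = 0.8,
    seed: int = 0,
    mean: float = 20.0,
    total_sd: float = 8.0,
) -> RatingsMatrix:
    """Ratings under the true-score-plus-error model with a set population ICC.

    Subject true scores ~ Normal(mean, icc * total_sd^2), rater errors ~
    Normal(0, (1 - icc) * total_sd^2), so the between-subject share of the
    variance equals ``true_icc`` exactly.
    """
    if not 0.0 <= true_icc < 1.0:
        raise ValidationError(f"true_icc must be in [0, 1), got {true_icc}")
    if n_subjects < 2 or n_raters < 2:
        raise ValidationError("need >= 2 subjects and >= 2 raters")
    rng = np.random.default_rng(seed)
    sigma_b = total_sd * np.sqrt(true_icc)
    sigma_e = total_sd * np.sqrt(1.0 - true_icc)
    true_scores = mean + rng.normal(0.0, sigma_b, size=n_subjects)
    values = true_scores[:, None] + rng.normal(
        0.0, sigma_e, size=(n_subjects, n_raters)
    )
    return RatingsMatrix(
        values,
        tuple(f"S{i + 1:03d}" for i in range(n_subjects)),
        tuple(f"R{j + 1}" for j in range(n_raters)),
    )


#: Default planted differential expression: the eight inflammation markers
#: down-shifted by -1.5 NPX at the late timepoint (group C), OSM and TNFRSF9
#: already partially down at the early timepoint (group B).
DEFAULT_DEP_SPEC: dict[str, dict[str, float]] = {
    "EN-RAGE": {"C": -1.5},
    "MCP-3": {"C": -1.5},
    "MCP-4": {"C": -1.5},
    "IL-13": {"C": -1.5},
    "FGF-21": {"C": -1.5},
    "TNFRSF9": {"B": -0.8, "C": -1.5},
    "OSM": {"B": -0.8, "C": -1.5},
    "CCL4": {"C": -1.5},
}


@dataclass(frozen=True)
class NpxSpec:
    """Parameters of the synthetic NPX panel.

    ``dep_spec`` maps protein -> {group: mean NPX shift}; unlisted
    protein-group pairs shift by 0 (group A is the unshifted reference).
    ``correlation_blocks`` lists (proteins, factor_sd) pairs; each block
    shares a per-sample standard-normal latent factor scaled by factor_sd.
    """

    n_subjects: int = 6
    n_proteins: int = 92
    groups: tuple[str, ...] = ("A", "B", "C")
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    subject_sd: float = 0.8
    noise_sd: float = 0.4
    dep_spec: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEP_SPEC.items()}
    )
    correlation_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    qc_fail_rate: float = 0.0
    seed: int = 0

    def protein_ids(self) -> list[str]:
        named = [p for p in self.dep_spec if not p.startswith("INF-")]
        if len(named) > self.n_proteins:
            raise GenerationError(
                f"dep_spec names {len(named)} proteins but panel has "
                f"{self.n_proteins}"
            )
        fillers = [f"INF-{i + 1:03d}" for i in range(self.n_proteins - len(named))]
        return named + fillers

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise GenerationError("n_subjects must be >= 2")
        if len(self.groups) < 2 or len(set(self.groups)) != len(self.groups):
            raise GenerationError("groups must be >= 2 distinct labels")
        for protein, shifts in self.dep_spec.items():
            for group, shift in shifts.items():
                if group not in self.groups:
                    raise GenerationError(
                        f"dep_spec for {protein!r} references unknown group {group!r}"
                    )
                if not np.isfinite(shift):
                    raise GenerationError(f"non-finite shift for {protein!r}")
        panel = set(self.protein_ids())
        for proteins, factor_sd in self.correlation_blocks:
            if factor_sd < 0:
                raise GenerationError("correlation block factor_sd must be >= 0")
            stray = sorted(set(proteins) - panel)
            if stray:
                raise GenerationError(f"correlation block proteins not on panel: {stray}")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise GenerationError("qc_fail_rate must be in [0, 1)")


def generate_npx(spec: NpxSpec = NpxSpec()) -> tuple[NpxMatrix, dict]:
    """Synthesize a paired NPX panel with known planted differential expression.

    NPX = per-protein baseline + per-(subject, protein) random intercept +
    planted group shift + shared latent block factors + Gaussian assay noise.
    Returns the matrix and a ground-truth dict with the planted shifts and,
    per ordered group contrast, the set of proteins whose means truly differ.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteins = spec.protein_ids()
    n_p, n_s = len(proteins), spec.n_subjects
    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_p)
    subject_fx = rng.normal(0.0, spec.subject_sd, size=(n_s, n_p))
    shift = np.zeros((len(spec.groups), n_p))
    p_index = {p: j for j, p in enumerate(proteins)}
    for protein, shifts in spec.dep_spec.items():
        for group, value in shifts.items():
            shift[spec.groups.index(group), p_index[protein]] = value

    rows, meta_rows = [], []
    for gi, group in enumerate(spec.groups):
        block_load = np.zeros((n_s, n_p))
        for proteins_in_block, factor_sd in spec.correlation_blocks:
            factor = rng.normal(0.0, 1.0, size=n_s)
            cols = [p_index[p] for p in proteins_in_block]
            block_load[:, cols] += factor_sd * factor[:, None]
        noise = rng.normal(0.0, spec.noise_sd, size=(n_s, n_p))
        values = baselines[None, :] + subject_fx + shift[gi][None, :]
        values = values + block_load + noise
        for si in range(n_s):
            subject = f"subj{si + 1}"
            sample = f"{subject}_{group}"
            rows.append(pd.Series(values[si], index=proteins, name=sample))
            meta_rows.append(
                {
                    "sample_id": sample,
                    "subject_id": subject,
                    "group": group,
                    "qc_pass": bool(rng.random() >= spec.qc_fail_rate),
                }
            )
    values_df = pd.DataFrame(rows)
    values_df.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = NpxMatrix(values_df, meta)

    planted: dict[tuple[str, str], set[str]] = {}
    for i, g1 in enumerate(spec.groups):
        for g2 in spec.groups[i + 1:]:
            i1, i2 = spec.groups.index(g1), spec.groups.index(g2)
            differing = {
                proteins[j] for j in range(n_p) if shift[i2, j] != shift[i1, j]
            }
            planted[(g1, g2)] = differing
    ground_truth = {
        "dep_spec": {k: dict(v) for k, v in spec.dep_spec.items()},
        "planted": planted,
    }
    return matrix, ground_truth
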