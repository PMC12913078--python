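"""Composite severity scoring for chronic actinic dermatitis (CAD).

The CAS-CAD (clinical active score of CAD) is a body-region-weighted composite:
for every region the four lesion-sign severities (erythema, papules/plaques,
scaling, lichenification; each 0-3) are summed, multiplied by an EASI-style
0-6 affected-area score, the region's share of body surface area (BSA), and a
photo-exposure weight (2 for sun-exposed skin, 1 otherwise).  Patients are
stratified by clothing habit -- Type 1 (long pants) versus Type 2 (shorts) --
which changes which regions count as exposed; Type 2 totals are rescaled by
the ratio of Type-1 to Type-2 exposed BSA so the two strata share a scale.

The module also carries the comparator instruments used alongside CAS-CAD in
longitudinal follow-up: the standard adult EASI, an additive EQ-5D-3L tariff
evaluator (tariff coefficients are user-supplied), treatment-response tiers
defined on fractional score improvement, and two-rater adjudication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import yaml

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ClothingType",
    "Exposure",
    "ResponseCategory",
    "LesionSeverity",
    "BodyRegion",
    "RegionMap",
    "RegionAssessment",
    "PatientAssessment",
    "CascadResult",
    "ResponseResult",
    "Eq5dTariff",
    "DEFAULT_REGION_MAP",
    "region_weight",
    "area_score",
    "region_contribution",
    "correction_coefficient",
    "cascad_total",
    "percent_improvement",
    "classify_response",
    "adjudicate_ratings",
    "easi_total",
    "eq5d_utility",
]


class ClothingType(str, Enum):
    """Clothing stratum: Type 1 wears long pants, Type 2 wears shorts."""

    TYPE1 = "Type1"
    TYPE2 = "Type2"


class Exposure(str, Enum):
    EXPOSED = "exposed"
    NON_EXPOSED = "non_exposed"


class ResponseCategory(str, Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    PARTIAL = "partial"
    NO_RESPONSE = "no_response"


# Photo-exposure weights: lesions on sun-exposed skin count double.
_EXPOSURE_WEIGHTS = {Exposure.EXPOSED: 2, Exposure.NON_EXPOSED: 1}

# EASI-convention area bins: upper edges of the 0-6 affected-area score.
# 0 only for no involvement; (0,10)->1, [10,30)->2, [30,50)->3, [50,70)->4,
# [70,90)->5, [90,100]->6.
_AREA_BIN_EDGES = (10.0, 30.0, 50.0, 70.0, 90.0)


@dataclass(frozen=True)
class LesionSeverity:
    """Per-region severity of the four lesion signs, each graded 0-3."""

    erythema: int
    papules_plaques: int
    scaling: int
    lichenification: int

    def __post_init__(self) -> None:
        for name in ("erythema", "papules_plaques", "scaling", "lichenification"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            if not 0 <= value <= 3:
                raise ValidationError(f"{name} must be in [0, 3], got {value}")

    @property
    def severity_sum(self) -> int:
        """Sum of the four sign grades, in [0, 12]."""
        return self.erythema + self.papules_plaques + self.scaling + self.lichenification


@dataclass(frozen=True)
class BodyRegion:
    """One region of the body map with its BSA share and exposure flags."""

    region_id: str
    name: str
    bsa_proportion: float
    exposed_type1: bool
    exposed_type2: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.bsa_proportion <= 1.0:
            raise ValidationError(
                f"bsa_proportion for {self.region_id!r} must be in (0, 1], "
                f"got {self.bsa_proportion}"
            )

    def exposure(self, clothing_type: ClothingType) -> Exposure:
        exposed = (
            self.exposed_type1
            if clothing_type is ClothingType.TYPE1
            else self.exposed_type2
        )
        return Exposure.EXPOSED if exposed else Exposure.NON_EXPOSED


@dataclass(frozen=True)
class RegionMap:
    """An ordered body-region partition whose BSA proportions sum to one.

    Editable: ship your own partition via :meth:`from_yaml` to replace the
    default eight-region map.
    """

    regions: tuple[BodyRegion, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate region ids: {sorted(ids)}")
        total = sum(r.bsa_proportion for r in self.regions)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"bsa_proportions must sum to 1 (got {total:.12g})"
            )

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def get(self, region_id: str) -> BodyRegion:
        for region in self.regions:
            if region.region_id == region_id:
                return region
        raise ValidationError(f"unknown region_id {region_id!r}")

    def exposed_bsa(self, clothing_type: ClothingType) -> float:
        return sum(
            r.bsa_proportion
            for r in self.regions
            if r.exposure(clothing_type) is Exposure.EXPOSED
        )

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, list):
            raise ValidationError("region map YAML must be a list of region entries")
        regions = []
        for i, entry in enumerate(raw):
            try:
                regions.append(
                    BodyRegion(
                        region_id=str(entry["region_id"]),
                        name=str(entry.get("name", entry["region_id"])),
                        bsa_proportion=float(entry["bsa_proportion"]),
                        exposed_type1=bool(entry["exposed_type1"]),
                        exposed_type2=bool(entry["exposed_type2"]),
                    )
                )
            except KeyError as exc:
                raise ValidationError(f"region entry {i}: missing key {exc}") from exc
        return cls(tuple(regions))

    def to_yaml(self, path) -> None:
        entries = [
            {
                "region_id": r.region_id,
                "name": r.name,
                "bsa_proportion": r.bsa_proportion,
                "exposed_type1": r.exposed_type1,
                "exposed_type2": r.exposed_type2,
            }
            for r in self.regions
        ]
        with open(path, "w") as handle:
            yaml.safe_dump(entries, handle, sort_keys=False)


# Default eight-region partition with rule-of-nines-style BSA shares.
# Head/neck and the dorsal hands + forearms are sun-exposed regardless of
# clothing; the lower legs become exposed only for Type 2 (shorts).  The
# partition is a configurable stand-in: substitute your own map where a
# study protocol prescribes one.
DEFAULT_REGION_MAP = RegionMap(
    (
        BodyRegion("head_neck", "Head and neck", 0.09, True, True),
        BodyRegion("anterior_trunk", "Anterior trunk", 0.18, False, False),
        BodyRegion("posterior_trunk", "Posterior trunk", 0.18, False, False),
        BodyRegion("hands_forearms", "Dorsal hands and forearms", 0.09, True, True),
        BodyRegion("upper_arms", "Upper arms", 0.09, False, False),
        BodyRegion("thighs", "Thighs", 0.18, False, False),
        BodyRegion("lower_legs", "Lower legs", 0.13, False, True),
        BodyRegion("feet", "Feet", 0.06, False, False),
    )
)

# Mapping from the default regions onto the four standard adult EASI regions
# and the EASI region multipliers.
_EASI_REGION_OF = {
    "head_neck": "head_neck",
    "anterior_trunk": "trunk",
    "posterior_trunk": "trunk",
    "hands_forearms": "upper_limbs",
    "upper_arms": "upper_limbs",
    "thighs": "lower_limbs",
    "lower_legs": "lower_limbs",
    "feet": "lower_limbs",
}
_EASI_MULTIPLIERS = {
    "head_neck": 0.1,
    "trunk": 0.3,
    "upper_limbs": 0.2,
    "lower_limbs": 0.4,
}


@dataclass(frozen=True)
class RegionAssessment:
    region_id: str
    severity: LesionSeverity
    area_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_percent <= 100.0:
            raise ValidationError(
                f"area_percent must be in [0, 100], got {self.area_percent}"
            )


@dataclass(frozen=True)
class PatientAssessment:
    """One visit's complete clinical record for one patient."""

    patient_id: str
    visit_week: int
    clothing_type: ClothingType
    regions: tuple[RegionAssessment, ...]
    nrs: int
    iga: int
    eq5d_responses: tuple[int, int, int, int, int] | None = None
    eq5d_utility: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.nrs <= 10:
            raise ValidationError(f"nrs must be in [0, 10], got {self.nrs}")
        if not 0 <= self.iga <= 4:
            raise ValidationError(f"iga must be in [0, 4], got {self.iga}")
        if self.eq5d_responses is not None:
            if len(self.eq5d_responses) != 5 or any(
                level not in (1, 2, 3) for level in self.eq5d_responses
            ):
                raise ValidationError(
                    f"eq5d_responses must be 5 levels in {{1,2,3}}, "
                    f"got {self.eq5d_responses}"
                )

    def region_assessment(self, region_id: str) -> RegionAssessment:
        for ra in self.regions:
            if ra.region_id == region_id:
                return ra
        raise ValidationError(
            f"patient {self.patient_id!r} week {self.visit_week}: "
            f"no assessment for region {region_id!r}"
        )


@dataclass(frozen=True)
class CascadResult:
    total: float
    region_contributions: Mapping[str, float]
    correction_coefficient: float


@dataclass(frozen=True)
class ResponseResult:
    category: ResponseCategory
    improvement: float


def region_weight(exposure: Exposure | str) -> int:
    """Photo-exposure weight of a region: 2 if sun-exposed, 1 otherwise."""
    try:
        exposure = Exposure(exposure)
    except ValueError:
        raise ValidationError(
            f"unknown exposure {exposure!r}; expected one of "
            f"{[e.value for e in Exposure]}"
        ) from None
    return _EXPOSURE_WEIGHTS[exposure]


def area_score(area_percent: float) -> int:
    """EASI-convention 0-6 score for the percent of a region affected.

    0 for no involvement; then (0,10)->1, [10,30)->2, [30,50)->3,
    [50,70)->4, [70,90)->5, [90,100]->6.
    """
    if not 0.0 <= area_percent <= 100.0:
        raise ValidationError(f"area_percent must be in [0, 100], got {area_percent}")
    if area_percent == 0.0:
        return 0
    score = 1
    for edge in _AREA_BIN_EDGES:
        if area_percent >= edge:
            score += 1
    return score


def region_contribution(
    severity: LesionSeverity,
    area_percent: float,
    bsa_proportion: float,
    weight: int,
) -> float:
    """One region's term: weight x BSA share x area score x severity sum."""
    return weight * bsa_proportion * area_score(area_percent) * severity.severity_sum


def correction_coefficient(
    clothing_type: ClothingType | str, region_map: RegionMap = DEFAULT_REGION_MAP
) -> float:
    """Type-2 rescaling factor: Type-1 exposed BSA over Type-2 exposed BSA.

    Type 1 is the reference stratum and gets 1.0.  Because shorts expose more
    skin, a Type-2 patient accrues more double-weighted BSA for the same
    lesions; the ratio pulls Type-2 totals back onto the Type-1 scale.
    """
    clothing_type = ClothingType(clothing_type)
    if clothing_type is ClothingType.TYPE1:
        return 1.0
    type2_exposed = region_map.exposed_bsa(ClothingType.TYPE2)
    if type2_exposed == 0.0:
        raise ConfigurationError(
            "region map has zero Type-2 exposed BSA; correction undefined"
        )
    return region_map.exposed_bsa(ClothingType.TYPE1) / type2_exposed


def cascad_total(
    assessment: PatientAssessment, region_map: RegionMap = DEFAULT_REGION_MAP
) -> CascadResult:
    """Total CAS-CAD score for one visit, with per-region contributions.

    total = correction_coefficient x sum over regions of
    (severity sum x area score x BSA proportion x exposure weight).
    """
    assessed = {ra.region_id for ra in assessment.regions}
    missing = [rid for rid in region_map.region_ids() if rid not in assessed]
    if missing:
        raise ValidationError(
            f"patient {assessment.patient_id!r} week {assessment.visit_week}: "
            f"missing regions {missing}"
        )
    contributions: dict[str, float] = {}
    for region in region_map:
        ra = assessment.region_assessment(region.region_id)
        weight = region_weight(region.exposure(assessment.clothing_type))
        contributions[region.region_id] = region_contribution(
            ra.severity, ra.area_percent, region.bsa_proportion, weight
        )
    coeff = correction_coefficient(assessment.clothing_type, region_map)
    total = coeff * sum(contributions.values())
    return CascadResult(total, contributions, coeff)


def percent_improvement(baseline: float, followup: float) -> float:
    """Fractional decrease from baseline; negative if the score worsened."""
    if not baseline > 0:
        raise ValidationError(f"baseline must be > 0, got {baseline}")
    if followup < 0:
        raise ValidationError(f"followup must be >= 0, got {followup}")
    return (baseline - followup) / baseline


def classify_response(improvement: float) -> ResponseResult:
    """Treatment-response tier for a fractional improvement.

    excellent: > 75% improvement; good: 50-75% (both endpoints included);
    partial: 25% (included) to 50% (excluded); no response otherwise,
    including any worsening.
    """
    if not math.isfinite(improvement):
        raise ValidationError(f"improvement must be finite, got {improvement}")
    if improvement > 0.75:
        category = ResponseCategory.EXCELLENT
    elif improvement >= 0.50:
        category = ResponseCategory.GOOD
    elif improvement >= 0.25:
        category = ResponseCategory.PARTIAL
    else:
        category = ResponseCategory.NO_RESPONSE
    return ResponseResult(category, improvement)


def adjudicate_ratings(
    score_a: float, score_b: float, threshold: float = 5.0
) -> tuple[float, bool]:
    """Average two independent raters' scores; flag disagreements > threshold.

    Returns (mean, escalate).  An escalated pair is referred to a third,
    more experienced rater; the threshold is applied per instrument scale.
    """
    mean = (score_a + score_b) / 2.0
    escalate = abs(score_a - score_b) > threshold
    return mean, escalate


def easi_total(
    assessment: PatientAssessment, region_map: RegionMap = DEFAULT_REGION_MAP
) -> float:
    """Standard adult EASI (0-72) computed from the region-level record.

    Body-map regions are pooled onto the four EASI regions (head/neck, trunk,
    upper limbs, lower limbs; multipliers 0.1/0.3/0.2/0.4) by BSA-weighted
    averaging of the four-sign severity sum and of the affected-area percent,
    the latter then re-binned to the 0-6 area score.
    """
    unmappable = [
        r.region_id for r in region_map if r.region_id not in _EASI_REGION_OF
    ]
    if unmappable:
        raise ValidationError(
            f"regions not mappable onto the standard EASI regions: {unmappable}"
        )
    pooled: dict[str, list[tuple[float, float, float]]] = {}
    for region in region_map:
        ra = assessment.region_assessment(region.region_id)
        pooled.setdefault(_EASI_REGION_OF[region.region_id], []).append(
            (region.bsa_proportion, ra.severity.severity_sum, ra.area_percent)
        )
    total = 0.0
    for easi_region, members in pooled.items():
        bsa = sum(m[0] for m in members)
        severity = sum(m[0] * m[1] for m in members) / bsa
        area = sum(m[0] * m[2] for m in members) / bsa
        total += _EASI_MULTIPLIERS[easi_region] * severity * area_score(area)
    return total


@dataclass(frozen=True)
class Eq5dTariff:
    """Additive time-trade-off tariff for EQ-5D-3L utilities.

    utility = constant - sum of per-dimension level decrements - an optional
    extra penalty if any dimension is at level 3.  The full-health state
    (1,1,1,1,1) evaluates to ``constant``, the tariff's anchor.  No national
    coefficient set is shipped; supply the published tariff for your
    population (e.g. via :meth:`from_yaml`).
    """

    constant: float
    decrements: Mapping[str, Mapping[int, float]]  # dim -> {2: d2, 3: d3}
    n3_penalty: float = 0.0

    DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain", "anxiety")

    def __post_init__(self) -> None:
        missing = [d for d in self.DIMENSIONS if d not in self.decrements]
        if missing:
            raise ConfigurationError(f"tariff missing dimensions: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "Eq5dTariff":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        decrements = {
            dim: {int(level): float(dec) for level, dec in levels.items()}
            for dim, levels in raw["decrements"].items()
        }
        return cls(
            constant=float(raw["constant"]),
            decrements=decrements,
            n3_penalty=float(raw.get("n3_penalty", 0.0)),
        )


def eq5d_utility(responses: Sequence[int], tariff: Eq5dTariff | None) -> float:
    """EQ-5D-3L utility under a supplied additive tariff."""
    if tariff is None:
        raise ConfigurationError(
            "no EQ-5D-3L tariff supplied; provide the published tariff for "
            "your population (coefficients are not shipped)"
        )
    if len(responses) != 5 or any(level not in (1, 2, 3) for level in responses):
        raise ValidationError(
            f"EQ-5D-3L responses must be 5 levels in {{1,2,3}}, got {tuple(responses)}"
        )
    utility = tariff.constant
    for dim, level in zip(Eq5dTariff.DIMENSIONS, responses):
        if level > 1:
            try:
                utility -= tariff.decrements[dim][level]
            except KeyError:
                raise ConfigurationError(
                    f"tariff has no decrement for {dim} level {level}"
                ) from None
    if any(level == 3 for level in responses):
        utility -= tariff.n3_penalty
    return utility
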