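"""Scoring engine: CAS-CAD, comparators, response tiers, adjudication."""

import dataclasses

import numpy as np
import pytest

from cascadkit import (
    ConfigurationError,
    ValidationError,
    adjudicate_ratings,
    area_score,
    cascad_total,
    classify_response,
    correction_coefficient,
    easi_total,
    eq5d_utility,
    percent_improvement,
    region_contribution,
    region_weight,
)
from cascadkit.scoring import (
    DEFAULT_REGION_MAP,
    BodyRegion,
    ClothingType,
    Eq5dTariff,
    LesionSeverity,
    RegionAssessment,
    RegionMap,
    ResponseCategory,
)
from conftest import make_assessment


class TestRegionWeight:
    @pytest.mark.parametrize("exposure,expected", [("exposed", 2), ("non_exposed", 1)])
    def test_weights(self, exposure, expected):
        assert region_weight(exposure) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="sun"):
            region_weight("sun")


class TestAreaScore:
    @pytest.mark.parametrize(
        "percent,expected",
        [(0, 0), (0.1, 1), (9.9, 1), (10, 2), (15, 2), (29.9, 2), (30, 3),
         (49.9, 3), (50, 4), (69.9, 4), (70, 5), (89.9, 5), (90, 6), (100, 6)],
    )
    def test_bin_boundaries(self, percent, expected):
        assert area_score(percent) == expected

    def test_matches_bin_lookup_oracle_on_all_integer_percents(self):
        # Independent oracle: explicit half-open bin table lookup.
        bins = [(0, 0, 0), (1, 9, 1), (10, 29, 2), (30, 49, 3),
                (50, 69, 4), (70, 89, 5), (90, 100, 6)]

        def oracle(p):
            return next(s for lo, hi, s in bins if lo <= p <= hi)

        for percent in range(101):
            assert area_score(percent) == oracle(percent)

    @pytest.mark.parametrize("percent", [-1, 100.5])
    def test_out_of_range_rejected(self, percent):
        with pytest.raises(ValidationError):
            area_score(percent)


class TestRegionContribution:
    def test_zero_severity_annihilates(self):
        zero = LesionSeverity(0, 0, 0, 0)
        assert region_contribution(zero, 80.0, 0.2, 2) == 0.0

    def test_direct_arithmetic(self):
        sev = LesionSeverity(3, 3, 3, 3)
        assert region_contribution(sev, 95.0, 0.10, 2) == pytest.approx(14.4)
        assert region_contribution(sev, 95.0, 0.10, 1) == pytest.approx(7.2)


def _map(entries):
    return RegionMap(tuple(BodyRegion(*e) for e in entries))


class TestCorrectionCoefficient:
    def test_type1_is_reference(self):
        assert correction_coefficient(ClothingType.TYPE1) == 1.0

    def test_ratio_of_exposed_bsa(self):
        rmap = _map(
            [
                ("a", "a", 0.20, True, True),
                ("b", "b", 0.20, False, True),
                ("c", "c", 0.60, False, False),
            ]
        )
        # Type1-exposed 0.20 over Type2-exposed 0.40
        assert correction_coefficient(ClothingType.TYPE2, rmap) == pytest.approx(0.5)

    def test_identical_exposure_gives_unity(self):
        rmap = _map([("a", "a", 0.5, True, True), ("b", "b", 0.5, False, False)])
        assert correction_coefficient(ClothingType.TYPE2, rmap) == pytest.approx(1.0)

    def test_no_type2_exposure_is_configuration_error(self):
        rmap = _map([("a", "a", 0.5, True, False), ("b", "b", 0.5, False, False)])
        with pytest.raises(ConfigurationError):
            correction_coefficient(ClothingType.TYPE2, rmap)


class TestCascadTotal:
    def test_all_zero_severity_scores_zero(self):
        result = cascad_total(make_assessment(severity=(0, 0, 0, 0)))
        assert result.total == 0.0

    def test_single_region_matches_contribution(self):
        sev = LesionSeverity(3, 3, 3, 3)
        regions = tuple(
            RegionAssessment(
                r.region_id,
                sev if r.region_id == "head_neck" else LesionSeverity(0, 0, 0, 0),
                95.0 if r.region_id == "head_neck" else 0.0,
            )
            for r in DEFAULT_REGION_MAP
        )
        a = dataclasses.replace(make_assessment(), regions=regions)
        # head/neck: weight 2, bsa 0.09 -> 2 * 0.09 * 6 * 12 = 12.96
        assert cascad_total(a).total == pytest.approx(12.96)
        assert cascad_total(a).correction_coefficient == 1.0

    def test_total_is_coefficient_times_contribution_sum(self):
        a = make_assessment(clothing=ClothingType.TYPE2, severity=(2, 1, 0, 3))
        res = cascad_total(a)
        assert res.total == pytest.approx(
            res.correction_coefficient * sum(res.region_contributions.values())
        )

    def test_missing_region_listed(self):
        a = make_assessment()
        a = dataclasses.replace(a, regions=a.regions[:-1])
        with pytest.raises(ValidationError, match="feet"):
            cascad_total(a)

    def test_monotone_in_severity_and_area(self):
        """Raising any one severity grade or area never lowers the total."""
        base = make_assessment(severity=(1, 2, 0, 3), area_percent=35.0)
        total = cascad_total(base).total
        for i, ra in enumerate(base.regions):
            for sign in ("erythema", "papules_plaques", "scaling", "lichenification"):
                grade = getattr(ra.severity, sign)
                if grade == 3:
                    continue
                bumped = dataclasses.replace(
                    ra, severity=dataclasses.replace(ra.severity, **{sign: grade + 1})
                )
                regions = base.regions[:i] + (bumped,) + base.regions[i + 1:]
                assert cascad_total(
                    dataclasses.replace(base, regions=regions)
                ).total >= total
            wider = dataclasses.replace(ra, area_percent=min(ra.area_percent + 20, 100))
            regions = base.regions[:i] + (wider,) + base.regions[i + 1:]
            assert cascad_total(dataclasses.replace(base, regions=regions)).total >= total

    def test_weight_homogeneity(self):
        """Doubling every region weight doubles the uncorrected total."""
        all_exposed = RegionMap(
            tuple(
                dataclasses.replace(r, exposed_type1=True)
                for r in DEFAULT_REGION_MAP
            )
        )
        none_exposed = RegionMap(
            tuple(
                dataclasses.replace(r, exposed_type1=False, exposed_type2=True)
                for r in DEFAULT_REGION_MAP
            )
        )
        a = make_assessment(severity=(2, 1, 3, 0), area_percent=55.0)
        heavy = cascad_total(a, all_exposed).total  # every weight 2
        light = cascad_total(a, none_exposed).total  # every weight 1
        assert heavy == pytest.approx(2 * light)

    def test_type_strata_agree_when_exposure_maps_coincide(self):
        rmap = RegionMap(
            tuple(
                dataclasses.replace(r, exposed_type2=r.exposed_type1)
                for r in DEFAULT_REGION_MAP
            )
        )
        t1 = cascad_total(make_assessment(clothing=ClothingType.TYPE1), rmap)
        t2 = cascad_total(make_assessment(clothing=ClothingType.TYPE2), rmap)
        assert t1.total == pytest.approx(t2.total)


class TestResponseClassification:
    def test_improvement_arithmetic(self):
        assert percent_improvement(21.610, 1.200) == pytest.approx(0.9445, abs=1e-4)
        assert percent_improvement(10.0, 10.0) == 0.0
        assert percent_improvement(10.0, 0.0) == 1.0
        with pytest.raises(ValidationError):
            percent_improvement(0.0, 1.0)

    @pytest.mark.parametrize(
        "improvement,category",
        [
            (0.9445, ResponseCategory.EXCELLENT),
            ((17.230 - 4.330) / 17.230, ResponseCategory.GOOD),
            (0.75, ResponseCategory.GOOD),
            (0.50, ResponseCategory.GOOD),
            (0.49, ResponseCategory.PARTIAL),
            (0.25, ResponseCategory.PARTIAL),
            (0.10, ResponseCategory.NO_RESPONSE),
            (-0.40, ResponseCategory.NO_RESPONSE),
        ],
    )
    def test_tier_boundaries(self, improvement, category):
        assert classify_response(improvement).category is category


class TestAdjudication:
    def test_mean_and_escalation(self):
        assert adjudicate_ratings(20, 22) == (21.0, False)
        assert adjudicate_ratings(20, 26)[1] is True
        assert adjudicate_ratings(20, 25)[1] is False  # exactly 5 points: no
        assert adjudicate_ratings(13.5, 13.5) == (13.5, False)


class TestEasi:
    def test_zero_and_maximum(self):
        assert easi_total(make_assessment(severity=(0, 0, 0, 0))) == 0.0
        assert easi_total(
            make_assessment(severity=(3, 3, 3, 3), area_percent=100.0)
        ) == pytest.approx(72.0)

    def test_half_severity_proportional(self):
        full = easi_total(make_assessment(severity=(3, 3, 3, 3), area_percent=100.0))
        half = easi_total(make_assessment(severity=(3, 3, 0, 0), area_percent=100.0))
        assert half == pytest.approx(full / 2)


class TestEq5d:
    def _toy_tariff(self):
        decrements = {
            dim: {2: 0.1, 3: 0.3} for dim in Eq5dTariff.DIMENSIONS
        }
        return Eq5dTariff(constant=1.0, decrements=decrements)

    def test_full_health_is_anchor(self):
        assert eq5d_utility((1, 1, 1, 1, 1), self._toy_tariff()) == pytest.approx(1.0)

    def test_additive_lookup(self):
        assert eq5d_utility((2, 1, 1, 1, 1), self._toy_tariff()) == pytest.approx(0.9)

    def test_missing_tariff_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            eq5d_utility((1, 1, 1, 1, 1), None)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            eq5d_utility((1, 1, 4, 1, 1), self._toy_tariff())


class TestRegionMapValidation:
    def test_bsa_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            _map([("a", "a", 0.5, True, True), ("b", "b", 0.4, False, False)])

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "map.yaml"
        DEFAULT_REGION_MAP.to_yaml(path)
        assert RegionMap.from_yaml(path) == DEFAULT_REGION_MAP

    def test_severity_grades_validated(self):
        with pytest.raises(ValidationError):
            LesionSeverity(4, 0, 0, 0)
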