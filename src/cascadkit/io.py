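"""File I/O, validation and the end-to-end analysis orchestrator.

All tabular interchange is plain CSV/TSV with documented schemas:

* ``assessments.csv`` (long): patient_id, visit_week, clothing_type,
  region_id, erythema, papules_plaques, scaling, lichenification,
  area_percent, nrs, iga[, eq5d_1..eq5d_5]
* ``scores.csv`` (wide): patient_id, then one ``<score>_w<week>`` column per
  score type and visit week
* ``ratings.csv``: subject_id, rater_id, score
* ``npx_long.csv``: sample_id, subject_id, group, protein_id, npx, qc_pass
* ``edges.tsv``: protein_a, protein_b;  ``annotations.tsv``: term_id, protein_id

Reports are CSV tables plus one JSON sidecar of metadata and decisions, so
runs stay diffable.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import icc as icc_mod
from . import npx as npx_mod
from . import stats as stats_mod
from .exceptions import ValidationError
from .scoring import (
    DEFAULT_REGION_MAP,
    ClothingType,
    LesionSeverity,
    PatientAssessment,
    RegionAssessment,
    RegionMap,
    adjudicate_ratings,
    cascad_total,
    easi_total,
)

__all__ = [
    "RunConfig",
    "read_assessments",
    "write_assessments",
    "read_scores",
    "write_scores",
    "read_ratings",
    "read_npx",
    "read_edges",
    "read_annotations",
    "score_assessments",
    "run_full_analysis",
]

_ASSESSMENT_COLUMNS = [
    "patient_id",
    "visit_week",
    "clothing_type",
    "region_id",
    "erythema",
    "papules_plaques",
    "scaling",
    "lichenification",
    "area_percent",
    "nrs",
    "iga",
]
_EQ5D_COLUMNS = [f"eq5d_{i}" for i in range(1, 6)]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def read_assessments(path) -> list[PatientAssessment]:
    """Read and validate a long-format clinical assessment CSV."""
    frame = pd.read_csv(path)
    _require_columns(frame, _ASSESSMENT_COLUMNS, str(path))
    has_eq5d = all(c in frame.columns for c in _EQ5D_COLUMNS)
    key = frame[["patient_id", "visit_week", "region_id"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].to_records(index=False).tolist()
        raise ValidationError(f"{path}: duplicate (patient, week, region) rows: {dupes}")
    assessments = []
    for (patient_id, week), visit in frame.groupby(
        ["patient_id", "visit_week"], sort=True
    ):
        regions = []
        for row_no, row in visit.iterrows():
            try:
                regions.append(
                    RegionAssessment(
                        str(row["region_id"]),
                        LesionSeverity(
                            int(row["erythema"]),
                            int(row["papules_plaques"]),
                            int(row["scaling"]),
                            int(row["lichenification"]),
                        ),
                        float(row["area_percent"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {row_no + 2}: {exc}") from exc
        first = visit.iloc[0]
        eq5d = None
        if has_eq5d and not first[_EQ5D_COLUMNS].isna().any():
            eq5d = tuple(int(first[c]) for c in _EQ5D_COLUMNS)
        try:
            clothing = ClothingType(str(first["clothing_type"]))
        except ValueError:
            raise ValidationError(
                f"{path}: unknown clothing_type {first['clothing_type']!r} "
                f"for patient {patient_id!r}"
            ) from None
        assessments.append(
            PatientAssessment(
                str(patient_id),
                int(week),
                clothing,
                tuple(regions),
                int(first["nrs"]),
                int(first["iga"]),
                eq5d,
            )
        )
    return assessments


def write_assessments(assessments: Sequence[PatientAssessment], path) -> None:
    rows = []
    for a in assessments:
        for ra in a.regions:
            row = {
                "patient_id": a.patient_id,
                "visit_week": a.visit_week,
                "clothing_type": a.clothing_type.value,
                "region_id": ra.region_id,
                "erythema": ra.severity.erythema,
                "papules_plaques": ra.severity.papules_plaques,
                "scaling": ra.severity.scaling,
                "lichenification": ra.severity.lichenification,
                "area_percent": ra.area_percent,
                "nrs": a.nrs,
                "iga": a.iga,
            }
            if a.eq5d_responses is not None:
                row.update(dict(zip(_EQ5D_COLUMNS, a.eq5d_responses)))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_SCORE_COLUMN = re.compile(r"^(?P<score>.+)_w(?P<week>\d+)$")


def read_scores(path) -> dict[str, stats_mod.LongitudinalScores]:
    """Read a wide per-patient score CSV into per-score longitudinal tables."""
    frame = pd.read_csv(path)
    _require_columns(frame, ["patient_id"], str(path))
    if frame["patient_id"].duplicated().any():
        dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"{path}: duplicate patient ids {dupes}")
    frame = frame.set_index("patient_id")
    per_score: dict[str, dict[int, pd.Series]] = {}
    for column in frame.columns:
        match = _SCORE_COLUMN.match(column)
        if match is None:
            raise ValidationError(
                f"{path}: column {column!r} does not match '<score>_w<week>'"
            )
        per_score.setdefault(match["score"], {})[int(match["week"])] = frame[column]
    return {
        score: stats_mod.LongitudinalScores(score, pd.DataFrame(weeks))
        for score, weeks in per_score.items()
    }


def write_scores(scores: Mapping[str, stats_mod.LongitudinalScores], path) -> None:
    pieces = []
    for name, table in scores.items():
        wide = table.matrix.copy()
        wide.columns = [f"{name}_w{week}" for week in wide.columns]
        pieces.append(wide)
    combined = pd.concat(pieces, axis=1)
    combined.index.name = "patient_id"
    combined.to_csv(path)


def read_ratings(path) -> icc_mod.RatingsMatrix:
    """Read a long subject/rater/score CSV into a complete ratings matrix."""
    frame = pd.read_csv(path)
    _require_columns(frame, ["subject_id", "rater_id", "score"], str(path))
    key = frame[["subject_id", "rater_id"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].to_records(index=False).tolist()
        raise ValidationError(f"{path}: duplicate (subject, rater) rows: {dupes}")
    wide = frame.pivot(index="subject_id", columns="rater_id", values="score")
    if wide.isna().any().any():
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValidationError(f"{path}: incomplete subjects {incomplete}")
    return icc_mod.RatingsMatrix.from_frame(wide)


def read_npx(path) -> npx_mod.NpxMatrix:
    frame = pd.read_csv(path)
    return npx_mod.NpxMatrix.from_long(frame)


def read_edges(path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["protein_a", "protein_b"], str(path))
    return [
        (str(a), str(b)) for a, b in zip(frame["protein_a"], frame["protein_b"])
    ]


def read_annotations(path) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["term_id", "protein_id"], str(path))
    return {
        str(term): set(map(str, members))
        for term, members in frame.groupby("term_id")["protein_id"]
    }


def score_assessments(
    assessments: Sequence[PatientAssessment],
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> dict[str, stats_mod.LongitudinalScores]:
    """Run the scoring engine over every visit; return per-score tables."""
    records: dict[str, dict[str, dict[int, float]]] = {
        "CAS-CAD": {},
        "EASI": {},
        "NRS": {},
        "IGA": {},
    }
    for a in assessments:
        records["CAS-CAD"].setdefault(a.patient_id, {})[a.visit_week] = cascad_total(
            a, region_map
        ).total
        records["EASI"].setdefault(a.patient_id, {})[a.visit_week] = easi_total(
            a, region_map
        )
        records["NRS"].setdefault(a.patient_id, {})[a.visit_week] = float(a.nrs)
        records["IGA"].setdefault(a.patient_id, {})[a.visit_week] = float(a.iga)
    return {
        name: stats_mod.LongitudinalScores(
            name, pd.DataFrame.from_dict(table, orient="index").sort_index()
        )
        for name, table in records.items()
    }


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    out_dir: Path
    assessments: Path | None = None
    scores: Path | None = None
    region_map: Path | None = None
    ratings: Path | None = None
    npx: Path | None = None
    edges: Path | None = None
    annotations: Path | None = None
    score_name: str = "CAS-CAD"
    baseline_week: int = 0
    followup_weeks: tuple[int, ...] = (1, 4, 12)
    alpha: float = 0.05
    de_alpha: float = 0.05
    contrasts: tuple[tuple[str, str], ...] = (("A", "B"), ("A", "C"), ("B", "C"))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.de_alpha < 1.0:
            raise ValidationError("alpha levels must be in (0, 1)")
        if self.assessments is None and self.scores is None:
            raise ValidationError("config needs an assessments or scores input")
        for name in ("assessments", "scores", "region_map", "ratings", "npx",
                     "edges", "annotations"):
            value = getattr(self, name)
            if value is not None:
                value = Path(value)
                setattr(self, name, value)
                if not value.exists():
                    raise ValidationError(f"{name} path does not exist: {value}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "followup_weeks" in raw:
            raw["followup_weeks"] = tuple(raw["followup_weeks"])
        return cls(**raw)


def _paired_report(
    scores: stats_mod.LongitudinalScores, baseline_week: int, week: int
) -> dict:
    baseline = scores.week(baseline_week).to_numpy(dtype=float)
    followup = scores.week(week).to_numpy(dtype=float)
    diffs = baseline - followup
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        method, normality_p = stats_mod.choose_paired_test(diffs)
    t_res = stats_mod.paired_t(baseline, followup)
    try:
        w_res = stats_mod.wilcoxon_signed_rank(baseline, followup)
        wilcoxon_p = w_res.p_two_sided
    except ValidationError:
        wilcoxon_p = None
    chosen = t_res.p_two_sided if method is stats_mod.TestMethod.PAIRED_T else wilcoxon_p
    return {
        "week": week,
        "method": method.value,
        "normality_p": None if np.isnan(normality_p) else normality_p,
        "p_paired_t": t_res.p_two_sided,
        "p_wilcoxon": wilcoxon_p,
        "p_value": chosen,
        "n_pairs": t_res.n_pairs,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Scores -> summaries -> paired tests -> response rates -> ICC -> NPX.

    Stages run in pipeline order; optional stages (ICC, NPX) run only when
    their inputs are configured.  Writes per-stage CSV tables and one
    ``report.json`` under ``config.out_dir`` and returns the report dict.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "decisions": {
            "response_boundaries": "50% and 75% -> good, 25% -> partial",
            "normality_gate": f"Shapiro-Wilk at alpha={config.alpha}",
            "de_multiple_testing": "none (BH column reported alongside)",
        },
    }

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise ValidationError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with _stage("scoring"):
        region_map = (
            RegionMap.from_yaml(config.region_map)
            if config.region_map
            else DEFAULT_REGION_MAP
        )
        if config.assessments is not None:
            assessments = read_assessments(config.assessments)
            scores = score_assessments(assessments, region_map)
            write_scores(scores, out / "scores.csv")
        else:
            scores = read_scores(config.scores)
        if config.score_name not in scores:
            raise ValidationError(
                f"score {config.score_name!r} not present (have {sorted(scores)})"
            )

    with _stage("efficacy"):
        table = scores[config.score_name]
        weeks = [w for w in table.visit_weeks]
        summaries = {
            str(week): stats_mod.summarize(table.week(week).dropna()).__dict__
            for week in weeks
        }
        followups = [w for w in config.followup_weeks if w in weeks]
        tests = [
            _paired_report(table, config.baseline_week, week) for week in followups
        ]
        rates = {}
        for week in followups:
            rate = stats_mod.response_rate_table(table, config.baseline_week, week)
            rates[str(week)] = {
                cat.value: {"count": count, "proportion": prop}
                for cat, (count, prop) in rate.items()
            }
        report["efficacy"] = {
            "score": config.score_name,
            "summaries": summaries,
            "paired_tests": tests,
            "response_rates": rates,
        }
        pd.DataFrame(tests).to_csv(out / "paired_tests.csv", index=False)

    if config.ratings is not None:
        with _stage("icc"):
            ratings = read_ratings(config.ratings)
            icc_table = icc_mod.icc_report(ratings)
            icc_table.to_csv(out / "icc.csv", index=False)
            report["icc"] = icc_table.to_dict(orient="records")

    if config.npx is not None:
        with _stage("npx"):
            matrix = npx_mod.qc_filter(read_npx(config.npx))
            npx_report: dict = {
                "qc_incomplete_subjects": list(matrix.incomplete_subjects)
            }
            dep_union: set[str] = set()
            for g1, g2 in config.contrasts:
                de = npx_mod.paired_de(matrix, g1, g2, config.de_alpha)
                de.to_csv(out / f"de_{g1}{g2}.csv")
                deps = de.index[de["significant"]].tolist()
                dep_union |= set(deps)
                npx_report[f"deps_{g1}_{g2}"] = deps
            npx_report["dep_union"] = sorted(dep_union)
            if len(dep_union) >= 2:
                for group in sorted({g for c in config.contrasts for g in c}):
                    rho, _ = npx_mod.spearman_matrix(
                        matrix, sorted(dep_union), group
                    )
                    rho.to_csv(out / f"spearman_{group}.csv")
            if config.edges is not None and dep_union:
                edges = [
                    e
                    for e in read_edges(config.edges)
                    if e[0] in dep_union and e[1] in dep_union
                ]
                hubs = npx_mod.degree_hubs(edges, sorted(dep_union))
                npx_report["hubs"] = hubs
            if config.annotations is not None and dep_union:
                annotations = read_annotations(config.annotations)
                background = set(matrix.protein_ids)
                ora = npx_mod.ora_hypergeometric(
                    dep_union & background, annotations, background
                )
                ora.to_csv(out / "ora.csv")
                npx_report["ora_top"] = (
                    ora.head(10).reset_index().to_dict(orient="records")
                )
            report["npx"] = npx_report

    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
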