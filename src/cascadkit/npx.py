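"""Paired differential expression on Olink-style NPX panels.

NPX (normalized protein expression) is an arbitrary log2-scale relative
abundance unit, so a paired difference of -1 NPX is a halving of measured
abundance.  The pipeline mirrors a three-timepoint treatment study design:
samples are grouped A (baseline), B (early follow-up), C (late follow-up),
one sample per subject per group.  Differentially expressed proteins (DEPs)
are called per contrast by a paired t-test over subjects at an unadjusted
p < 0.05 by default (Benjamini-Hochberg adjusted p-values are always reported
alongside); downstream steps are Spearman correlation among DEPs, degree-based
hub ranking on a user-supplied protein-interaction edge list, and generic
hypergeometric over-representation analysis against a user-supplied
annotation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .stats import paired_t

__all__ = [
    "NpxMatrix",
    "qc_filter",
    "paired_de",
    "spearman_matrix",
    "degree_hubs",
    "ora_hypergeometric",
]


@dataclass
class NpxMatrix:
    """Samples x proteins NPX table with subject/timepoint metadata.

    ``values`` is indexed by sample_id with one column per protein;
    ``sample_meta`` is indexed identically with columns ``subject_id``,
    ``group`` and ``qc_pass``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    incomplete_subjects: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValidationError("values and sample_meta must share a sample index")
        for col in ("subject_id", "group"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample_meta missing column {col!r}")
        if "qc_pass" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(qc_pass=True)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate protein ids: {dupes}")
        key = self.sample_meta[["subject_id", "group"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (subject, group) samples: {dupes}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_meta["group"].unique())

    def group_values(self, group: str) -> pd.DataFrame:
        """NPX values of one group, indexed by subject_id."""
        mask = self.sample_meta["group"] == group
        if not mask.any():
            raise ValidationError(f"no samples in group {group!r}")
        sub = self.values.loc[mask]
        sub.index = self.sample_meta.loc[mask, "subject_id"]
        return sub

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "NpxMatrix":
        required = {"sample_id", "subject_id", "group", "protein_id", "npx"}
        missing = required - set(long.columns)
        if missing:
            raise ValidationError(f"long NPX table missing columns {sorted(missing)}")
        if "qc_pass" not in long.columns:
            long = long.assign(qc_pass=True)
        values = long.pivot(index="sample_id", columns="protein_id", values="npx")
        meta = (
            long[["sample_id", "subject_id", "group", "qc_pass"]]
            .drop_duplicates()
            .set_index("sample_id")
        )
        if meta.index.duplicated().any():
            raise ValidationError("inconsistent metadata for some sample_id")
        return cls(values, meta.loc[values.index])

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.reset_index(names="sample_id")
            .melt(id_vars="sample_id", var_name="protein_id", value_name="npx")
        )
        return long.merge(
            self.sample_meta.reset_index(names="sample_id"), on="sample_id"
        )[["sample_id", "subject_id", "group", "protein_id", "npx", "qc_pass"]]


def qc_filter(npx: NpxMatrix) -> NpxMatrix:
    """Drop QC-failing samples; flag subjects left without a full visit set.

    The vendor-side extension/inter-plate normalization is assumed already
    applied; only the per-sample pass/fail gate acts here.
    """
    passing = npx.sample_meta["qc_pass"].astype(bool)
    if not passing.any():
        raise ValidationError("all samples fail QC")
    kept_meta = npx.sample_meta.loc[passing]
    expected_groups = set(npx.sample_meta["group"].unique())
    incomplete = tuple(
        sorted(
            subject
            for subject, groups in kept_meta.groupby("subject_id")["group"]
            if set(groups) != expected_groups
        )
    )
    return NpxMatrix(npx.values.loc[passing], kept_meta, incomplete)


def paired_de(
    npx: NpxMatrix,
    group1: str,
    group2: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein paired t-test between two timepoint groups.

    Pairs are subjects with a sample in both groups; per protein, subjects
    with a missing NPX in either sample are dropped (complete-case), and
    proteins left with fewer than 2 complete pairs are reported untested.
    ``mean_diff`` is group2 - group1 in NPX units.  Significance is gated at
    unadjusted ``p < alpha``; a Benjamini-Hochberg ``p_adjusted`` column is
    reported alongside but plays no part in the default call.
    """
    if group1 == group2:
        raise ValidationError(f"contrast groups must differ, got {group1!r} twice")
    g1 = npx.group_values(group1)
    g2 = npx.group_values(group2)
    subjects = g1.index.intersection(g2.index)
    if len(subjects) < 2:
        raise ValidationError(
            f"need >= 2 subjects with samples in both {group1!r} and {group2!r}"
        )
    g1, g2 = g1.loc[subjects], g2.loc[subjects]
    rows = []
    for protein in npx.protein_ids:
        x, y = g2[protein], g1[protein]
        complete = x.notna() & y.notna()
        n_pairs = int(complete.sum())
        if n_pairs < 2:
            rows.append(
                dict(protein_id=protein, n_pairs=n_pairs, mean_diff=np.nan,
                     t_stat=np.nan, df=np.nan, p_value=np.nan, tested=False)
            )
            continue
        res = paired_t(x[complete].to_numpy(), y[complete].to_numpy())
        rows.append(
            dict(
                protein_id=protein,
                n_pairs=n_pairs,
                mean_diff=float((x[complete] - y[complete]).mean()),
                t_stat=res.statistic,
                df=res.df,
                p_value=res.p_two_sided,
                tested=True,
            )
        )
    table = pd.DataFrame(rows).set_index("protein_id")
    tested = table["tested"]
    adjusted = np.full(len(table), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = multipletests(
            table.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    table["p_adjusted"] = adjusted
    table["significant"] = tested & (table["p_value"] < alpha)
    table["direction"] = np.where(table["mean_diff"] > 0, "up", "down")
    table.loc[~tested, "direction"] = None
    table.attrs["contrast"] = (group1, group2)
    table.attrs["alpha"] = alpha
    return table


def spearman_matrix(
    npx: NpxMatrix, proteins: Sequence[str], group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation (mid-rank ties) among chosen proteins.

    Returns (rho, p) DataFrames, symmetric with unit diagonal.  A protein
    constant within the group has undefined correlations; its off-diagonal
    entries are reported missing (NaN).
    """
    unknown = [p for p in proteins if p not in npx.values.columns]
    if unknown:
        raise ValidationError(f"unknown proteins: {unknown}")
    sub = npx.group_values(group)[list(proteins)]
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 samples in group {group!r}, got {len(sub)}")
    arr = sub.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(arr)
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = pd.Index(proteins, name="protein_id")
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def degree_hubs(
    edges: Iterable[tuple[str, str]], nodes: Sequence[str]
) -> list[tuple[str, int]]:
    """Rank nodes by degree in an undirected interaction network.

    ``nodes`` must cover every edge endpoint; isolated nodes get degree 0.
    Ties break lexicographically.  Parallel edges collapse; self-loops are
    rejected (a protein interacting with itself carries no ranking signal).
    """
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    node_set = set(nodes)
    for a, b in edges:
        if a == b:
            raise ValidationError(f"self-loop on {a!r} not allowed")
        stray = [x for x in (a, b) if x not in node_set]
        if stray:
            raise ValidationError(f"edge ({a!r}, {b!r}) has endpoints outside nodes: {stray}")
        graph.add_edge(a, b)
    return sorted(
        ((node, int(deg)) for node, deg in graph.degree()),
        key=lambda item: (-item[1], item[0]),
    )


def ora_hypergeometric(
    dep_set: Iterable[str],
    annotations: Mapping[str, set[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of annotation terms in a DEP list.

    Per term, the upper-tail hypergeometric probability of drawing at least
    the observed overlap when sampling |deps| proteins without replacement
    from the background; Benjamini-Hochberg adjusted p-values alongside.
    Term members outside the background are ignored with the background
    acting as the sampling universe.
    """
    background = set(background)
    deps = set(dep_set)
    stray = sorted(deps - background)
    if stray:
        raise ValidationError(f"DEPs absent from the background: {stray}")
    rows = []
    for term_id, members in annotations.items():
        members_in_bg = set(members) & background
        overlap = deps & members_in_bg
        p = float(
            sps.hypergeom.sf(
                len(overlap) - 1, len(background), len(members_in_bg), len(deps)
            )
        )
        rows.append(
            dict(
                term_id=term_id,
                term_size=len(members_in_bg),
                overlap=len(overlap),
                overlap_proteins=",".join(sorted(overlap)),
                p_value=p,
            )
        )
    table = pd.DataFrame(rows).set_index("term_id")
    if len(table):
        table["p_adjusted"] = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        table = table.sort_values("p_value")
    return table
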