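"""NPX panel QC, paired differential expression, and post-processing."""

import math

import numpy as np
import pandas as pd
import pytest

from cascadkit import (
    NpxMatrix,
    ValidationError,
    degree_hubs,
    ora_hypergeometric,
    paired_de,
    qc_filter,
    spearman_matrix,
)
from cascadkit.simulate import NpxSpec, generate_npx


def _tiny_matrix(values_by_group, qc_fail=()):
    """Build an NpxMatrix from {group: {protein: per-subject values}}."""
    rows, meta = [], []
    proteins = sorted(next(iter(values_by_group.values())))
    for group, columns in values_by_group.items():
        n = len(next(iter(columns.values())))
        for i in range(n):
            sample = f"s{i}_{group}"
            rows.append(
                pd.Series({p: columns[p][i] for p in proteins}, name=sample)
            )
            meta.append(
                {
                    "sample_id": sample,
                    "subject_id": f"s{i}",
                    "group": group,
                    "qc_pass": sample not in qc_fail,
                }
            )
    return NpxMatrix(pd.DataFrame(rows), pd.DataFrame(meta).set_index("sample_id"))


class TestQcFilter:
    def test_all_pass_is_identity(self):
        m = _tiny_matrix({"A": {"p1": [1, 2, 3]}, "B": {"p1": [2, 3, 4]}})
        filtered = qc_filter(m)
        assert filtered.values.equals(m.values)
        assert filtered.incomplete_subjects == ()

    def test_failing_sample_flags_subject(self):
        m = _tiny_matrix(
            {"A": {"p1": [1, 2, 3]}, "B": {"p1": [2, 3, 4]}}, qc_fail=("s1_B",)
        )
        filtered = qc_filter(m)
        assert len(filtered.values) == 5
        assert filtered.incomplete_subjects == ("s1",)

    def test_full_panel_count(self):
        spec = NpxSpec(seed=0)
        m, _ = generate_npx(spec)
        m.sample_meta.loc["subj3_B", "qc_pass"] = False
        assert len(qc_filter(m).values) == 17

    def test_all_fail_rejected(self):
        m = _tiny_matrix(
            {"A": {"p1": [1, 2]}, "B": {"p1": [2, 3]}},
            qc_fail=("s0_A", "s1_A", "s0_B", "s1_B"),
        )
        with pytest.raises(ValidationError):
            qc_filter(m)


class TestPairedDe:
    def test_identical_groups_give_no_deps(self):
        m = _tiny_matrix(
            {"A": {"p1": [1.0, 2.0, 3.0], "p2": [5.0, 6.0, 7.0]},
             "B": {"p1": [1.0, 2.0, 3.0], "p2": [5.0, 6.0, 7.0]}}
        )
        table = paired_de(m, "A", "B")
        assert not table["significant"].any()
        assert (table["p_value"] == 1.0).all()

    def test_planted_shifts_recovered_with_direction(self):
        m, truth = generate_npx(NpxSpec(seed=7))
        table = paired_de(m, "A", "C")
        planted = truth["planted"][("A", "C")]
        recovered = set(table.index[table["significant"]]) & planted
        assert len(recovered) >= 7
        assert (table.loc[sorted(recovered), "direction"] == "down").all()
        assert (table["significant"] == (table["p_value"] < 0.05)).all()

    def test_missing_values_complete_case(self):
        m, _ = generate_npx(NpxSpec(seed=1, n_subjects=3, n_proteins=4, dep_spec={}))
        m.values.iloc[0, 0] = np.nan  # one A sample loses protein 0
        m.values.loc[m.sample_meta["group"] == "C", m.values.columns[1]] = np.nan
        table = paired_de(m, "A", "C")
        assert table.iloc[0]["n_pairs"] == 2
        assert not table.iloc[1]["tested"]
        assert np.isnan(table.iloc[1]["p_value"])

    def test_identical_group_labels_rejected(self):
        m, _ = generate_npx(NpxSpec(seed=1))
        with pytest.raises(ValidationError):
            paired_de(m, "A", "A")


class TestSpearman:
    def test_monotone_pairs(self):
        m = _tiny_matrix(
            {"A": {"p1": [1.0, 2.0, 3.0, 4.0], "p2": [10.0, 20.0, 25.0, 90.0],
                   "p3": [4.0, 3.0, 2.0, 1.0]}}
        )
        rho, _ = spearman_matrix(m, ["p1", "p2", "p3"], "A")
        assert rho.loc["p1", "p2"] == pytest.approx(1.0)
        assert rho.loc["p1", "p3"] == pytest.approx(-1.0)
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)

    def test_tied_fixture_matches_pearson_on_midranks(self, rng):
        values = rng.integers(0, 4, size=(10, 5)).astype(float)
        m = _tiny_matrix({"A": {f"p{j}": values[:, j] for j in range(5)}})
        proteins = [f"p{j}" for j in range(5)]
        rho, _ = spearman_matrix(m, proteins, "A")
        from scipy.stats import rankdata

        ranks = np.column_stack([rankdata(values[:, j]) for j in range(5)])
        expected = np.corrcoef(ranks, rowvar=False)
        assert np.allclose(rho.to_numpy(), expected, atol=1e-12)

    def test_constant_protein_reported_missing(self):
        m = _tiny_matrix(
            {"A": {"p1": [1.0, 2.0, 3.0], "p2": [5.0, 5.0, 5.0]}}
        )
        rho, _ = spearman_matrix(m, ["p1", "p2"], "A")
        assert np.isnan(rho.loc["p1", "p2"])
        assert rho.loc["p2", "p2"] == 1.0


class TestDegreeHubs:
    def test_star_graph_center_first(self):
        edges = [("hub", f"n{i}") for i in range(4)]
        ranked = degree_hubs(edges, ["hub", "n0", "n1", "n2", "n3"])
        assert ranked[0] == ("hub", 4)
        assert all(deg == 1 for _, deg in ranked[1:])

    def test_empty_edge_list_all_zero(self):
        assert degree_hubs([], ["b", "a"]) == [("a", 0), ("b", 0)]

    def test_matches_brute_force_incidence_count(self, rng):
        nodes = [f"p{i}" for i in range(8)]
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j]))
        ranked = dict(degree_hubs(edges, nodes))
        for node in nodes:
            count = sum(node in e for e in edges)
            assert ranked[node] == count

    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError, match="self-loop"):
            degree_hubs([("a", "a")], ["a"])


def brute_force_ora_p(n_background, term, deps):
    """Enumerate the overlap distribution: P(overlap >= observed)."""
    k_obs = len(deps & term)
    n, K = len(deps), len(term)
    total = math.comb(n_background, n)
    return sum(
        math.comb(K, j) * math.comb(n_background - K, n - j)
        for j in range(k_obs, min(n, K) + 1)
    ) / total


class TestOra:
    def test_term_equal_to_background_p_one(self):
        background = {f"p{i}" for i in range(10)}
        table = ora_hypergeometric({"p0", "p1"}, {"T": set(background)}, background)
        assert table.loc["T", "p_value"] == pytest.approx(1.0)

    def test_exact_combinatorial_example(self):
        background = {f"p{i}" for i in range(20)}
        term = {f"p{i}" for i in range(5)}
        table = ora_hypergeometric(term, {"T": term}, background)
        assert table.loc["T", "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_matches_enumeration_on_small_backgrounds(self, rng):
        for _ in range(20):
            n_bg = int(rng.integers(8, 26))
            background = {f"p{i}" for i in range(n_bg)}
            term = set(rng.choice(sorted(background), rng.integers(1, n_bg), False))
            deps = set(rng.choice(sorted(background), rng.integers(1, n_bg // 2 + 1), False))
            table = ora_hypergeometric(deps, {"T": term}, background)
            assert table.loc["T", "p_value"] == pytest.approx(
                brute_force_ora_p(n_bg, term, deps), rel=1e-9
            )

    def test_dep_outside_background_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            ora_hypergeometric({"x"}, {"T": {"p1"}}, {"p1", "p2"})


class TestNpxMatrix:
    def test_long_round_trip(self):
        m, _ = generate_npx(NpxSpec(seed=3, n_subjects=2, n_proteins=3, dep_spec={}))
        rebuilt = NpxMatrix.from_long(m.to_long())
        assert np.allclose(
            rebuilt.values.loc[m.values.index, m.values.columns], m.values
        )

    def test_duplicate_subject_group_rejected(self):
        values = pd.DataFrame({"p1": [1.0, 2.0]}, index=["a", "b"])
        meta = pd.DataFrame(
            {"subject_id": ["s1", "s1"], "group": ["A", "A"], "qc_pass": [True, True]},
            index=["a", "b"],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            NpxMatrix(values, meta)
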