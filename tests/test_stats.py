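"""Hypothesis tests, Holm correction, compact letters, Kendall tau-b and the
correlation-network / BMI-stratification reports."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from guttype.abundance import to_relative
from guttype.simulate import (
    QuestionnaireCoupling,
    SyntheticCohortConfig,
    study_archetypes,
    generate_cohort,
)
from guttype.stats import (
    ConstantInputError,
    StratificationError,
    bmi_strata_compare,
    build_network,
    compact_letters,
    fisher_exact,
    group_abundance_report,
    holm_adjust,
    kendall_tau_b,
    mann_whitney_u,
    significance_stars,
    welch_t,
)

from conftest import relative_table, two_archetype_config


def hypergeom_two_sided(table):
    """Independent oracle: full enumeration with the probability-mass rule."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs * (1 + 1e-7):
            total += prob(x)
    return min(total, 1.0)


class TestWelch:
    def test_identical_groups_null(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_example(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_value == pytest.approx(0.2878, abs=1e-3)
        assert res.effect_direction == -1

    def test_shift_alternative_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        res = welch_t(x, y)
        assert res.p_value < 0.01 and res.effect_direction == 1

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_all_tied_uninformative(self):
        res = mann_whitney_u([2, 2, 2], [2, 2])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_ordinal_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, 100)
        y = np.minimum(rng.integers(1, 6, 100) + 1, 5)
        res = mann_whitney_u(x, y)
        assert res.p_value < 0.01


class TestFisher:
    def test_hand_example(self):
        res = fisher_exact([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(0.002759, abs=1e-5)

    def test_balanced_table_null(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0:
                continue
            assert fisher_exact(table).p_value == pytest.approx(
                hypergeom_two_sided(table), rel=1e-7, abs=1e-12
            )

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            p = fisher_exact(t).p_value
            assert fisher_exact(t[::-1, ::-1]).p_value == pytest.approx(p, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


class TestHolm:
    def test_hand_step_down(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_dominates_raw_and_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            adj = holm_adjust(p)
            assert (adj >= p - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestCompactLetters:
    @staticmethod
    def check_invariant(letters, pmat, groups, alpha=0.05):
        for i, j in itertools.combinations(range(len(groups)), 2):
            share = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
            assert share == (pmat[i, j] >= alpha), (groups[i], groups[j])

    @staticmethod
    def brute_minimum_letters(pmat, alpha=0.05):
        """Independent oracle: smallest letter count over all subsets of groups
        that are cliques of the not-significant graph."""
        n = pmat.shape[0]
        edges = {
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if pmat[i, j] >= alpha
        }
        cliques = []
        for size in range(1, n + 1):
            for subset in itertools.combinations(range(n), size):
                if all((a, b) in edges for a, b in itertools.combinations(subset, 2)):
                    cliques.append(set(subset))
        for r in range(1, len(cliques) + 1):
            for combo in itertools.combinations(cliques, r):
                cov_e = {
                    (a, b)
                    for c in combo
                    for a, b in itertools.combinations(sorted(c), 2)
                }
                cov_v = set().union(*combo)
                if edges <= cov_e and cov_v == set(range(n)):
                    return r
        raise AssertionError("no cover found")

    def test_no_significant_pairs_single_letter(self):
        groups = ["a", "b", "c"]
        letters = compact_letters(groups, np.ones((3, 3)))
        assert len({letters[g] for g in groups}) == 1

    def test_all_pairs_significant_distinct_letters(self):
        groups = ["g1", "g2", "g3"]
        pmat = np.full((3, 3), 0.001)
        np.fill_diagonal(pmat, 1.0)
        letters = compact_letters(groups, pmat)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_one_extreme_pair_pattern(self):
        # only first-vs-last differs; intermediates share letters with both
        groups = [f"r{i}" for i in range(7)]
        pmat = np.ones((7, 7))
        pmat[0, 6] = pmat[6, 0] = 0.01
        letters = compact_letters(groups, pmat)
        self.check_invariant(letters, pmat, groups)
        assert set(letters["r0"]) - set(letters["r6"])
        for g in groups[1:-1]:
            assert set(letters[g]) & set(letters["r0"])
            assert set(letters[g]) & set(letters["r6"])

    def test_invariant_and_minimality_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            pmat = np.ones((n, n))
            for i, j in itertools.combinations(range(n), 2):
                pmat[i, j] = pmat[j, i] = rng.choice([0.01, 0.5])
            groups = [f"g{i}" for i in range(n)]
            letters = compact_letters(groups, pmat)
            self.check_invariant(letters, pmat, groups)
            used = len({ch for g in groups for ch in letters[g]})
            assert used == self.brute_minimum_letters(pmat)

    def test_asymmetric_matrix_rejected(self):
        pmat = np.ones((2, 2))
        pmat[0, 1] = 0.01
        with pytest.raises(ValueError):
            compact_letters(["a", "b"], pmat)


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]).tau == 1.0

    def test_pair_enumeration_example(self):
        edge = kendall_tau_b([1, 2, 3, 4], [2, 1, 4, 3])
        assert edge.tau == pytest.approx(1 / 3)

    def test_greiner_relation(self):
        rng = np.random.default_rng(6)
        rho = 0.5
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        edge = kendall_tau_b(z[:, 0], z[:, 1])
        se = np.sqrt(2 * (2 * 2000 + 5) / (9 * 2000 * 1999))
        assert abs(edge.tau - (2 / np.pi) * np.arcsin(rho)) < 3 * se

    def test_antisymmetric_under_reversal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        assert kendall_tau_b(x, y).tau == pytest.approx(-kendall_tau_b(-x, y).tau)

    def test_constant_variable_rejected(self):
        with pytest.raises(ConstantInputError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestNetwork:
    def test_coupled_families_form_mutual_edges(self):
        # two archetypes in which three families are jointly high vs jointly
        # low induce pairwise positive tau among them across the cohort
        from guttype.simulate import EnterotypeArchetype, archetype_composition, study_families

        taxa = study_families(20)
        high = archetype_composition(
            {"Christensenellaceae": 0.06, "Mogibacteriaceae": 0.04, "Rikenellaceae": 0.08},
            taxa,
        )
        low = archetype_composition(
            {"Christensenellaceae": 0.002, "Mogibacteriaceae": 0.001, "Rikenellaceae": 0.003},
            taxa,
        )
        cfg = SyntheticCohortConfig(
            n_samples=400,
            archetypes=[
                EnterotypeArchetype("high", high, 300.0),
                EnterotypeArchetype("low", low, 300.0),
            ],
            n_taxa=20,
            depth_mean=10000.0,
            depth_sd=0.0,
            seed=14,
            questionnaire_couplings=[],
        )
        rel = to_relative(generate_cohort(cfg).counts)
        net = build_network(rel)
        trio = {"Christensenellaceae", "Mogibacteriaceae", "Rikenellaceae"}
        trio_edges = {
            frozenset((e.a, e.b)) for e in net.edges if {e.a, e.b} <= trio
        }
        assert len(trio_edges) == 3
        for e in net.edges:
            if {e.a, e.b} <= trio:
                assert e.tau > 0.2 and e.p_value < 0.001

    def test_small_n_has_no_power(self):
        # at n=10 the tie-adjusted normal p cannot cross 0.001 for |tau| <= 0.6
        rng = np.random.default_rng(8)
        rel = relative_table(rng.dirichlet(np.ones(6), size=10))
        net = build_network(rel)
        for e in net.edges:
            assert abs(e.tau) > 0.6

    def test_edges_respect_filters(self):
        rng = np.random.default_rng(9)
        rel = relative_table(rng.dirichlet(np.ones(10), size=150))
        net = build_network(rel, p_threshold=0.05, tau_threshold=0.1)
        for e in net.edges:
            assert e.p_value < 0.05 and abs(e.tau) > 0.1
        ids = {frozenset((e.a, e.b)) for e in net.edges}
        assert len(ids) == len(net.edges)  # undirected, no duplicates

    def test_item_taxon_edges(self):
        cfg = two_archetype_config(n_samples=300, seed=15)
        cfg.questionnaire_couplings = [
            QuestionnaireCoupling("Q7", ("Rikenellaceae",), -0.45, 5)
        ]
        cohort = generate_cohort(cfg)
        rel = to_relative(cohort.counts)
        net = build_network(
            rel, items=cohort.metadata[["Q7"]], taxon_pairs=False
        )
        found = {(e.a, e.b): e.tau for e in net.edges}
        assert ("Q7", "Rikenellaceae") in found
        assert found[("Q7", "Rikenellaceae")] < -0.2


class TestBMIStrata:
    @staticmethod
    def make_cohort(n=120, seed=16, lean_taxon_boost=None):
        cfg = two_archetype_config(n_samples=n, seed=seed)
        cohort = generate_cohort(cfg)
        return cohort

    def test_boundary_semantics(self):
        cohort = self.make_cohort()
        rel = to_relative(cohort.counts)
        meta = cohort.metadata.copy()
        ids = list(meta.index)
        meta["bmi"] = 22.0
        meta.loc[ids[0], "bmi"] = 25.0  # excluded
        meta.loc[ids[1], "bmi"] = 27.0  # excluded
        meta.loc[ids[2], "bmi"] = 24.9  # lean
        meta.loc[ids[3], "bmi"] = 30.1  # obese
        meta.loc[ids[4], "bmi"] = 30.5  # obese
        report = bmi_strata_compare(rel, meta, item=None)
        assert report.attrs["n_lean"] == len(ids) - 4
        assert report.attrs["n_obese"] == 2

    def test_identical_strata_nothing_significant(self):
        rng = np.random.default_rng(17)
        rows = np.tile(rng.dirichlet(np.ones(5)), (40, 1))
        rel = relative_table(rows + 0)
        meta = pd.DataFrame(
            {"bmi": [22.0] * 20 + [32.0] * 20}, index=rel.sample_ids
        )
        report = bmi_strata_compare(rel, meta, item=None)
        assert (report["sig_abundance"] == "NS").all()

    def test_lean_enriched_taxon_flagged(self):
        rng = np.random.default_rng(18)
        n_lean, n_obese = 200, 15
        lean = rng.dirichlet([8, 4, 4, 4], size=n_lean)
        obese = rng.dirichlet([4, 4, 4, 8], size=n_obese)
        rel = relative_table(np.vstack([lean, obese]))
        meta = pd.DataFrame(
            {"bmi": [22.0] * n_lean + [32.0] * n_obese}, index=rel.sample_ids
        )
        report = bmi_strata_compare(rel, meta, item=None)
        assert report.loc["t0", "p_abundance"] < 0.05
        assert report.loc["t0", "lean_mean"] > report.loc["t0", "obese_mean"]

    def test_empty_stratum_raises(self):
        cohort = self.make_cohort()
        rel = to_relative(cohort.counts)
        meta = cohort.metadata.copy()
        meta["bmi"] = 22.0  # nobody obese
        with pytest.raises(StratificationError):
            bmi_strata_compare(rel, meta)


def test_significance_stars():
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.5) == "NS"


def test_group_abundance_report_letters():
    rng = np.random.default_rng(19)
    # one group shifted strongly on taxon t0
    base = rng.dirichlet([5, 5, 5], size=60)
    shifted = rng.dirichlet([20, 5, 5], size=30)
    rel = relative_table(np.vstack([base, shifted]))
    meta = pd.DataFrame(
        {"region": ["north"] * 30 + ["middle"] * 30 + ["south"] * 30},
        index=rel.sample_ids,
    )
    report = group_abundance_report(rel, meta, by="region")
    assert "^" in report.loc["t0", "south"]  # letters mark the shifted group
    assert "±" in report.loc["t1", "north"]
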