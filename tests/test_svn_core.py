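"""Hypergeometric validation core: incidence, p-values, FDR, networks."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import hypergeom as scipy_hypergeom

from comorbnet.cohorts import CohortDataset, Decade
from comorbnet.records_io import Gender
from comorbnet.svn_core import (
    Correction,
    ValidationConfig,
    build_incidence,
    build_svn,
    degree_distribution,
    fdr_select,
    hypergeom_logpmf,
    hypergeom_pvalue,
    hypergeom_pvalues,
)


def enumeration_tail(n, n_i, n_j, n_ij):
    """Independent oracle: exhaustively enumerate all C(n, n_j) equally
    likely patient subsets for code j against a fixed i-set, and count the
    fraction with overlap >= n_ij.  Exact rational arithmetic."""
    i_set = set(range(n_i))
    hits = 0
    total = 0
    for j_set in combinations(range(n), n_j):
        total += 1
        if len(i_set.intersection(j_set)) >= n_ij:
            hits += 1
    return Fraction(hits, total)


def make_cohort(histories, gender=Gender.W, decade=Decade(50, 59)):
    return CohortDataset(gender, decade, {p: frozenset(h) for p, h in histories.items()})


class TestBuildIncidence:
    def test_direct_counts(self):
        inc = build_incidence(make_cohort({"P1": {"A01.0", "B01.0"}, "P2": {"A01.0"}}))
        assert inc.n_patients == 2
        assert inc.code_counts == {"A01.0": 2, "B01.0": 1}
        assert inc.pair_counts == {("A01.0", "B01.0"): 1}

    def test_identical_histories(self):
        inc = build_incidence(
            make_cohort({p: {"A01.0", "B01.0", "C01.0"} for p in "PQR"})
        )
        assert all(v == 3 for v in inc.pair_counts.values())
        assert len(inc.pair_counts) == 3

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_incidence(make_cohort({}))

    def test_min_prevalence_filters_codes(self):
        inc = build_incidence(
            make_cohort({"P1": {"A01.0", "B01.0"}, "P2": {"A01.0"}}),
            ValidationConfig(min_prevalence=2),
        )
        assert set(inc.code_counts) == {"A01.0"}
        assert inc.pair_counts == {}

    def test_matches_brute_force_double_loop(self, rng):
        codes = [f"C{k:02d}.0" for k in range(12)]
        histories = {
            f"P{i}": {c for c in codes if rng.random() < 0.3} | {codes[i % 12]}
            for i in range(100)
        }
        inc = build_incidence(make_cohort(histories))
        patients = sorted(histories)
        for i, j in combinations(sorted(codes), 2):
            expected = sum(
                1 for p in patients if i in histories[p] and j in histories[p]
            )
            assert inc.pair_counts.get((i, j), 0) == expected


class TestHypergeomPvalue:
    def test_zero_cooccurrence_gives_one(self):
        assert hypergeom_pvalue(10, 4, 5, 0) == 1.0

    def test_degenerate_full_margin_gives_one(self):
        # code i carried by every patient: the only achievable overlap is N_j
        assert hypergeom_pvalue(10, 10, 5, 5) == 1.0

    def test_enumeration_example(self):
        expected = enumeration_tail(10, 4, 5, 4)  # = 6/252
        assert expected == Fraction(6, 252)
        assert hypergeom_pvalue(10, 4, 5, 4) == pytest.approx(float(expected), abs=1e-14)

    @pytest.mark.parametrize("n", [6, 8])
    def test_enumeration_oracle_small_grid(self, n):
        for n_i in range(1, n + 1):
            for n_j in range(1, n + 1):
                for n_ij in range(0, min(n_i, n_j) + 1):
                    expected = float(enumeration_tail(n, n_i, n_j, n_ij))
                    got = hypergeom_pvalue(n, n_i, n_j, n_ij)
                    assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "n, n_i, n_j, n_ij, bound",
        [
            (0, 1, 1, 0, "N must be positive"),
            (10, 0, 5, 0, "N_i"),
            (10, 11, 5, 0, "N_i"),
            (10, 4, 0, 0, "N_j"),
            (10, 4, 5, 5, "N_ij"),
        ],
    )
    def test_margin_violations_name_the_bound(self, n, n_i, n_j, n_ij, bound):
        with pytest.raises(ValueError, match=bound):
            hypergeom_pvalue(n, n_i, n_j, n_ij)

    def test_extreme_tail_stays_accurate(self):
        # all-overlap of two rare codes in a large cohort: p ~ 1e-248
        p = hypergeom_pvalue(100_000, 80, 80, 80)
        ref = scipy_hypergeom.sf(79, 100_000, 80, 80)
        assert 0.0 < p < 1e-200
        assert p == pytest.approx(ref, rel=1e-6)

    def test_agrees_with_scipy_on_random_margins(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 5000))
            n_i = int(rng.integers(1, n + 1))
            n_j = int(rng.integers(1, n + 1))
            lo, hi = max(0, n_i + n_j - n), min(n_i, n_j)
            n_ij = int(rng.integers(lo, hi + 1)) if hi > lo else hi
            got = hypergeom_pvalue(n, n_i, n_j, n_ij)
            ref = scipy_hypergeom.sf(n_ij - 1, n, n_i, n_j)
            assert got == pytest.approx(ref, rel=1e-6, abs=1e-300)

    @given(
        st.integers(2, 40).flatmap(
            lambda n: st.tuples(
                st.just(n), st.integers(1, n), st.integers(1, n)
            )
        )
    )
    def test_symmetry_and_monotonicity(self, margins):
        """p is symmetric in (N_i, N_j) and strictly decreasing in N_ij
        across the support."""
        n, n_i, n_j = margins
        lo, hi = max(0, n_i + n_j - n), min(n_i, n_j)
        prev = None
        for n_ij in range(lo, hi + 1):
            p = hypergeom_pvalue(n, n_i, n_j, n_ij)
            assert p == pytest.approx(hypergeom_pvalue(n, n_j, n_i, n_ij), rel=1e-12)
            if prev is not None and n_ij > lo:
                assert p < prev
            prev = p

    def test_vector_and_scalar_paths_agree(self, rng):
        n = 1000
        n_i = rng.integers(1, 400, size=50)
        n_j = rng.integers(1, 400, size=50)
        n_ij = np.minimum(n_i, n_j) // 2
        vec = hypergeom_pvalues(n, n_i, n_j, n_ij)
        for k in range(50):
            assert vec[k] == hypergeom_pvalue(n, int(n_i[k]), int(n_j[k]), int(n_ij[k]))

    def test_pmf_normalizes(self):
        for n, n_i, n_j in [(50, 10, 20), (1000, 300, 150), (10**5, 5000, 300)]:
            lo, hi = max(0, n_i + n_j - n), min(n_i, n_j)
            x = np.arange(lo, hi + 1)
            total = np.exp(logsumexp(hypergeom_logpmf(x, n, n_i, n_j)))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestFdrSelect:
    def test_nothing_passes_when_all_p_one(self):
        results = [((f"A0{k}.0", f"B0{k}.0"), 1.0) for k in range(5)]
        assert not any(r.validated for r in fdr_select(results))

    def test_step_up_rule_hand_example(self):
        """T=3, alpha=0.01: thresholds 1/300, 2/300, 3/300; the two smallest
        p-values pass, the third does not."""
        results = [
            (("A01.0", "B01.0"), 0.001),
            (("A02.0", "B02.0"), 0.002),
            (("A03.0", "B03.0"), 0.5),
        ]
        out = fdr_select(results, ValidationConfig(alpha=0.01))
        by_pair = {r.pair: r for r in out}
        assert by_pair[("A01.0", "B01.0")].validated
        assert by_pair[("A02.0", "B02.0")].validated
        assert not by_pair[("A03.0", "B03.0")].validated
        assert [r.threshold for r in sorted(out, key=lambda r: r.rank)] == pytest.approx(
            [0.01 / 3, 0.02 / 3, 0.01]
        )
        assert sorted(r.rank for r in out) == [1, 2, 3]

    def test_single_test_at_nominal_level(self):
        (r,) = fdr_select([(("A01.0", "B01.0"), 0.009)], ValidationConfig(alpha=0.01))
        assert r.validated and r.threshold == pytest.approx(0.01)

    def test_step_up_rescues_later_ranks(self):
        # p_(1) fails its own threshold but p_(2) passes; both validated
        out = fdr_select(
            [(("A01.0", "B01.0"), 0.006), (("A02.0", "B02.0"), 0.009)],
            ValidationConfig(alpha=0.01),
        )
        assert all(r.validated for r in out)

    def test_bonferroni_mode(self):
        out = fdr_select(
            [(("A01.0", "B01.0"), 0.006), (("A02.0", "B02.0"), 0.009)],
            ValidationConfig(alpha=0.01, correction=Correction.BONFERRONI),
        )
        assert not any(r.validated for r in out)

    def test_duplicate_pair_fatal(self):
        with pytest.raises(ValueError, match="duplicate"):
            fdr_select([(("A01.0", "B01.0"), 0.5), (("B01.0", "A01.0"), 0.4)])

    def test_carries_cooccurrence_when_given(self):
        (r,) = fdr_select([(("A01.0", "B01.0"), 7, 0.001)])
        assert r.n_cooccurrence == 7 and r.validated

    @given(st.permutations(range(6)))
    def test_order_invariance(self, order):
        base = [((f"A{k:02d}.0", f"B{k:02d}.0"), (k + 1) / 100.0) for k in range(6)]
        shuffled = [base[i] for i in order]
        a = sorted(fdr_select(base), key=lambda r: r.pair)
        b = sorted(fdr_select(shuffled), key=lambda r: r.pair)
        assert a == b


class TestBuildSvn:
    def test_no_cooccurrence_no_edges(self):
        cohort = make_cohort({f"P{i}": {f"C{i:02d}.0"} for i in range(5)})
        net = build_svn(cohort)
        assert net.n_tested == 0
        assert net.graph.number_of_edges() == 0

    def test_perfect_pair_validated(self, rng):
        """Codes A and B co-occur in exactly the same 50 of 1000 patients;
        background codes are independent.  The A-B link must be validated
        at alpha = 0.01."""
        histories = {}
        for i in range(1000):
            h = {f"C{k:02d}.0" for k in range(10) if rng.random() < 0.1}
            if i < 50:
                h |= {"A01.0", "B01.0"}
            histories[f"P{i:04d}"] = h or {"Z99.9"}
        net = build_svn(make_cohort(histories), ValidationConfig(alpha=0.01))
        assert net.graph.has_edge("A01.0", "B01.0")
        d = net.graph.edges["A01.0", "B01.0"]
        assert d["n_cooccurrence"] == 50
        assert d["p_value"] < d["threshold"]

    def test_patient_order_invariance(self, rng):
        histories = {
            f"P{i}": {f"C{k}.0" for k in range(8) if rng.random() < 0.4} | {"C0.0"}
            for i in range(60)
        }
        net1 = build_svn(make_cohort(histories))
        net2 = build_svn(make_cohort(dict(reversed(list(histories.items())))))
        assert sorted(net1.graph.edges) == sorted(net2.graph.edges)

    def test_min_cooccurrence_shrinks_tested_set(self, rng):
        histories = {
            f"P{i}": {f"C{k}.0" for k in range(6) if rng.random() < 0.5} | {"C0.0"}
            for i in range(40)
        }
        loose = build_svn(make_cohort(histories), ValidationConfig(min_cooccurrence=1))
        tight = build_svn(make_cohort(histories), ValidationConfig(min_cooccurrence=5))
        assert tight.n_tested <= loose.n_tested

    def test_isolates_optional(self):
        cohort = make_cohort({"P1": {"A01.0"}, "P2": {"B01.0"}})
        assert build_svn(cohort).graph.number_of_nodes() == 0
        assert build_svn(cohort, include_isolates=True).graph.number_of_nodes() == 2


class TestDegreeDistribution:
    def test_triangle(self):
        import networkx as nx

        from comorbnet.svn_core import ValidatedNetwork

        g = nx.cycle_graph(["A", "B", "C"])
        assert degree_distribution(ValidatedNetwork(("M", "50-59"), g)) == {2: 1.0}

    def test_star(self):
        import networkx as nx

        from comorbnet.svn_core import ValidatedNetwork

        g = nx.star_graph(["hub", "a", "b", "c", "d"])
        dist = degree_distribution(ValidatedNetwork(("M", "50-59"), g))
        assert dist == {1: pytest.approx(0.8), 4: pytest.approx(0.2)}
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_network_errors(self):
        import networkx as nx

        from comorbnet.svn_core import ValidatedNetwork

        with pytest.raises(ValueError):
            degree_distribution(ValidatedNetwork(("M", "50-59"), nx.Graph()))
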