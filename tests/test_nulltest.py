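"""Constrained multinomial null test: predicates, pmf, simulation,
Monte Carlo vs exact enumeration."""

from dataclasses import replace
from math import factorial

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stairsafe import (
    ConditionCounts,
    ConstraintConfig,
    NullModel,
    check_constraints,
    codification_table,
    compositions,
    exact_probability,
    mc_probability,
    multinomial_pmf,
    n_compositions,
    run_test,
    simulate_null,
)
from stairsafe.nulltest import _check_matrix

DEFAULT = ConstraintConfig()


def oracle_exact(n, config=DEFAULT, probs=(0.25, 0.25, 0.25, 0.25)):
    """Independent brute-force oracle: factorial-arithmetic multinomial sum
    over all compositions, scalar predicate evaluation."""
    total = 0.0
    for lc in range(n + 1):
        for ls in range(n + 1 - lc):
            for hc in range(n + 1 - lc - ls):
                hs = n - lc - ls - hc
                diff = abs(ls - lc)
                a2 = diff < config.a2_max_diff if config.a2_strict else diff <= config.a2_max_diff
                a4 = (
                    abs(hc - lc) > abs(hs - ls)
                    if config.a4_absolute
                    else (hc - lc) > (hs - ls)
                )
                if hc > lc and a2 and hc >= config.a3_ratio * hs and a4:
                    coeff = factorial(n) // (
                        factorial(lc) * factorial(ls) * factorial(hc) * factorial(hs)
                    )
                    total += (
                        coeff
                        * probs[0] ** lc
                        * probs[1] ** ls
                        * probs[2] ** hc
                        * probs[3] ** hs
                    )
    return total


class TestCheckConstraints:
    def test_observed_study_counts_satisfy_all(self):
        b = check_constraints(ConditionCounts(2, 2, 13, 3))
        assert b.as_dict() == {"a1": True, "a2": True, "a3": True, "a4": True, "all": True}

    def test_uniform_counts_fail_a1(self):
        b = check_constraints(ConditionCounts(5, 5, 5, 5))
        assert not b.a1 and not b.all_satisfied

    def test_all_events_in_hc(self):
        assert check_constraints(ConditionCounts(0, 0, 20, 0)).all_satisfied

    def test_a2_strict_reading(self):
        # difference exactly 2 passes "<= 2" but fails "< 2"
        counts = ConditionCounts(0, 2, 13, 5)
        assert check_constraints(counts, DEFAULT).a2
        assert not check_constraints(counts, replace(DEFAULT, a2_strict=True)).a2

    def test_a4_signed_reading(self):
        # hc - lc = 2 vs hs - ls = -3: signed passes, absolute fails
        counts = ConditionCounts(5, 6, 7, 3)
        assert not check_constraints(counts, DEFAULT).a4
        assert check_constraints(counts, replace(DEFAULT, a4_absolute=False)).a4

    def test_a3_ratio_boundary_inclusive(self):
        assert check_constraints(ConditionCounts(0, 0, 14, 6), DEFAULT).a3  # 14 >= 12
        assert not check_constraints(ConditionCounts(0, 0, 11, 6), DEFAULT).a3

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=30)] * 4),
        st.integers(min_value=0, max_value=5),
        st.booleans(),
        st.sampled_from([1.0, 1.5, 2.0, 3.0]),
        st.booleans(),
    )
    def test_vectorised_matches_scalar(self, cells, a2_max, a2_strict, a3_ratio, a4_abs):
        """The Monte Carlo fast path agrees predicate-by-predicate with the
        scalar reference evaluation."""
        config = ConstraintConfig(
            a2_max_diff=a2_max, a2_strict=a2_strict, a3_ratio=a3_ratio, a4_absolute=a4_abs
        )
        scalar = check_constraints(ConditionCounts(*cells), config)
        matrix = _check_matrix(np.array([cells]), config)[0]
        assert list(matrix) == [scalar.a1, scalar.a2, scalar.a3, scalar.a4]


class TestMultinomialPmf:
    def test_degenerate_composition(self):
        assert multinomial_pmf((20, 0, 0, 0)) == pytest.approx(0.25**20, rel=1e-12)

    def test_single_event(self):
        assert multinomial_pmf((1, 0, 0, 0)) == pytest.approx(0.25)

    def test_normalizes_over_compositions(self):
        total = sum(multinomial_pmf(c) for c in compositions(20))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_composition_count_stars_and_bars(self):
        assert len(list(compositions(20))) == 1771
        assert n_compositions(20) == 1771


class TestSimulateNull:
    def test_draws_conserve_total(self):
        draws = simulate_null(NullModel(seed=7, n_samples=500))
        assert draws.shape == (500, 4)
        assert (draws.sum(axis=1) == 20).all()

    def test_seed_determinism(self):
        a = simulate_null(NullModel(seed=11))
        b = simulate_null(NullModel(seed=11))
        assert (a == b).all()

    def test_cell_means_match_expectation(self):
        model = NullModel(seed=3, n_samples=10_000)
        draws = simulate_null(model)
        # per-cell mean 20 * 0.25 = 5; SE of the mean over 10,000 draws
        se = np.sqrt(20 * 0.25 * 0.75 / model.n_samples)
        assert np.all(np.abs(draws.mean(axis=0) - 5.0) < 4 * se)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            NullModel(seed=1, cell_probs=(0.3, 0.3, 0.3, 0.3))


class TestExactProbability:
    def test_matches_independent_oracle(self):
        res = exact_probability(20)
        assert res.p_exact == pytest.approx(oracle_exact(20), abs=1e-12)
        assert res.p_exact == pytest.approx(0.035374799381315825, abs=1e-10)
        assert res.n_satisfying_compositions == 132

    @pytest.mark.parametrize("n", [1, 5, 12])
    def test_small_n_against_oracle(self, n):
        assert exact_probability(n).p_exact == pytest.approx(oracle_exact(n), abs=1e-12)

    def test_impossible_configuration_still_defined(self):
        # a huge ratio leaves only hs = 0 allocations eligible
        cfg = replace(DEFAULT, a3_ratio=100.0)
        res = exact_probability(20, config=cfg)
        assert 0.0 <= res.p_exact <= 1.0

    def test_enumeration_cap(self):
        with pytest.raises(ValueError, match="enumeration cap"):
            exact_probability(1000, enumeration_cap=500)

    def test_bounded_by_marginal_rates(self):
        res = exact_probability(20)
        assert res.p_exact <= min(res.per_constraint_rates.values())

    def test_a2_marginal_symmetric_in_low_cells(self):
        """With uniform cell probabilities, swapping the roles of the two
        low-variation cells leaves the A2 marginal rate unchanged."""
        rate = exact_probability(20).per_constraint_rates["a2"]
        swapped = sum(
            multinomial_pmf((ls, lc, hc, hs))
            for (lc, ls, hc, hs) in compositions(20)
            if abs(lc - ls) <= DEFAULT.a2_max_diff
        )
        assert rate == pytest.approx(swapped, abs=1e-12)

    def test_monotone_under_a2_relaxation(self):
        p2 = exact_probability(20, config=replace(DEFAULT, a2_max_diff=2)).p_exact
        p3 = exact_probability(20, config=replace(DEFAULT, a2_max_diff=3)).p_exact
        assert p3 >= p2

    def test_monotone_under_a3_tightening(self):
        p2 = exact_probability(20, config=replace(DEFAULT, a3_ratio=2.0)).p_exact
        p3 = exact_probability(20, config=replace(DEFAULT, a3_ratio=3.0)).p_exact
        assert p3 <= p2


class TestMcProbability:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_agrees_with_enumeration(self, seed):
        """MC estimate within 4 standard errors of the exact probability."""
        res = mc_probability(NullModel(seed=seed))
        exact = exact_probability(20).p_exact
        assert abs(res.p_hat - exact) <= 4 * res.mc_se

    def test_se_formula(self):
        res = mc_probability(NullModel(seed=1, n_samples=2_000))
        expected = np.sqrt(res.p_hat * (1 - res.p_hat) / 2_000)
        assert res.mc_se == pytest.approx(expected)

    def test_run_test_populates_both_routes(self):
        res = run_test(NullModel(seed=9))
        assert res.p_hat is not None and res.p_exact is not None
        assert abs(res.p_hat - res.p_exact) <= 4 * res.mc_se

    def test_tautological_constraints_give_probability_one(self):
        """With every predicate relaxed to triviality except A1/A4, a
        maximally permissive config upper-bounds the default one."""
        permissive = ConstraintConfig(a2_max_diff=40, a2_strict=False, a3_ratio=1.0)
        res = mc_probability(NullModel(seed=2), permissive)
        default = mc_probability(NullModel(seed=2), DEFAULT)
        assert res.p_hat >= default.p_hat


class TestCodificationTable:
    def test_four_variants_reported(self):
        table = codification_table()
        assert set(table) == {
            "a2_nonstrict|a4_absolute",
            "a2_nonstrict|a4_signed",
            "a2_strict|a4_absolute",
            "a2_strict|a4_signed",
        }
        # strictening A2 lowers the probability; signed A4 admits more
        assert table["a2_strict|a4_absolute"] <= table["a2_nonstrict|a4_absolute"]
        assert table["a2_nonstrict|a4_signed"] >= table["a2_nonstrict|a4_absolute"]
        for value in table.values():
            assert 0.0 <= value <= 1.0
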