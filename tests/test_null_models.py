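"""Taxonomic null models: observed statistic, resampled nulls, exact oracles.

Two independent checks back the sampled nulls: full enumeration of every
with-replacement pseudo-set (the package's own oracle, itself verified here
against closed-form moments of a mean of iid draws) and Monte-Carlo
convergence at large draw counts.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from vacniche.nullmodels import (
    CombinatorialGuardError,
    NullModelResult,
    Z_THRESHOLD,
    exhaustive_null,
    flag_significant,
    observed_statistic,
    one_tailed_threshold,
    random_acquisition_null,
    rra_null,
    run_null_models,
    z_vs_ncomparisons,
    _null_profile,
)
from vacniche.types import FateTable, NotComputableError, ValidationError

from conftest import tax
from vacniche.taxodist import build_tree


def make_fate_table(fates: dict, ptype: str = "helminth") -> FateTable:
    community = frozenset(sp for sp, f in fates.items() if f == "not_acquired")
    return FateTable(
        invasion_id="inv-t",
        focal_host="Focalis hostus",
        fate_map=fates,
        parasite_type_map={sp: ptype for sp in fates},
        community_nonnative=community,
    )


class TestObservedStatistic:
    def test_single_pair(self, toy_tree):
        ft = make_fate_table({"A1": "acquired", "L2": "lost"})
        pds, stat = observed_statistic(ft, toy_tree, "helminth")
        assert pds == [4] and stat == 4.0  # A1-L2 share the family only

    def test_mean_of_minima(self, toy_tree):
        ft = make_fate_table(
            {"A1": "acquired", "N2": "acquired", "L1": "lost", "L2": "lost"}
        )
        pds, stat = observed_statistic(ft, toy_tree, "helminth")
        assert pds == [2, 6] and stat == 4.0

    def test_no_acquired_gives_not_computable_marker(self, toy_tree):
        ft = make_fate_table({"L1": "lost", "N1": "not_acquired"})
        assert observed_statistic(ft, toy_tree, "helminth") is None

    def test_no_lost_gives_not_computable_marker(self, toy_tree):
        ft = make_fate_table({"A1": "acquired", "N1": "not_acquired"})
        assert observed_statistic(ft, toy_tree, "helminth") is None


class TestExhaustiveNull:
    def test_two_member_pool_exact_moments(self):
        # pool = {X, Y} with min-PDs 2 and 6 to the lost set; |acquired| = 1
        # -> two equally likely outcomes: mean 4.0, population sd 2.0
        taxa = [tax("L", genus="G1"), tax("A", family="F9", genus="G9"),
                tax("X", genus="G1"), tax("Y", family="F2", genus="G4")]
        # d(X, L) = 2 ; d(Y, L) = 6
        tree = build_tree(taxa)
        ft = make_fate_table(
            {"L": "lost", "A": "acquired", "X": "not_acquired", "Y": "not_acquired"}
        )
        mean, sd = exhaustive_null(ft, tree, "helminth", "random_acquisition")
        assert mean == pytest.approx(4.0) and sd == pytest.approx(2.0)

    def test_single_member_pool_sd_zero(self, toy_tree):
        ft = make_fate_table({"L1": "lost", "L2": "lost", "A1": "acquired",
                              "N1": "not_acquired"})
        # pool = {L1, L2, N1}: force one member by restricting via rra on a
        # minimal table instead; simplest: single not-acquired with lone lost
        ft2 = make_fate_table({"L1": "lost", "A1": "acquired", "N1": "not_acquired"})
        mean, sd = exhaustive_null(ft2, toy_tree, "helminth", "random_acquisition")
        assert sd == pytest.approx(0.0)  # lone lost drops out; pool = {N1}

    def test_guard_trips_on_large_enumeration(self, toy_tree):
        fates = {f"a{i}": "acquired" for i in range(12)}
        fates.update({"L1": "lost", "L2": "lost"})
        fates.update({f"n{i}": "not_acquired" for i in range(10)})
        taxa = [tax(sp) for sp in fates]
        tree = build_tree(taxa)
        ft = make_fate_table(fates)
        with pytest.raises(CombinatorialGuardError):
            exhaustive_null(ft, tree, "helminth", "random_acquisition", guard=10**4)

    def test_matches_closed_form_mean_of_iid_draws(self, toy_tree):
        # independent route: mean of k iid draws from the profile multiset has
        # mean = mean(m) and sd = popsd(m)/sqrt(k)
        ft = make_fate_table(
            {"L1": "lost", "L2": "lost", "A1": "acquired", "N1": "acquired",
             "N2": "not_acquired", "N3": "not_acquired"}
        )
        m = _null_profile(ft, toy_tree, "helminth", "random_acquisition")
        k = 2  # |acquired|
        mean, sd = exhaustive_null(ft, toy_tree, "helminth", "random_acquisition")
        assert mean == pytest.approx(float(np.mean(m)))
        assert sd == pytest.approx(float(np.std(m)) / math.sqrt(k))


class TestSampledNulls:
    def test_sampled_converges_to_exhaustive_three_outcome_pool(self, toy_tree):
        # pool of 3 usable members, |acquired| = 1: sampled moments must sit
        # within 3 standard errors of the exact enumeration at 1000 draws
        ft = make_fate_table(
            {"L1": "lost", "L2": "lost", "A1": "acquired",
             "N1": "not_acquired", "N2": "not_acquired", "N3": "not_acquired"}
        )
        exact_mean, exact_sd = exhaustive_null(
            ft, toy_tree, "helminth", "random_acquisition"
        )
        res = random_acquisition_null(ft, toy_tree, "helminth", n_draws=1000, seed=5)
        se = exact_sd / math.sqrt(res.n_draws)
        assert abs(res.null_mean - exact_mean) < 3 * se
        assert res.null_sd == pytest.approx(exact_sd, rel=0.15)

    def test_large_draws_match_exhaustive_mean(self, toy_tree):
        ft = make_fate_table(
            {"L1": "lost", "L2": "lost", "A1": "acquired", "N2": "acquired",
             "N1": "not_acquired", "N3": "not_acquired"}
        )
        exact_mean, exact_sd = exhaustive_null(
            ft, toy_tree, "helminth", "random_acquisition"
        )
        res = random_acquisition_null(ft, toy_tree, "helminth", n_draws=10**5, seed=9)
        assert abs(res.null_mean - exact_mean) < 3 * exact_sd / math.sqrt(10**5)

    def test_determinism_same_seed_same_result(self, toy_tree, toy_fate_table):
        a = random_acquisition_null(toy_fate_table, toy_tree, "helminth", seed=3)
        b = random_acquisition_null(toy_fate_table, toy_tree, "helminth", seed=3)
        assert a == b
        c = rra_null(toy_fate_table, toy_tree, "helminth", seed=3)
        d = rra_null(toy_fate_table, toy_tree, "helminth", seed=3)
        assert c == d

    def test_degenerate_null_flagged_not_zero(self):
        # every pool member equidistant from the lost set -> constant null
        taxa = [tax("L", genus="G1"), tax("A", genus="G1"),
                tax("X", genus="G1"), tax("Y", genus="G1")]
        tree = build_tree(taxa)
        ft = make_fate_table(
            {"L": "lost", "A": "acquired", "X": "not_acquired", "Y": "not_acquired"}
        )
        res = random_acquisition_null(ft, tree, "helminth", n_draws=200, seed=1)
        assert res.degenerate and math.isnan(res.z_score)

    def test_not_computable_raises(self, toy_tree):
        ft = make_fate_table({"L1": "lost", "N1": "not_acquired"})
        with pytest.raises(NotComputableError):
            random_acquisition_null(ft, toy_tree, "helminth", seed=0)

    def test_draws_must_be_positive(self, toy_tree, toy_fate_table):
        with pytest.raises(ValidationError):
            random_acquisition_null(toy_fate_table, toy_tree, "helminth", n_draws=0)

    def test_rra_pool_is_known_associations(self, toy_tree, toy_fate_table):
        m_rra = _null_profile(toy_fate_table, toy_tree, "helminth", "rra")
        # retained + lost + acquired = {R1, L1, L2, A1}; all have self-excluded
        # min distances to {L1, L2}
        assert len(m_rra) == 4

    def test_rra_null_uses_known_association_profiles(self):
        # hand-checkable RRA pool: A1 and R1 are congeners of the two lost
        # species (distance 2); each lost species is distance 4 from the other
        taxa = [tax("L1", genus="G1"), tax("L2", genus="G2"),
                tax("A1", genus="G1"), tax("R1", genus="G2")]
        tree = build_tree(taxa)
        ft = make_fate_table(
            {"L1": "lost", "L2": "lost", "A1": "acquired", "R1": "retained"}
        )
        # profiles: A1->2, R1->2, L1->4, L2->4; observed = 2, null mean -> 3
        res = rra_null(ft, tree, "helminth", n_draws=2000, seed=2)
        assert res.observed_stat == pytest.approx(2.0)
        exact_mean, exact_sd = exhaustive_null(ft, tree, "helminth", "rra")
        assert exact_mean == pytest.approx(3.0) and exact_sd == pytest.approx(1.0)
        assert abs(res.null_mean - exact_mean) < 3 * exact_sd / math.sqrt(2000)


class TestSignificance:
    @pytest.mark.parametrize(
        "z,expected", [(-2.0, True), (-1.645, False), (3.0, False)]
    )
    def test_one_tailed_strict_threshold(self, z, expected):
        r = NullModelResult(
            focal_host="H", parasite_type="helminth", model="rra",
            true_min_pds=(2,), observed_stat=2.0, null_mean=3.0, null_sd=1.0,
            z_score=z, quantile=0.5, n_draws=100, seed=0,
        )
        (flagged,) = flag_significant([r])
        assert flagged.significant is expected

    def test_degenerate_never_significant(self):
        r = NullModelResult(
            focal_host="H", parasite_type="helminth", model="rra",
            true_min_pds=(2,), observed_stat=2.0, null_mean=2.0, null_sd=0.0,
            z_score=float("nan"), quantile=1.0, n_draws=100, seed=0,
            degenerate=True,
        )
        (flagged,) = flag_significant([r])
        assert flagged.significant is False

    def test_threshold_value(self):
        assert one_tailed_threshold() == -1.645 == Z_THRESHOLD


def _result(z, n_comp):
    return NullModelResult(
        focal_host="H", parasite_type="helminth", model="rra",
        true_min_pds=tuple([2] * n_comp), observed_stat=2.0, null_mean=3.0,
        null_sd=1.0, z_score=z, quantile=0.5, n_draws=100, seed=0,
    )


class TestZvsNComparisons:
    def test_perfect_monotone_decrease(self):
        results = [_result(z=-float(i), n_comp=i) for i in range(1, 6)]
        rho, p = z_vs_ncomparisons(results)
        assert rho == pytest.approx(-1.0)

    def test_constant_z_flagged_nan(self):
        results = [_result(z=1.0, n_comp=i) for i in range(1, 6)]
        with pytest.warns(UserWarning, match="constant"):
            rho, p = z_vs_ncomparisons(results)
        assert math.isnan(rho)

    def test_too_few_results_rejected(self):
        with pytest.raises(ValidationError):
            z_vs_ncomparisons([_result(-1.0, 3), _result(-2.0, 4)])

    def test_random_permutations_give_small_rho_on_average(self):
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(50):
            z = rng.permutation(20).astype(float)
            results = [_result(zi, i + 1) for i, zi in enumerate(z)]
            rho, _ = z_vs_ncomparisons(results)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1


class TestRunNullModels:
    def test_full_run_and_skip_accounting(self, toy_tree, toy_fate_table):
        results, skipped = run_null_models(
            toy_fate_table, {"helminth": toy_tree}, seed=4
        )
        assert {r.model for r in results} == {"random_acquisition", "rra"}
        assert all(r.significant is not None for r in results)
        assert skipped == []

    def test_missing_type_reported_as_skipped(self, toy_tree):
        ft = make_fate_table({"L1": "lost", "N1": "not_acquired"})  # nothing acquired
        results, skipped = run_null_models(ft, {"helminth": toy_tree}, seed=4)
        assert results == [] and len(skipped) == 2

    def test_reproducible_under_master_seed(self, toy_tree, toy_fate_table):
        r1, _ = run_null_models(toy_fate_table, {"helminth": toy_tree}, seed=7)
        r2, _ = run_null_models(toy_fate_table, {"helminth": toy_tree}, seed=7)
        assert r1 == r2
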