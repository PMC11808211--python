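"""Enemy-release statistics: beta partition, PSR change, paired test,
environmental dissimilarity, single-predictor regressions."""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vacniche.enemy import (
    beta_partition,
    environmental_dissimilarity,
    phylo_paired_ttest,
    psr_change,
    simple_regressions,
)
from vacniche.types import EmptySetError, SchemaError, ValidationError


class TestPsrChange:
    def test_red_deer_proportional_change(self):
        assert psr_change(104, 31) == pytest.approx(1 - 31 / 104)

    def test_equal_richness_gives_zero(self):
        assert psr_change(50, 50) == 0.0

    def test_total_loss_gives_one(self):
        assert psr_change(12, 0) == 1.0

    def test_zero_native_rejected(self):
        with pytest.raises(ValidationError):
            psr_change(0, 5)

    def test_antitone_in_nonnative(self):
        vals = [psr_change(100, nn) for nn in range(0, 101, 10)]
        assert vals == sorted(vals, reverse=True)


class TestBetaPartition:
    def test_identical_sets_zero_flagged(self):
        with pytest.warns(UserWarning, match="proportions undefined"):
            part = beta_partition({"a", "b"}, {"a", "b"})
        assert part.beta_sor == part.beta_sim == part.beta_sne == 0.0
        assert not part.proportions_defined

    def test_disjoint_sets_pure_turnover(self):
        part = beta_partition({"a", "b"}, {"c", "d"})
        assert part.beta_sor == 1.0 and part.beta_sim == 1.0 and part.beta_sne == 0.0

    def test_red_deer_worked_example(self):
        # a = 17 shared, b = 87 native-only, c = 14 non-native-only
        native = {f"s{i}" for i in range(17)} | {f"b{i}" for i in range(87)}
        nonnative = {f"s{i}" for i in range(17)} | {f"c{i}" for i in range(14)}
        part = beta_partition(native, nonnative)
        assert part.beta_sor == pytest.approx(101 / 135)
        assert part.beta_sim == pytest.approx(14 / 31)
        assert part.beta_sne == pytest.approx(101 / 135 - 14 / 31)

    def test_both_empty_rejected(self):
        with pytest.raises(EmptySetError):
            beta_partition(set(), set())

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        a=st.integers(0, 30), b=st.integers(0, 30), c=st.integers(0, 30)
    )
    def test_conservation_and_proportions(self, a, b, c):
        if a + b == 0:  # native set must be non-empty
            return
        native = {f"s{i}" for i in range(a)} | {f"b{i}" for i in range(b)}
        nonnative = {f"s{i}" for i in range(a)} | {f"c{i}" for i in range(c)}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = beta_partition(native, nonnative)
        assert part.beta_sor == pytest.approx(part.beta_sim + part.beta_sne)
        assert 0 <= part.beta_sim <= part.beta_sor <= 1
        if part.beta_sor > 0:
            assert part.turnover_prop + part.nestedness_prop == pytest.approx(1.0)


@pytest.fixture(scope="module")
def host_tree():
    nwk = "((A:1.0,B:1.0):2.0,((C:0.5,D:0.5):1.5,(E:1.2,F:1.2):0.8):1.0);"
    return dendropy.Tree.get(data=nwk, schema="newick")


PSR_NATIVE = dict(A=104, B=126, C=58, D=76, E=127, F=90)
PSR_NONNATIVE = dict(A=31, B=18, C=22, D=16, E=38, F=40)


class TestPhyloPairedTTest:
    def test_lambda_zero_reduces_to_classical_paired_t(self, host_tree):
        res = phylo_paired_ttest(PSR_NATIVE, PSR_NONNATIVE, host_tree, lam=0.0)
        d = np.array([PSR_NATIVE[h] - PSR_NONNATIVE[h] for h in sorted(PSR_NATIVE)])
        t_classical = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t_classical, abs=1e-10)
        assert res.mean_diff == pytest.approx(d.mean(), abs=1e-10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_lambda_zero_reduction_holds_for_random_data(self, host_tree, seed):
        rng = np.random.default_rng(seed)
        hosts = sorted(PSR_NATIVE)
        x1 = dict(zip(hosts, rng.normal(50, 10, size=6)))
        x2 = dict(zip(hosts, rng.normal(30, 10, size=6)))
        res = phylo_paired_ttest(x1, x2, host_tree, lam=0.0)
        d = np.array([x1[h] - x2[h] for h in hosts])
        t_classical = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.t == pytest.approx(t_classical, rel=1e-9)

    def test_matches_phytools_ml_fit(self, host_tree):
        # frozen oracle: phytools::phyl.pairedttest on this exact fixture
        # (R, lambda profiled by ML) gives t = 6.6058447, dbar = 70.1138686,
        # sig2 = 192.9611399, lambda = 0.1485909, p = 0.0070627, df = 3
        res = phylo_paired_ttest(
            PSR_NATIVE, PSR_NONNATIVE, host_tree, variance="ml"
        )
        assert res.t == pytest.approx(6.6058447196, rel=1e-3)
        assert res.mean_diff == pytest.approx(70.1138686288, rel=1e-3)
        assert res.sigma2 == pytest.approx(192.9611398606, rel=1e-3)
        assert res.lambda_hat == pytest.approx(0.1485908937, abs=2e-4)
        assert res.p == pytest.approx(0.0070626718, rel=1e-3)
        assert res.df == 3

    def test_matches_phytools_at_fixed_lambda_one(self, host_tree):
        # frozen oracle: fixed lambda = 1 -> t = 3.7326689, dbar = 72.6428558,
        # p = 0.0202498 on df = n - 2
        res = phylo_paired_ttest(
            PSR_NATIVE, PSR_NONNATIVE, host_tree, lam=1.0, variance="ml"
        )
        assert res.t == pytest.approx(3.7326688709, rel=1e-6)
        assert res.mean_diff == pytest.approx(72.6428557991, rel=1e-6)
        assert res.p == pytest.approx(0.0202497770, rel=1e-4)
        assert res.df == 4

    def test_p_consistent_with_t_and_df(self, host_tree):
        res = phylo_paired_ttest(PSR_NATIVE, PSR_NONNATIVE, host_tree)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), res.df))
        assert res.df == len(PSR_NATIVE) - 3

    def test_equal_differences_degenerate(self, host_tree):
        x1 = {h: 10.0 for h in PSR_NATIVE}
        x2 = {h: 4.0 for h in PSR_NATIVE}
        with pytest.raises(ValidationError, match="zero variance"):
            phylo_paired_ttest(x1, x2, host_tree)

    def test_too_few_hosts_rejected(self):
        nwk = "((A:1,B:1):1,C:2);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        with pytest.raises(ValidationError, match="at least 4"):
            phylo_paired_ttest(dict(A=1, B=2, C=3), dict(A=0, B=0, C=1), tree)


class TestEnvironmentalDissimilarity:
    def _frame(self, rows, cols=("bio1", "bio2")):
        return pd.DataFrame(rows, columns=list(cols))

    def test_identical_single_rows_zero(self):
        a = self._frame([[3.0, 7.0]])
        b = self._frame([[3.0, 7.0]])
        with pytest.warns(UserWarning, match="constant"):
            with pytest.raises(ValidationError):
                environmental_dissimilarity(a, b)
        # with a second, distinct variable pair the distance is defined and 0
        a = self._frame([[0.0, 1.0], [1.0, 0.0]])
        assert environmental_dissimilarity(a, a.copy()) == pytest.approx(0.5)

    def test_extreme_rows_maximally_dissimilar(self):
        a = self._frame([[0.0, 0.0]])
        b = self._frame([[1.0, 1.0]])
        assert environmental_dissimilarity(a, b) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # scaled rows: native (1,0); non-native (0,1) and (0.5, 0.5)
        # BC((1,0),(0,1)) = 1 ; BC((1,0),(0.5,0.5)) = 0.5 ; mean = 0.75
        native = self._frame([[1.0, 0.0]])
        nonnative = self._frame([[0.0, 1.0], [0.5, 0.5]])
        assert environmental_dissimilarity(native, nonnative) == pytest.approx(0.75)

    def test_symmetry_and_row_order_invariance(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(4, 5)), columns=[f"bio{i}" for i in range(5)])
        b = pd.DataFrame(rng.normal(size=(3, 5)), columns=[f"bio{i}" for i in range(5)])
        d1 = environmental_dissimilarity(a, b)
        assert environmental_dissimilarity(b, a) == pytest.approx(d1)
        assert environmental_dissimilarity(
            a.sample(frac=1, random_state=0), b
        ) == pytest.approx(d1)

    def test_disjoint_variables_rejected(self):
        a = self._frame([[1.0, 2.0]], cols=("bio1", "bio2"))
        b = self._frame([[1.0, 2.0]], cols=("bio3", "bio4"))
        with pytest.raises(SchemaError):
            environmental_dissimilarity(a, b)


class TestSimpleRegressions:
    def _table(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "psr_change": rng.uniform(0, 1, n),
                "turnover_prop": rng.uniform(0, 1, n),
                "nestedness_prop": rng.uniform(0, 1, n),
                "beta_sor": rng.uniform(0, 1, n),
                "time_since_invasion": rng.uniform(50, 300, n),
                "population_density": rng.uniform(1, 10, n),
                "home_range_area": rng.uniform(0.5, 20, n),
                "environmental_dissimilarity": rng.uniform(0, 1, n),
            }
        )
        return df

    def test_sixteen_fits_with_log_home_range(self):
        out = simple_regressions(self._table())
        assert len(out) == 16
        assert set(out["predictor"]).issuperset({"log_home_range"})
        assert out["p"].between(0, 1).all()

    def test_exact_line_recovered(self):
        df = self._table()
        df["psr_change"] = 2.0 * df["time_since_invasion"]
        out = simple_regressions(df)
        row = out[(out.response == "psr_change") & (out.predictor == "time_since_invasion")]
        assert row["slope"].iloc[0] == pytest.approx(2.0)
        assert row["p"].iloc[0] < 1e-10

    def test_independent_response_slope_near_zero_on_average(self):
        slopes = []
        for seed in range(40):
            out = simple_regressions(self._table(seed=seed))
            row = out[(out.response == "beta_sor") & (out.predictor == "environmental_dissimilarity")]
            slopes.append(row["slope"].iloc[0])
        assert abs(np.mean(slopes)) < 0.2

    def test_constant_predictor_flagged(self):
        df = self._table()
        df["population_density"] = 3.0
        out = simple_regressions(df)
        flagged = out[out.predictor == "population_density"]
        assert (flagged["flag"] == "constant_predictor").all()
        assert flagged["slope"].isna().all()

    def test_two_hosts_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            simple_regressions(self._table(n=2))

    def test_nonpositive_home_range_rejected(self):
        df = self._table()
        df.loc[0, "home_range_area"] = 0.0
        with pytest.raises(ValidationError, match="positive"):
            simple_regressions(df)
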