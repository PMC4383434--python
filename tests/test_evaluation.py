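import dataclasses
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentalcbr.case_model import CaseBase
from dentalcbr.evaluation import (
    ErrorTable,
    TieError,
    compare_methods,
    five_by_two_cv,
    leave_one_out_error,
    mann_whitney_exact,
    report_average_duration,
    report_failure_rates,
    report_yearly_usage,
)
from dentalcbr.synthetic_data import default_paper_like_config, generate_casebase

TABLE6 = {
    "Initial CBR": [0.67, 0.72, 0.82, 0.63, 0.73],
    "Proposal": [0.41, 0.54, 0.38, 0.38, 0.45],
    "MLP": [0.85, 0.95, 0.80, 1.06, 0.79],
    "RBF": [1.01, 0.84, 0.87, 1.10, 0.81],
}


def brute_force_p(x, y):
    """Enumerate every C(n1+n2, n1) rank arrangement of the pooled sample."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    n1 = len(x)
    U_obs = float((np.asarray(x)[:, None] > np.asarray(y)[None, :]).sum())
    ranks = np.argsort(np.argsort(pooled))  # distinct values -> unique ranks
    count = 0
    total = 0
    for x_pos in itertools.combinations(range(n), n1):
        x_ranks = sorted(ranks[list(x_pos)])
        u = sum(r - i for i, r in enumerate(x_ranks))
        total += 1
        if u <= U_obs:
            count += 1
    return count / total


class TestMannWhitneyExact:
    def test_published_comparison_values(self):
        _, p1 = mann_whitney_exact(TABLE6["Proposal"], TABLE6["Initial CBR"])
        assert round(p1, 4) == 0.0040
        _, p2 = mann_whitney_exact(TABLE6["Initial CBR"], TABLE6["MLP"])
        assert round(p2, 4) == 0.0159

    def test_tiny_enumeration(self):
        U, p = mann_whitney_exact([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 6)

    def test_complete_separation_five_vs_five(self):
        _, p = mann_whitney_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(1 / comb(10, 5))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n1=st.integers(1, 6),
        n2=st.integers(1, 6),
        seed=st.integers(0, 10**6),
    )
    def test_agrees_with_brute_force_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        values = rng.permutation(1000)[: n1 + n2].astype(float)
        x, y = values[:n1], values[n1:]
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(brute_force_p(x, y), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n1=st.integers(2, 6), n2=st.integers(2, 6), seed=st.integers(0, 10**6))
    def test_pairwise_identity(self, n1, n2, seed):
        """P(A,B) + P(B,A) = 1 + Pr_null(U = U_obs) for every pair."""
        rng = np.random.default_rng(seed)
        values = rng.permutation(1000)[: n1 + n2].astype(float)
        x, y = values[:n1], values[n1:]
        _, p_xy = mann_whitney_exact(x, y)
        _, p_yx = mann_whitney_exact(y, x)
        pr_equal = p_xy - _p_leq_minus_one(x, y)  # Pr_null(U = U_obs)
        assert p_xy + p_yx == pytest.approx(1.0 + pr_equal, abs=1e-12)

    def test_cross_sample_ties_raise(self):
        with pytest.raises(TieError):
            mann_whitney_exact([1.0, 2.0], [2.0, 3.0])

    def test_within_sample_ties_allowed(self):
        _, p = mann_whitney_exact([1.0, 1.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 6)

    def test_permutation_fallback_with_ties(self):
        U, p = mann_whitney_exact([1.0, 2.0], [2.0, 3.0], permutation=True, seed=1)
        assert U == pytest.approx(0.5)
        assert 0.0 < p <= 1.0

    def test_matches_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(1, 8, 2)
            v = rng.permutation(500)[: n1 + n2].astype(float)
            x, y = v[:n1], v[n1:]
            _, p = mann_whitney_exact(x, y)
            ref = mannwhitneyu(x, y, alternative="less", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)


def _p_leq_minus_one(x, y):
    """P(U <= U_obs - 1) by brute force (0 when U_obs == 0)."""
    U = float((np.asarray(x)[:, None] > np.asarray(y)[None, :]).sum())
    if U == 0:
        return 0.0
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled))
    n1 = len(x)
    count = total = 0
    for pos in itertools.combinations(range(len(pooled)), n1):
        u = sum(r - i for i, r in enumerate(sorted(ranks[list(pos)])))
        total += 1
        if u <= U - 1:
            count += 1
    return count / total


class TestCompareMethods:
    def test_reproduces_published_matrix(self):
        table = ErrorTable(pd.DataFrame(TABLE6).T)
        got = compare_methods(table).round(4)
        expected = pd.DataFrame(
            [
                [np.nan, 1.0000, 0.0159, 0.0079],
                [0.0040, np.nan, 0.0040, 0.0040],
                [0.9921, 1.0000, np.nan, 0.2738],
                [0.9960, 1.0000, 0.7897, np.nan],
            ],
            index=list(TABLE6),
            columns=list(TABLE6),
        )
        pd.testing.assert_frame_equal(got, expected)

    def test_dominated_method_hits_floor(self):
        table = ErrorTable(
            pd.DataFrame({"good": [1, 2, 3, 4, 5], "bad": [6, 7, 8, 9, 10]}).T
        )
        m = compare_methods(table)
        assert m.loc["good", "bad"] == pytest.approx(1 / comb(10, 5))

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(ErrorTable(pd.DataFrame({"only": [1.0, 2.0]}).T))

    def test_negative_errors_rejected(self):
        with pytest.raises(ValueError):
            ErrorTable(pd.DataFrame({"m": [-1.0]}).T)


@pytest.fixture(scope="module")
def medium_casebase():
    return generate_casebase(default_paper_like_config(17, n_cases=600))[0]


class TestFiveByTwoCV:
    def test_oracle_method_has_zero_error(self, medium_casebase):
        factories = {"oracle": lambda train: (lambda case: case.restoration_longevity)}
        table = five_by_two_cv(medium_casebase, factories, seed=0)
        assert np.allclose(table.values.to_numpy(), 0.0)

    def test_constant_predictor_mean_absolute_deviation(self):
        # longevities ~ N(10, 1): predicting the mean gives E|X-10| = sqrt(2/pi)
        cb, _ = generate_casebase(default_paper_like_config(23, n_cases=2000))
        rng = np.random.default_rng(0)
        cases = [
            dataclasses.replace(c, restoration_longevity=float(rng.normal(10.0, 1.0)))
            for c in cb.cases
        ]
        cb = CaseBase(cases, cb.reference_date)
        factories = {"const": lambda train: (lambda case: 10.0)}
        table = five_by_two_cv(cb, factories, seed=1)
        expected = np.sqrt(2 / np.pi)
        for v in table.values.loc["const"]:
            assert v == pytest.approx(expected, abs=0.1)

    def test_deterministic_given_seed(self, medium_casebase):
        factories = {
            "mean": lambda train: (lambda case: float(np.mean(train.longevities())))
        }
        a = five_by_two_cv(medium_casebase, factories, seed=5)
        b = five_by_two_cv(medium_casebase, factories, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestLeaveOneOut:
    def _builder(self):
        from dentalcbr.cbr_engine import EngineConfig, build_knowledge_base

        return lambda cb: build_knowledge_base(cb, EngineConfig(k_fixed=1), seed=0)

    def test_identical_longevities_give_zero_error(self):
        cb, _ = generate_casebase(default_paper_like_config(29, n_cases=25))
        cases = [
            dataclasses.replace(c, restoration_type="composite", restoration_longevity=10.0)
            for c in cb.cases
        ]
        cb = CaseBase(cases, cb.reference_date)
        assert leave_one_out_error(cb, self._builder()) == pytest.approx(0.0)

    def test_two_case_cross_prediction(self):
        cb, _ = generate_casebase(default_paper_like_config(31, n_cases=2))
        cases = [
            dataclasses.replace(c, restoration_type="composite", restoration_longevity=lon)
            for c, lon in zip(cb.cases, (8.0, 12.0))
        ]
        cb = CaseBase(cases, cb.reference_date)
        # each case is predicted as the other -> both absolute errors are 4
        assert leave_one_out_error(cb, self._builder()) == pytest.approx(4.0)

    def test_empty_filter_rejected(self, medium_casebase):
        only_composite = CaseBase(
            [c for c in medium_casebase.cases if c.restoration_type == "composite"],
            medium_casebase.reference_date,
        )
        with pytest.raises(ValueError, match="filter"):
            leave_one_out_error(only_composite, self._builder(), type_filter="amalgam")


class TestReports:
    def _casebase_with(self, spec):
        """spec: list of (year, type, longevity)."""
        cb, _ = generate_casebase(default_paper_like_config(37, n_cases=len(spec)))
        import datetime as dt

        cases = []
        for i, (c, (year, rtype, lon)) in enumerate(zip(cb.cases, spec)):
            cases.append(
                dataclasses.replace(
                    c,
                    patient_number=i + 1,
                    restoration_date=dt.date(year, 6, 15),
                    date_of_birth=dt.date(year - 30, 1, 1),
                    prior_restoration_date=dt.date(year - 5, 1, 1),
                    restoration_type=rtype,
                    restoration_longevity=lon,
                )
            )
        return CaseBase(cases, cb.reference_date)

    def test_usage_percentages(self):
        spec = [(2003, "composite", 10.0)] * 93 + [(2003, "amalgam", 15.0)] * 7
        usage = report_yearly_usage(self._casebase_with(spec))
        assert usage.loc[2003, "composite"] == pytest.approx(93.0)
        assert usage.loc[2003, "amalgam"] == pytest.approx(7.0)

    def test_single_case_usage(self):
        usage = report_yearly_usage(self._casebase_with([(2005, "composite", 9.0)]))
        assert usage.loc[2005, "composite"] == pytest.approx(100.0)
        assert usage.loc[2005, "amalgam"] == pytest.approx(0.0)

    def test_usage_rows_sum_to_hundred(self, medium_casebase):
        usage = report_yearly_usage(medium_casebase)
        assert np.allclose(usage.sum(axis=1), 100.0)

    def test_average_duration_values(self):
        spec = [(2004, "amalgam", 16.0), (2004, "amalgam", 14.0), (2004, "composite", 9.0)]
        dur = report_average_duration(self._casebase_with(spec))
        assert dur.loc[2004, "amalgam"] == pytest.approx(15.0)
        assert dur.loc[2004, "composite"] == pytest.approx(9.0)

    def test_average_duration_matches_groupby_oracle(self, medium_casebase):
        dur = report_average_duration(medium_casebase)
        df = pd.DataFrame(
            {
                "year": medium_casebase.years(),
                "type": medium_casebase.types(),
                "lon": medium_casebase.longevities(),
            }
        )
        for (year, rtype), grp in df.groupby(["year", "type"]):
            assert dur.loc[year, rtype] == pytest.approx(grp["lon"].mean())

    def test_failure_threshold_strict(self):
        # type mean 16 -> threshold 8; 7 fails, exactly 8 does not
        spec = (
            [(2003, "amalgam", 7.0), (2004, "amalgam", 8.0)]
            + [(2005, "amalgam", 24.5), (2006, "amalgam", 24.5)]
            + [(2003, "composite", 10.0)]
        )
        rates = report_failure_rates(self._casebase_with(spec))
        assert rates.loc[2003, "amalgam"] == pytest.approx(100.0)
        assert rates.loc[2004, "amalgam"] == pytest.approx(0.0)

    def test_failure_rates_match_oracle(self, medium_casebase):
        rates = report_failure_rates(medium_casebase)
        lons = medium_casebase.longevities()
        types = medium_casebase.types()
        years = medium_casebase.years()
        for rtype in ("composite", "amalgam"):
            threshold = 0.5 * lons[types == rtype].mean()
            for year in np.unique(years[types == rtype]):
                mask = (types == rtype) & (years == year)
                want = 100.0 * np.mean(lons[mask] < threshold)
                assert rates.loc[year, rtype] == pytest.approx(want)
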