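import numpy as np
import pandas as pd
import pytest

from cox_oracle import grid_search_beta
from sfdkit import (
    Endpoint,
    NoOverlappingGenesError,
    ProteinSet,
    cox_univariate,
    filter_cohort,
    km_median,
    screen,
)
from sfdkit.survival import transform_expression, validate_clinical

# small fixtures for the grid-search oracle comparison (n <= 8, with and
# without ties/censoring)
ORACLE_FIXTURES = [
    ([1, 0, 1, 0], [1, 2, 3, 4], [1, 1, 1, 1]),
    ([0.5, 1, 0, 2, 1, 0], [3, 3, 5, 2, 2, 4], [1, 1, 0, 1, 1, 1]),  # ties
    ([2, 1, 0, 1], [4, 3, 2, 1], [0, 1, 1, 1]),
    ([-1, 0.5, 2, -0.3, 1.2], [2, 2, 2, 5, 7], [1, 1, 1, 0, 1]),  # triple tie
    ([0, 1, 0, 1, 1, 0, 1, 0], [1, 1, 2, 2, 3, 3, 4, 4], [1, 0, 1, 1, 0, 1, 1, 1]),
]


@pytest.mark.parametrize("x, t, d", ORACLE_FIXTURES)
def test_cox_beta_matches_grid_search_oracle(x, t, d):
    """Fitted beta maximizes the Efron partial likelihood (|Δ| ≤ 1e-3)."""
    x, t, d = map(np.asarray, (x, t, d))
    oracle = grid_search_beta(x, t, d)
    result = cox_univariate(x, t, d, check_proportionality=False)
    assert not result.degenerate
    assert abs(result.beta - oracle) <= 1e-3


def test_cox_frozen_fixture_value():
    """Alternating covariate, four events: beta frozen from the grid oracle."""
    result = cox_univariate(
        np.array([1.0, 0, 1, 0]), np.array([1.0, 2, 3, 4]), np.ones(4),
        check_proportionality=False,
    )
    assert result.beta == pytest.approx(0.9406, abs=1e-3)
    assert result.hr == pytest.approx(np.exp(result.beta))
    assert result.ci_low <= result.hr <= result.ci_high


def test_constant_covariate_degenerate_contract():
    result = cox_univariate(np.ones(6), np.arange(1.0, 7), np.ones(6))
    assert result.degenerate
    assert result.beta == 0.0
    assert np.isnan(result.ci_low) and np.isnan(result.p)
    assert "constant" in result.reason


def test_fewer_than_two_events_flagged_not_raised():
    result = cox_univariate(
        np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), np.array([1.0, 0, 0])
    )
    assert result.degenerate and "events" in result.reason
    assert np.isnan(result.prop_p)  # Schoenfeld check skipped


def test_scale_equivariance_and_location_invariance():
    rng = np.random.default_rng(3)
    z = rng.standard_normal(40)
    t = rng.exponential(1 / (0.1 * np.exp(0.5 * z)))
    d = np.ones(40)
    base = cox_univariate(z, t, d, check_proportionality=False).beta
    scaled = cox_univariate(3 * z, t, d, check_proportionality=False).beta
    shifted = cox_univariate(z + 10, t, d, check_proportionality=False).beta
    assert scaled == pytest.approx(base / 3, rel=1e-4)
    assert shifted == pytest.approx(base, rel=1e-4)


class TestSchoenfeld:
    def test_nominal_level_under_proportional_hazards(self):
        rng = np.random.default_rng(11)
        flags = 0
        reps = 60
        for _ in range(reps):
            z = rng.standard_normal(150)
            t = rng.exponential(1 / (0.05 * np.exp(0.5 * z)))
            c = rng.uniform(0, 40, 150)
            r = cox_univariate(z, np.minimum(t, c), (t <= c).astype(float))
            flags += r.prop_violation
        assert flags / reps <= 0.10  # ~5% nominal plus Monte-Carlo slack

    def test_power_under_crossing_hazards(self):
        """An effect that reverses mid-follow-up is flagged well above nominal."""
        rng = np.random.default_rng(12)
        flags = 0
        reps = 20
        for _ in range(reps):
            z = rng.standard_normal(300)
            early, late, switch = 0.1 * np.exp(z), 0.1 * np.exp(-z), 7.0
            e = rng.exponential(1.0, 300)
            t = np.where(e < early * switch, e / early, switch + (e - early * switch) / late)
            r = cox_univariate(z, t, np.ones(300))
            flags += r.prop_violation
        assert flags / reps >= 0.5


class TestKmMedian:
    def test_all_censored_not_reached(self):
        assert km_median([1, 2, 3], [0, 0, 0]) is None

    def test_three_events_median_is_two(self):
        assert km_median([1, 2, 3], [1, 1, 1]) == 2

    def test_curve_touching_half_is_not_reached(self):
        assert km_median([5, 10], [1, 0]) is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_median([], [])


def make_cohort(rng, n=80, beta=1.2):
    z = rng.standard_normal(n)
    t = rng.exponential(1 / (0.05 * np.exp(beta * z)))
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "sample_type": "primary",
            "os_time": t,
            "os_event": 1,
            "dfs_time": t,
            "dfs_event": 1,
        }
    )
    expr = pd.DataFrame(
        {f"P{i}": [2 ** (z[i] + 8) - 1, rng.uniform(0, 100)] for i in range(n)},
        index=["RISKY", "NOISE"],
    )
    return expr, clinical


class TestScreen:
    def test_screen_reports_unavailable_and_sorts_by_p(self, rng):
        expr, clinical = make_cohort(rng)
        candidates = ProteinSet.from_symbols("c", ["RISKY", "NOISE", "ABSENT"])
        out = screen(candidates, expr, clinical, Endpoint.OS)
        assert out.unavailable == ["ABSENT"]
        assert [r.gene for r in out.results] == ["RISKY", "NOISE"]
        assert out.results[0].p < out.results[1].p
        assert out.results[0].hr > 1
        qs = [r.q for r in out.results]
        assert all(np.isfinite(qs)) and qs[0] >= out.results[0].p

    def test_disjoint_candidates_rejected(self, rng):
        expr, clinical = make_cohort(rng)
        with pytest.raises(NoOverlappingGenesError):
            screen(ProteinSet.from_symbols("c", ["NOPE"]), expr, clinical)

    def test_dfs_endpoint_drops_missing_records_pairwise(self, rng):
        expr, clinical = make_cohort(rng)
        clinical.loc[:9, ["dfs_time", "dfs_event"]] = np.nan
        out = screen(
            ProteinSet.from_symbols("c", ["RISKY"]), expr, clinical, Endpoint.DFS
        )
        assert out.results[0].n == len(clinical) - 10


def test_filter_cohort_by_sample_type():
    clinical = pd.DataFrame(
        {
            "patient_id": list("abcde"),
            "sample_type": ["primary"] * 3 + ["metastatic"] * 2,
            "os_time": 1.0,
            "os_event": 1,
            "dfs_time": 1.0,
            "dfs_event": 0,
        }
    )
    assert len(filter_cohort(clinical, "primary")) == 3
    assert len(filter_cohort(clinical, "metastatic")) == 2
    assert filter_cohort(clinical, "xenograft").empty


class TestClinicalContract:
    def base(self):
        return pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "sample_type": "primary",
                "os_time": [1.0, 2.0],
                "os_event": [1, 0],
                "dfs_time": [1.0, np.nan],
                "dfs_event": [1, np.nan],
            }
        )

    def test_valid_table_passes(self):
        validate_clinical(self.base())

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda df: df.assign(os_time=[-1.0, 2.0]),
            lambda df: df.assign(os_event=[2, 0]),
            lambda df: df.assign(dfs_event=[np.nan, 1]),  # jointly-missing violated
            lambda df: df.assign(patient_id=["a", "a"]),
            lambda df: df.drop(columns=["sample_type"]),
        ],
    )
    def test_contract_violations_rejected(self, mutate):
        with pytest.raises(ValueError):
            validate_clinical(mutate(self.base()))


def test_transform_is_log2_then_zscore():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    out = transform_expression(x)
    expected = np.log2(x + 1)
    expected = (expected - expected.mean()) / expected.std(ddof=1)
    np.testing.assert_allclose(out, expected)
    assert np.all(transform_expression(np.full(5, 9.0)) == 0)
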