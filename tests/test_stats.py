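import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.spatial.distance import jensenshannon

from hepix.errors import (
    ConfigError,
    DataError,
    EmptyStratumError,
    InsufficientDataError,
)
from hepix.stats import (
    area_weighted_resample,
    compare_regions,
    default_bin_edges,
    default_stage_table,
    entropy_histogram,
    jensen_shannon_divergence,
    map_tnm_to_stage,
    welch_t_test,
)


class TestStageMapping:
    @pytest.mark.parametrize(
        "t,n,m,expected",
        [
            ("T1", "N0", "M0", "I"),
            ("T2", "N0", "M0", "II"),
            ("T3", "N0", "M0", "III"),
            ("T4", "N0", "M0", "IV-A"),
            ("T1", "N1", "M0", "IV-A"),
            ("T2", "N1", "M1", "IV-B"),
            (None, "N0", "M0", "Unknown"),
            ("T1", None, "M0", "Unknown"),
            ("T1", "N0", None, "Unknown"),
            ("TX", "N0", "M0", "Unknown"),
            ("", "N0", "M0", "Unknown"),
            (float("nan"), "N0", "M0", "Unknown"),
        ],
    )
    def test_examples(self, t, n, m, expected):
        assert map_tnm_to_stage(t, n, m) == expected

    def test_numeric_and_lowercase_codes_accepted(self):
        assert map_tnm_to_stage("1", "0", "0") == "I"
        assert map_tnm_to_stage("t3", "n0", "m0") == "III"

    def test_table_is_exhaustive_and_consistent(self):
        table = default_stage_table()
        assert len(table) == 4 * 2 * 2
        for (t, n, m), stage in table.items():
            assert map_tnm_to_stage(t, n, m) == stage
            if m == "M1":
                assert stage == "IV-B"
            elif t == "T4" or n == "N1":
                assert stage == "IV-A"

    def test_custom_table(self):
        table = {("T1", "N0", "M0"): "IV-B"}
        assert map_tnm_to_stage("T1", "N0", "M0", table) == "IV-B"
        assert map_tnm_to_stage("T2", "N0", "M0", table) == "Unknown"


def _records(spec_values: dict[str, np.ndarray], region="cancer") -> pd.DataFrame:
    frames = []
    for sid, values in spec_values.items():
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": sid,
                    "row": np.arange(len(values)),
                    "col": 0,
                    "channel": 0,
                    "entropy": values,
                    "region_label": region,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _cohort(areas: dict[str, tuple[int, int]], stages=None) -> pd.DataFrame:
    rows = []
    for sid, (ca, nc) in areas.items():
        stage = (stages or {}).get(sid, "I")
        rows.append(
            {
                "specimen_id": sid,
                "cohort": "c",
                "T": "T1",
                "N": "N0",
                "M": "M0",
                "stage": stage,
                "tissue_area_cancer": ca,
                "tissue_area_noncancer": nc,
            }
        )
    return pd.DataFrame(rows)


class TestResampling:
    def test_inverse_area_weights_balance_specimens(self, rng):
        # specimen areas A and 2A -> equal expected draw fractions
        a_vals = rng.normal(3.0, 0.1, size=100)
        b_vals = rng.normal(5.0, 0.1, size=200)
        records = _records({"a": a_vals, "b": b_vals})
        records_nc = _records({"a": a_vals, "b": b_vals}, region="noncancer")
        records = pd.concat([records, records_nc], ignore_index=True)
        cohort = _cohort({"a": (100, 100), "b": (200, 200)})
        n_draws = 10_000
        draws = area_weighted_resample(records, cohort, n_draws=n_draws, seed=42)
        cancer = draws[draws["region_class"] == "cancer"]
        frac_a = (cancer["specimen_id"] == "a").mean()
        se = math.sqrt(0.25 / n_draws)
        assert abs(frac_a - 0.5) <= 3 * se

    def test_seed_determinism(self, rng):
        spec_values = {"a": rng.normal(size=50), "b": rng.normal(size=70)}
        records = pd.concat(
            [_records(spec_values), _records(spec_values, region="noncancer")],
            ignore_index=True,
        )
        cohort = _cohort({"a": (50, 50), "b": (70, 70)})
        d1 = area_weighted_resample(records, cohort, n_draws=500, seed=9)
        d2 = area_weighted_resample(records, cohort, n_draws=500, seed=9)
        pd.testing.assert_frame_equal(d1, d2)

    def test_zero_draws_gives_empty_set(self, rng):
        records = _records({"a": rng.normal(size=10)})
        cohort = _cohort({"a": (10, 1)})
        draws = area_weighted_resample(records, cohort, n_draws=0, seed=0)
        assert draws.empty

    def test_empty_stratum_named(self, rng):
        records = _records({"a": rng.normal(size=10)}, region="cancer")
        cohort = _cohort({"a": (10, 5)})
        with pytest.raises(EmptyStratumError, match="noncancer"):
            area_weighted_resample(records, cohort, n_draws=10, seed=0)

    def test_unknown_stage_excluded_when_grouped(self, rng):
        spec_values = {"a": rng.normal(size=30), "b": rng.normal(size=30)}
        records = pd.concat(
            [_records(spec_values), _records(spec_values, region="noncancer")],
            ignore_index=True,
        )
        cohort = _cohort(
            {"a": (30, 30), "b": (30, 30)}, stages={"a": "I", "b": "Unknown"}
        )
        draws = area_weighted_resample(
            records, cohort, n_draws=100, seed=0, group_by="stage"
        )
        assert set(draws["specimen_id"]) == {"a"}
        assert set(draws["stage"]) == {"I"}

    def test_per_specimen_stratified_mode(self, rng):
        spec_values = {"a": rng.normal(size=20), "b": rng.normal(size=200)}
        records = pd.concat(
            [_records(spec_values), _records(spec_values, region="noncancer")],
            ignore_index=True,
        )
        cohort = _cohort({"a": (20, 20), "b": (200, 200)})
        draws = area_weighted_resample(
            records, cohort, n_draws=1000, seed=3, per_specimen_stratified=True
        )
        cancer = draws[draws["region_class"] == "cancer"]
        counts = cancer["specimen_id"].value_counts()
        assert counts["a"] == 500 and counts["b"] == 500

    def test_estimator_consistency(self, rng):
        # stratum mean converges to the specimen-balanced population mean
        a_vals = rng.normal(2.0, 0.3, size=500)
        b_vals = rng.normal(6.0, 0.3, size=2000)
        balanced = (a_vals.mean() + b_vals.mean()) / 2
        records = pd.concat(
            [
                _records({"a": a_vals, "b": b_vals}),
                _records({"a": a_vals, "b": b_vals}, region="noncancer"),
            ],
            ignore_index=True,
        )
        cohort = _cohort({"a": (500, 500), "b": (2000, 2000)})
        errors = []
        for n_draws in (1_000, 100_000):
            draws = area_weighted_resample(records, cohort, n_draws=n_draws, seed=5)
            sub = draws[draws["region_class"] == "cancer"]["entropy"]
            errors.append(abs(sub.mean() - balanced))
        assert errors[1] < errors[0]
        assert errors[1] < 0.05

    def test_orphan_specimen_rejected(self, rng):
        records = _records({"ghost": rng.normal(size=5)})
        cohort = _cohort({"a": (5, 5)})
        with pytest.raises(DataError, match="ghost"):
            area_weighted_resample(records, cohort, n_draws=5, seed=0)


class TestWelch:
    def test_identical_samples(self):
        result = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == 0.0
        assert result.p == pytest.approx(1.0)

    def test_hand_derived_values(self):
        # means 2 and 4, variances 1 and 4:
        # t = -2 / sqrt(1/3 + 4/3) = -1.549...,
        # df = (5/3)^2 / ((1/3)^2/2 + (4/3)^2/2) = 2.941...
        result = welch_t_test([1, 2, 3], [2, 4, 6])
        assert result.t == pytest.approx(-1.549, abs=5e-4)
        assert result.df == pytest.approx(2.941, abs=5e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(1.0, 2.0, size=30)
        assert welch_t_test(a, b).t == pytest.approx(-welch_t_test(b, a).t)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(100):
            a = rng.normal(rng.normal(), 1 + rng.random(), size=rng.integers(5, 50))
            b = rng.normal(rng.normal(), 1 + rng.random(), size=rng.integers(5, 50))
            ours = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)
            assert ours.df == pytest.approx(ref.df, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestHistogram:
    def test_single_bin_mass(self):
        probs = entropy_histogram([0.5, 0.6, 0.55], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(probs, [1.0, 0.0])

    def test_uniform_over_midpoints(self):
        edges = np.linspace(0, 8, 5)
        mids = (edges[:-1] + edges[1:]) / 2
        probs = entropy_histogram(np.repeat(mids, 10), edges)
        np.testing.assert_allclose(probs, [0.25] * 4)

    def test_counting_oracle(self, rng):
        draws = rng.uniform(0, 8, size=500)
        edges = default_bin_edges(16)
        probs = entropy_histogram(draws, edges)
        oracle = np.array(
            [
                ((draws >= lo) & (draws < hi)).sum()
                for lo, hi in zip(edges[:-1], edges[1:])
            ],
            dtype=float,
        )
        oracle[-1] += (draws == edges[-1]).sum()
        np.testing.assert_allclose(probs, oracle / oracle.sum())

    def test_out_of_range_clipped_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            probs = entropy_histogram([-1.0, 0.5, 9.0], np.array([0.0, 1.0, 8.0]))
        assert "clipped" in caplog.text
        assert probs.sum() == pytest.approx(1.0)
        assert probs[0] == pytest.approx(2 / 3)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            entropy_histogram([], np.array([0.0, 1.0]))
        with pytest.raises(ConfigError):
            entropy_histogram([0.5], np.array([1.0, 0.0]))


class TestJSD:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == 0.0

    def test_disjoint_supports_one_bit(self):
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        # 0.5*KL([.5,.5]||[.75,.25]) + 0.5*KL([1,0]||[.75,.25]) = 0.31127...
        result = jensen_shannon_divergence([0.5, 0.5], [1.0, 0.0])
        assert result == pytest.approx(0.3113, abs=5e-5)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.001, 10.0), min_size=2, max_size=12),
        st.data(),
    )
    def test_symmetry_and_bounds(self, weights, data):
        p = np.array(weights)
        p /= p.sum()
        q_raw = np.array(
            data.draw(
                st.lists(
                    st.floats(0.001, 10.0),
                    min_size=len(weights),
                    max_size=len(weights),
                )
            )
        )
        q = q_raw / q_raw.sum()
        forward = jensen_shannon_divergence(p, q)
        assert forward == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)
        assert -1e-12 <= forward <= 1.0 + 1e-12

    def test_zero_iff_equal(self, rng):
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert jensen_shannon_divergence(p, p) <= 1e-12
        if not np.allclose(p, q):
            assert jensen_shannon_divergence(p, q) > 1e-12

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(16))
            q = rng.dirichlet(np.ones(16))
            ref = jensenshannon(p, q, base=2) ** 2
            assert jensen_shannon_divergence(p, q) == pytest.approx(ref, abs=1e-9)

    def test_validation(self):
        with pytest.raises(DataError):
            jensen_shannon_divergence([0.5, 0.5], [0.5, 0.4])
        with pytest.raises(DataError):
            jensen_shannon_divergence([0.5, 0.5], [1.0, 0.0, 0.0])
        with pytest.raises(DataError):
            jensen_shannon_divergence([1.5, -0.5], [0.5, 0.5])


class TestCompareRegions:
    def _resampled(self, rng, cancer_shift=1.0, stages=("I",)):
        frames = []
        for stage in stages:
            for channel in range(3):
                for region, loc in (("cancer", 4 + cancer_shift), ("noncancer", 4)):
                    frames.append(
                        pd.DataFrame(
                            {
                                "entropy": np.clip(
                                    rng.normal(loc, 0.4, size=800), 0, 8
                                ),
                                "channel": channel,
                                "region_class": region,
                                "stage": stage,
                                "specimen_id": "s",
                            }
                        )
                    )
        return pd.concat(frames, ignore_index=True)

    def test_dominant_cancer_entropy(self, rng):
        report = compare_regions(self._resampled(rng), group_by=None)
        assert len(report) == 3
        assert (report["t"] > 0).all()
        assert (report["p"] < 1e-3).all()
        assert (report["jsd"] > 0.1).all()

    def test_grouped_by_stage(self, rng):
        report = compare_regions(
            self._resampled(rng, stages=("I", "IV-B")), group_by="stage"
        )
        assert sorted(set(report["group"])) == ["I", "IV-B"]
        assert len(report) == 6

    def test_missing_region_class_flagged(self, rng):
        resampled = self._resampled(rng)
        resampled = resampled[
            ~((resampled["channel"] == 2) & (resampled["region_class"] == "cancer"))
        ]
        report = compare_regions(resampled)
        flagged = report[report["channel"] == 2]
        assert flagged["note"].str.contains("missing region class").all()
        assert np.isnan(flagged["t"]).all()
        ok = report[report["channel"] != 2]
        assert (ok["note"] == "").all()
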