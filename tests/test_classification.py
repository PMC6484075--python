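import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from disturbnet.classification import (
    MemberClassifier,
    abundance_class,
    aggregate_properties,
    class_summary,
    classify_all,
    cv,
    presence_class,
    present_mean,
    response_class,
    stability_class,
)
from disturbnet.io import AbundanceTable, PhaseDesign

from ._oracles import classify_taxon_oracle, cv_oracle, present_mean_oracle
from .conftest import random_table


class TestPresentMean:
    def test_constant_series(self):
        assert present_mean([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_zeros_excluded_from_denominator(self):
        assert present_mean([4, 0, 2]) == pytest.approx(3.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            present_mean([0.0, 0.0])

    @given(st.lists(st.floats(0, 10), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_matches_oracle(self, values):
        if not any(v > 0 for v in values):
            return
        assert present_mean(values) == pytest.approx(
            present_mean_oracle(values), rel=1e-12
        )


class TestCv:
    def test_zero_variance(self):
        assert cv([1.0, 1.0, 1.0]) == 0.0

    def test_two_point_series(self):
        # sd = sqrt(2), present-mean = 3
        assert cv([2, 4]) == pytest.approx(math.sqrt(2) / 3, rel=1e-12)

    def test_zeros_enter_deviations_but_not_mean(self):
        # present-mean 3; deviations (2-3)^2 + (0-3)^2 + (4-3)^2 = 11
        assert cv([2, 0, 4]) == pytest.approx(math.sqrt(5.5) / 3, rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cv([1.0])

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(30):
            s = rng.gamma(1.0, 1.0, size=12)
            s[rng.random(12) < 0.3] = 0.0
            if not (s > 0).any():
                continue
            assert cv(s) == pytest.approx(cv_oracle(s), rel=1e-12)


class TestAbundanceClass:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (0.02, "HA"),
            (0.005, "LA"),
            (0.0002, "RA"),
            (0.01, "LA"),  # boundary: closed interval
            (0.001, "LA"),
            (0.010000001, "HA"),
        ],
    )
    def test_thresholds(self, mean, expected):
        assert abundance_class(mean) == expected

    def test_mean_includes_zeros(self):
        # plain mean 0.005 despite present-mean 0.015
        assert abundance_class([0.015, 0.0, 0.0]) == "LA"


class TestPresenceClass:
    def test_strictly_positive_row_is_core(self):
        assert presence_class([0.1, 0.2, 0.001]) == "Core"

    def test_single_zero_makes_ncore(self):
        assert presence_class([0.1, 0.0, 0.2]) == "Ncore"

    def test_all_zero_is_ncore(self):
        assert presence_class([0.0, 0.0]) == "Ncore"


class TestStabilityClass:
    def test_identical_windows_give_nc(self):
        label, p, flag = stability_class([1, 2, 3], [1, 2, 3])
        assert label == "NC" and p == pytest.approx(1.0) and flag == ""

    def test_variable_before_stable_after_is_bs(self, rng):
        before = rng.normal(1.0, 0.5, 12).clip(min=0.01)
        after = rng.normal(1.0, 0.02, 15).clip(min=0.01)
        label, p, _ = stability_class(before, after)
        # oracle: reference two-sided F p-value + CV comparison
        f = np.var(before, ddof=1) / np.var(after, ddof=1)
        dist = stats.f(11, 14)
        p_ref = min(1.0, 2 * min(dist.cdf(f), dist.sf(f)))
        assert p == pytest.approx(p_ref, rel=1e-12)
        assert label == "BS"

    def test_stable_before_variable_after_is_bv(self, rng):
        before = rng.normal(1.0, 0.02, 12).clip(min=0.01)
        after = rng.normal(1.0, 0.5, 15).clip(min=0.01)
        label, _, _ = stability_class(before, after)
        assert label == "BV"

    def test_both_windows_degenerate(self):
        label, p, _ = stability_class([1.0, 1.0], [1.0, 1.0])
        assert label == "NC" and p == 1.0

    def test_one_window_degenerate(self):
        label, p, _ = stability_class([2.0, 2.0], [1.0, 3.0])
        assert p == 0.0
        assert label == "BV"  # cv_before = 0 < cv_after

    def test_absent_window_flagged(self):
        label, p, flag = stability_class([0.0, 0.0], [1.0, 2.0])
        assert label == "NC" and math.isnan(p) and flag == "window-absent"


class TestResponseClass:
    def test_convex_pattern_is_induced(self):
        label, _ = response_class([0.01] * 3, [0.03] * 2, [0.01] * 3)
        assert label == "induced"

    def test_concave_pattern_is_repressed(self):
        label, _ = response_class([0.03] * 3, [0.01] * 2, [0.02] * 3)
        assert label == "repressed"

    def test_tie_is_neither(self):
        label, _ = response_class([0.01] * 3, [0.01] * 2, [0.01] * 3)
        assert label == "neither"

    def test_empty_during_flagged(self):
        label, flag = response_class([0.01] * 3, [], [0.01] * 3)
        assert label == "neither" and flag == "no-during"

    def test_absent_window_flagged(self):
        label, flag = response_class([0.0] * 3, [0.01] * 2, [0.01] * 3)
        assert label == "neither" and flag == "window-absent"


class TestClassifyAll:
    def test_single_core_ha_nc_taxon(self):
        data = pd.DataFrame(
            [np.full(8, 0.5), 1 - np.full(8, 0.5)],
            index=["focal", "rest"],
            columns=[f"S{i}" for i in range(8)],
        )
        table = AbundanceTable(data)
        design = PhaseDesign.from_sizes(3, 2, 3)
        labels = classify_all(table, design).set_index("taxon")
        assert labels.loc["focal", "abundance_class"] == "HA"
        assert labels.loc["focal", "presence_class"] == "Core"
        assert labels.loc["focal", "stability_class"] == "NC"

    def test_matches_brute_force_oracle_exactly(self, rng, design_12_3_15):
        design = design_12_3_15
        for _ in range(5):
            table = random_table(rng, n_taxa=25, n_samples=30)
            labels = classify_all(table, design)
            for rec in labels.itertuples(index=False):
                row = table.data.loc[rec.taxon].to_numpy()
                expected = classify_taxon_oracle(
                    row, list(design.before), list(design.during), list(design.after)
                )
                got = (
                    rec.abundance_class,
                    rec.presence_class,
                    rec.stability_class,
                    rec.response,
                )
                assert got == expected, rec.taxon

    def test_within_phase_column_permutation_invariance(self, rng, design_12_3_15):
        table = random_table(rng, n_taxa=15, n_samples=30)
        labels = classify_all(table, design_12_3_15)
        perm = (
            list(rng.permutation(12))
            + list(12 + rng.permutation(3))
            + list(15 + rng.permutation(15))
        )
        shuffled = AbundanceTable(
            table.data.iloc[:, perm].set_axis(table.samples, axis=1)
        )
        labels2 = classify_all(shuffled, design_12_3_15)
        for col in ("abundance_class", "presence_class", "stability_class", "response"):
            assert (labels[col] == labels2[col]).all()

    def test_scale_invariance_of_stability_and_response(self, rng, design_12_3_15):
        table = random_table(rng, n_taxa=15, n_samples=30)
        scaled = AbundanceTable(table.data * 7.3)
        a = classify_all(table, design_12_3_15)
        b = classify_all(scaled, design_12_3_15)
        assert (a["stability_class"] == b["stability_class"]).all()
        assert (a["response"] == b["response"]).all()

    def test_partition_property(self, rng, design_12_3_15):
        table = random_table(rng, n_taxa=40, n_samples=30)
        labels = classify_all(table, design_12_3_15)
        summary = class_summary(labels)
        assert summary["n_taxa"].sum() == table.n_taxa
        assert labels["abundance_class"].isin(["HA", "LA", "RA"]).all()
        assert labels["presence_class"].isin(["Core", "Ncore"]).all()
        assert labels["stability_class"].isin(["BS", "BV", "NC"]).all()

    def test_estimator_interface(self, rng, design_12_3_15):
        table = random_table(rng, n_taxa=10, n_samples=30)
        clf = MemberClassifier(alpha=0.01)
        assert clf.get_params()["alpha"] == 0.01
        clf.set_params(alpha=0.05).fit(table, design_12_3_15)
        assert len(clf.labels_) == 10
        pd.testing.assert_frame_equal(clf.transform(), clf.labels_)


class TestAggregateProperties:
    def _labels(self, groups):
        return pd.DataFrame(
            {
                "taxon": [f"t{i}" for i in range(len(groups))],
                "abundance_class": ["HA"] * len(groups),
                "presence_class": ["Core"] * len(groups),
                "stability_class": groups,
                "response": ["neither"] * len(groups),
            }
        )

    def test_identical_groups_zero_difference(self):
        labels = self._labels(["BS"] * 3 + ["BV"] * 3)
        ann = pd.DataFrame(
            {"gc_percent": [50.0, 55.0, 60.0] * 2},
            index=[f"t{i}" for i in range(6)],
        )
        out = aggregate_properties(labels, ann)
        row = out["genomic_tests"].iloc[0]
        assert row["mean_high"] == pytest.approx(row["mean_low"])

    def test_pathway_union_counts_distinct(self):
        labels = self._labels(["BS", "BS"])
        ann = pd.DataFrame(
            {"pathways": [frozenset({"p1", "p2"}), frozenset({"p2", "p3"})]},
            index=["t0", "t1"],
        )
        out = aggregate_properties(labels, ann)
        assert out["pathways"].set_index("abundance_class").loc["HA", "n_pathways"] == 3

    def test_separated_groups_significant(self, rng):
        labels = self._labels(["BV"] * 20 + ["BS"] * 20)
        ann = pd.DataFrame(
            {
                "gc_percent": np.concatenate(
                    [rng.normal(60, 1, 20), rng.normal(50, 1, 20)]
                )
            },
            index=[f"t{i}" for i in range(40)],
        )
        out = aggregate_properties(labels, ann)
        row = out["genomic_tests"].query("metric == 'gc_percent'").iloc[0]
        assert row["group_high"] == "BV" and row["mean_high"] > row["mean_low"]
        assert row["t_p"] < 0.01

    def test_small_group_skips_tests(self):
        labels = self._labels(["BS", "BV"])
        ann = pd.DataFrame({"gc_percent": [50.0, 60.0]}, index=["t0", "t1"])
        out = aggregate_properties(labels, ann)
        assert (out["genomic_tests"]["flag"] == "too-few-annotated").all()


def test_null_calibration_of_stability(rng):
    """Under equal before/after distributions, ~1-alpha of taxa come out NC."""
    n = 1000
    nc = 0
    for _ in range(n):
        label, _, _ = stability_class(
            rng.normal(1.0, 0.2, 12), rng.normal(1.0, 0.2, 15)
        )
        nc += label == "NC"
    assert 0.92 <= nc / n <= 0.98
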