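"""Richness, rarefaction, extrapolation and coverage solving."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from conftest import random_incidence
from npdiv import diversity
from npdiv.containers import IncidenceMatrix
from npdiv.errors import DegenerateDataError


def exhaustive_expected_richness(incidence: IncidenceMatrix, t: int) -> float:
    """Oracle: average distinct-item count over every size-t isolate subset."""
    presence = incidence.presence.to_numpy(dtype=bool)
    isolates = range(incidence.T)
    values = [
        int(presence[:, list(subset)].any(axis=1).sum())
        for subset in itertools.combinations(isolates, t)
    ]
    return float(np.mean(values))


class TestAlphaRichness:
    def test_counts_presences(self, toy_incidence):
        richness = diversity.alpha_richness(toy_incidence)
        assert richness.tolist() == [3, 2, 2, 3]

    def test_empty_isolate_counts_zero(self):
        presence = pd.DataFrame({"i1": [1, 1], "i2": [0, 0]}, index=["a", "b"])
        inc = IncidenceMatrix(presence)
        assert diversity.alpha_richness(inc)["i2"] == 0


class TestCompareRichness:
    def test_identical_groups_f_zero(self):
        richness = pd.Series([1, 2, 3, 1, 2, 3], index=list("abcdef"), dtype=float)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        res = diversity.compare_richness(richness, groups)
        assert res.anova_F == pytest.approx(0.0)
        assert res.anova_p == pytest.approx(1.0)

    def test_hand_anova_table(self):
        richness = pd.Series([1, 2, 3, 11, 12, 13], index=list("abcdef"), dtype=float)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        res = diversity.compare_richness(richness, groups)
        assert res.anova_F == pytest.approx(150.0)
        assert not res.tukey.empty

    def test_degenerate_zero_variance(self):
        richness = pd.Series([2, 2, 5, 5], index=list("abcd"), dtype=float)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        with pytest.raises(DegenerateDataError):
            diversity.compare_richness(richness, groups)

    def test_synth_medians_follow_pool_sizes(self, default_survey, default_incidence):
        """Clade richness medians rank by configured pool size: U > Y > V > W > X."""
        _, incidence = default_incidence
        richness = diversity.alpha_richness(incidence)
        medians = richness.groupby(incidence.groups).median()
        assert (
            medians["U"] > medians["Y"] > medians["V"] > medians["W"] > medians["X"]
        )


class TestBalancedSubsample:
    def test_n_equal_to_group_size_is_identity(self, toy_incidence):
        groups = pd.Series(
            ["g1", "g1", "g2", "g2"], index=toy_incidence.presence.columns
        )
        inc = IncidenceMatrix(toy_incidence.presence, groups)
        sub = diversity.balanced_subsample(inc, n=2, seed=0)
        assert list(sub.isolates) == list(inc.isolates)

    def test_large_groups_downsampled(self, default_incidence):
        _, incidence = default_incidence
        sub = diversity.balanced_subsample(incidence, n=26, seed=0)
        counts = sub.groups.value_counts()
        assert counts["U"] == 26
        assert counts["Y"] == 14  # smaller than n, kept whole

    def test_deterministic(self, default_incidence):
        _, incidence = default_incidence
        a = diversity.balanced_subsample(incidence, n=26, seed=5)
        b = diversity.balanced_subsample(incidence, n=26, seed=5)
        assert list(a.isolates) == list(b.isolates)


class TestAnalyticRarefaction:
    def test_full_sample_returns_observed(self, toy_incidence):
        assert diversity.analytic_rarefaction(toy_incidence, 4) == pytest.approx(5.0)

    def test_single_isolate_returns_mean_richness(self, toy_incidence):
        assert diversity.analytic_rarefaction(toy_incidence, 1) == pytest.approx(2.5)

    def test_toy_two_isolates(self, toy_incidence):
        assert diversity.analytic_rarefaction(toy_incidence, 2) == pytest.approx(11 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        inc = random_incidence(rng, T=int(rng.integers(3, 9)), n_items=25)
        for t in range(1, inc.T + 1):
            assert diversity.analytic_rarefaction(inc, t) == pytest.approx(
                exhaustive_expected_richness(inc, t), abs=1e-10
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_curve_nondecreasing_and_concave(self, seed):
        rng = np.random.default_rng(seed)
        inc = random_incidence(rng, T=12, n_items=60)
        curve = diversity.analytic_rarefaction(inc, np.arange(1, 13))
        diffs = np.diff(curve)
        assert (diffs >= -1e-9).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_out_of_range_rejected(self, toy_incidence):
        with pytest.raises(ValueError):
            diversity.analytic_rarefaction(toy_incidence, 5)

    def test_matches_vegan_specaccum(self, tmp_path):
        """Independent oracle: vegan's exact sample-based accumulation."""
        rng = np.random.default_rng(11)
        inc = random_incidence(rng, T=6, n_items=20)
        csv = tmp_path / "inc.csv"
        # vegan expects sites x species
        inc.presence.T.to_csv(csv)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}", row.names = 1))
            sp <- specaccum(m, method = "exact")
            cat(sp$richness, sep = ",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vegan_curve = np.array([float(x) for x in out.stdout.strip().split(",")])
        ours = diversity.analytic_rarefaction(inc, np.arange(1, inc.T + 1))
        # Rscript's cat prints ~7 significant digits
        np.testing.assert_allclose(ours, vegan_curve, rtol=1e-6)


class TestCollectorCurve:
    def test_last_point_is_observed_total(self, toy_incidence):
        order = ["C", "A", "D", "B"]
        curve = diversity.collector_curve(toy_incidence, order=order)
        assert curve.at(4) == pytest.approx(5.0)

    def test_mean_over_all_orders_matches_analytic(self, toy_incidence):
        isolates = list(toy_incidence.isolates)
        t2_values = [
            diversity.collector_curve(toy_incidence, order=list(perm)).at(2)
            for perm in itertools.permutations(isolates)
        ]
        assert np.mean(t2_values) == pytest.approx(11 / 3)

    def test_fixed_orders_share_endpoints_not_interiors(self, toy_incidence):
        a = diversity.collector_curve(toy_incidence, order=["A", "B", "C", "D"])
        b = diversity.collector_curve(toy_incidence, order=["B", "A", "D", "C"])
        assert a.at(4) == b.at(4)
        assert a.at(1) != b.at(1)  # raw data as entered: interiors differ

    def test_invalid_order_rejected(self, toy_incidence):
        with pytest.raises(ValueError):
            diversity.collector_curve(toy_incidence, order=["A", "A", "B", "C"])

    def test_permutation_mean_near_analytic(self, toy_incidence):
        curve = diversity.collector_curve(toy_incidence, n_perm=2000, seed=0)
        analytic = diversity.analytic_rarefaction(toy_incidence, np.arange(1, 5))
        np.testing.assert_allclose(
            curve.data["richness"].to_numpy(), analytic, rtol=0.02
        )


class TestChao2:
    def test_no_uniques_nothing_unseen(self):
        assert diversity.chao2_unseen(0, 5, 10) == 0.0

    def test_standard_branch(self):
        assert diversity.chao2_unseen(4, 2, 10) == pytest.approx(3.6)

    def test_bias_corrected_branch(self):
        assert diversity.chao2_unseen(3, 0, 5) == pytest.approx(2.4)


class TestExtrapolation:
    def test_zero_additional_isolates(self, toy_incidence):
        assert diversity.extrapolate_richness(toy_incidence, 0) == pytest.approx(5.0)

    def test_asymptote(self, toy_incidence):
        q0 = diversity.chao2_unseen(2, 2, 4)  # 0.75
        assert diversity.extrapolate_richness(toy_incidence, 10**6) == pytest.approx(
            5 + q0, abs=1e-9
        )

    def test_toy_one_step(self, toy_incidence):
        assert diversity.extrapolate_richness(toy_incidence, 1) == pytest.approx(5.3)

    def test_rarefaction_curve_interpolated_then_extrapolated(self, toy_incidence):
        curve = diversity.rarefaction_curve(toy_incidence, endpoint=10)
        data = curve.data
        assert data.loc[data["t"] == 4, "method"].iloc[0] == "interpolated"
        assert data.loc[data["t"] == 5, "method"].iloc[0] == "extrapolated"
        assert (data["richness"].diff().dropna() >= -1e-9).all()
        assert (data.loc[data["method"] == "extrapolated", "richness"] >= 5.0).all()


class TestCoverageTargets:
    def test_toy_thresholds(self, toy_incidence):
        targets = diversity.coverage_targets(toy_incidence, [0.5, 0.75, 0.9])
        assert targets == {0.5: 1, 0.75: 3, 0.9: 3}

    def test_full_coverage_needs_all_isolates_with_uniques(self, toy_incidence):
        assert diversity.coverage_targets(toy_incidence, [1.0])[1.0] == 4

    @pytest.mark.parametrize("seed", range(3))
    def test_nondecreasing_in_fraction(self, seed):
        rng = np.random.default_rng(seed)
        inc = random_incidence(rng, T=15, n_items=80)
        fractions = [0.5, 0.75, 0.9, 0.95, 0.99, 1.0]
        targets = diversity.coverage_targets(inc, fractions)
        counts = [targets[p] for p in fractions]
        assert counts == sorted(counts)


class TestEndSlope:
    def test_toy_identity(self, toy_incidence):
        slope = diversity.end_slope(toy_incidence)
        assert slope == pytest.approx(0.5)
        assert slope == pytest.approx(toy_incidence.Q1 / toy_incidence.T)

    def test_no_uniques_means_zero_slope(self):
        presence = pd.DataFrame(
            {"i1": [1, 1], "i2": [1, 0], "i3": [0, 1]}, index=["a", "b"]
        )
        assert diversity.end_slope(IncidenceMatrix(presence)) == pytest.approx(0.0)

    def test_larger_groups_closer_to_saturation(self):
        """Under a common per-isolate feature model, the end slope falls
        as group size grows (bigger clades are closer to saturation)."""
        rng = np.random.default_rng(2)
        slopes = []
        for T in (8, 16, 32, 64):
            presence = (rng.random((400, T)) < 0.15).astype(int)
            presence = presence[presence.sum(axis=1) > 0]
            inc = IncidenceMatrix(
                pd.DataFrame(
                    presence,
                    index=[f"f{i}" for i in range(len(presence))],
                    columns=[f"i{j}" for j in range(T)],
                )
            )
            slopes.append(diversity.end_slope(inc))
        assert slopes == sorted(slopes, reverse=True)
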