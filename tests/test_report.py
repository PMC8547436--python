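"""Venn partitioning, percent formatting, ordered accumulation, pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npdiv import report, synth
from npdiv.containers import IncidenceMatrix
from npdiv.errors import DegenerateDataError


class TestAsPercent:
    def test_zero_count(self):
        assert report.as_percent(0, 50) == 0.0

    def test_half_rounds_away_from_zero(self):
        assert report.as_percent(1, 800) == 0.1  # 0.125 -> 0.1
        assert report.as_percent(3, 2000) == 0.2  # 0.15 -> 0.2, not 0.1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            report.as_percent(1, 0)
        with pytest.raises(ValueError):
            report.as_percent(5, 4)

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_resolution(self, count, total):
        if count > total:
            return
        pct = report.as_percent(count, total)
        assert 0.0 <= pct <= 100.0
        assert pct == round(pct, 1)


def _venn_fixture():
    """Two groups; patterns {A}, {B}, {AB}, {AB}."""
    presence = pd.DataFrame(
        {
            "i1": [1, 0, 1, 0],
            "i2": [0, 1, 0, 1],
        },
        index=["fA", "fB", "fAB1", "fAB2"],
    )
    presence.loc["fAB1"] = [1, 1]
    presence.loc["fAB2"] = [1, 1]
    groups = pd.Series(["A", "B"], index=["i1", "i2"])
    return IncidenceMatrix(presence, groups)


class TestVennPartition:
    def test_toy_counts(self):
        venn = report.venn_partition(_venn_fixture())
        assert venn.unique_count("A") == 1
        assert venn.unique_count("B") == 1
        assert venn.subset_count("A", "B") == 2
        assert venn.core_count == 2
        assert venn.total == 4

    def test_single_group_rejected(self):
        presence = pd.DataFrame({"i1": [1], "i2": [1]}, index=["f"])
        groups = pd.Series(["A", "A"], index=["i1", "i2"])
        with pytest.raises(DegenerateDataError):
            report.venn_partition(IncidenceMatrix(presence, groups))

    @pytest.mark.parametrize("seed", range(3))
    def test_subset_counts_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        presence = pd.DataFrame(
            (rng.random((40, 9)) < 0.4).astype(int),
            index=[f"f{i}" for i in range(40)],
            columns=[f"i{j}" for j in range(9)],
        )
        presence = presence.loc[presence.sum(axis=1) > 0]
        groups = pd.Series(
            ["A", "A", "A", "B", "B", "B", "C", "C", "C"], index=presence.columns
        )
        venn = report.venn_partition(IncidenceMatrix(presence, groups))
        assert sum(venn.counts.values()) == venn.total == len(presence)

    def test_synth_venn_matches_ground_truth(self, default_survey, default_incidence):
        """Venn by true chemotype equals the tallies implied by each
        feature's recorded cluster-eligibility set."""
        _, _, _, _, truth = default_survey
        _, incidence = default_incidence
        clusters = truth.isolates.loc[incidence.isolates, "true_cluster"].astype(str)
        venn = report.venn_partition(incidence, groups=clusters)
        expected: dict[frozenset, int] = {}
        for fid in incidence.items:
            subset = frozenset(truth.features.at[fid, "clusters"].split(","))
            expected[subset] = expected.get(subset, 0) + 1
        assert venn.counts == expected


class TestOrderedAccumulation:
    def test_single_group_is_total(self):
        presence = pd.DataFrame({"i1": [1, 1], "i2": [1, 0]}, index=["f1", "f2"])
        groups = pd.Series(["A", "B"], index=["i1", "i2"])
        inc = IncidenceMatrix(presence, groups)
        rep = report.ordered_accumulation(inc, order=["A", "B"])
        assert rep.increments_pct[0] == 100.0
        assert rep.increments_pct[1] == 0.0

    def test_toy_three_quarters_then_quarter(self):
        presence = pd.DataFrame(
            {"i1": [1, 1, 1, 0], "i2": [0, 0, 0, 1]},
            index=["f1", "f2", "f3", "f4"],
        )
        groups = pd.Series(["A", "B"], index=["i1", "i2"])
        rep = report.ordered_accumulation(IncidenceMatrix(presence, groups), ["A", "B"])
        assert rep.increments_pct == [75.0, 25.0]
        assert rep.cumulative_pct[-1] == 100.0

    @pytest.mark.parametrize("seed", range(3))
    def test_increments_sum_to_hundred_for_any_order(self, seed):
        rng = np.random.default_rng(seed)
        presence = pd.DataFrame(
            (rng.random((30, 8)) < 0.35).astype(int),
            index=[f"f{i}" for i in range(30)],
            columns=[f"i{j}" for j in range(8)],
        )
        presence = presence.loc[presence.sum(axis=1) > 0]
        groups = pd.Series(list("AABBCCDD"), index=presence.columns)
        inc = IncidenceMatrix(presence, groups)
        order = list(rng.permutation(["A", "B", "C", "D"]))
        rep = report.ordered_accumulation(inc, order)
        assert sum(rep.increments_pct) == pytest.approx(100.0)
        assert all(i >= 0 for i in rep.increments_raw)
        assert sum(rep.increments_raw) == pytest.approx(1.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            report.ordered_accumulation(_venn_fixture(), ["A", "Z"])

    def test_builtin_orders(self, default_incidence):
        _, incidence = default_incidence
        large = report.ordered_accumulation(incidence, "largest-first")
        small = report.ordered_accumulation(incidence, "smallest-first")
        assert large.order[0] == "U"  # the 111-isolate clade leads
        assert small.order[-1] == "U"
        assert sum(large.increments_pct) == pytest.approx(100.0)
        assert sum(small.increments_pct) == pytest.approx(100.0)


class TestGeographicSummary:
    @staticmethod
    def _meta(rows):
        frame = pd.DataFrame(
            rows, columns=["sample_id", "isolate_id", "is_blank", "lon", "lat"]
        )
        return frame.set_index("sample_id", drop=False)

    def test_single_isolate_degenerate_box(self):
        meta = self._meta([["s1", "iso1", False, -100.0, 40.0]])
        labels = pd.Series({"iso1": 1})
        geo = report.geographic_summary(meta, labels)
        row = geo.loc[1]
        assert row["lon_min"] == row["lon_max"] == -100.0
        assert row["lon_span"] == 0.0

    def test_identical_coordinates_zero_spans(self):
        meta = self._meta(
            [["s1", "a", False, -90.0, 35.0], ["s2", "b", False, -90.0, 35.0]]
        )
        labels = pd.Series({"a": 1, "b": 2})
        geo = report.geographic_summary(meta, labels)
        assert (geo["lon_span"] == 0.0).all()

    def test_missing_coordinates_skipped_with_warning(self):
        meta = self._meta(
            [["s1", "a", False, -90.0, 35.0], ["s2", "b", False, np.nan, np.nan]]
        )
        labels = pd.Series({"a": 1, "b": 2})
        with pytest.warns(UserWarning):
            geo = report.geographic_summary(meta, labels)
        assert list(geo.index) == [1]

    def test_restricted_cluster_flagged(self, default_survey):
        """The far-west chemotype's box lies inside its configured bounds
        and is flagged as range-restricted."""
        config, _, metadata, _, truth = default_survey
        labels = truth.isolates["true_cluster"]
        geo = report.geographic_summary(metadata, labels)
        box = config.cluster_geo_boxes[5]
        assert geo.loc[5, "lon_min"] >= box[0]
        assert geo.loc[5, "lon_max"] <= box[1]
        assert bool(geo.loc[5, "range_restricted"])
        assert not bool(geo.loc[1, "range_restricted"])


class TestPipeline:
    @pytest.fixture(scope="class")
    def pipeline_runs(self, tmp_path_factory):
        config = synth.GeneratorConfig(
            clade_sizes=(16, 10, 8, 6, 6),
            n_core_features=15,
            n_clade_features=(60, 40, 25, 20, 30),
            n_pairwise_shared_features=15,
            n_scaffolds=50,
            n_blank_features=6,
            seed=3,
        )
        outdir = tmp_path_factory.mktemp("pipe")
        cfg = report.PipelineConfig(
            simulate=config,
            outdir=str(outdir),
            n_perm_permanova=99,
            k_min=2,
            k_max=8,
            seed=3,
        )
        outs = []
        for _ in range(2):  # rerun into the same directory
            summary = report.run_pipeline(cfg)
            outs.append((outdir, summary, (outdir / "summary.json").read_bytes()))
        return outs

    def test_summary_validates_against_schema(self, pipeline_runs):
        _, summary, _ = pipeline_runs[0]
        report.validate_summary(summary)

    def test_rerun_is_byte_identical(self, pipeline_runs):
        (_, _, bytes_a), (_, _, bytes_b) = pipeline_runs
        assert bytes_a == bytes_b

    def test_coverage_targets_nondecreasing(self, pipeline_runs):
        _, summary, _ = pipeline_runs[0]
        targets = summary["diversity"]["coverage_targets"]
        counts = [targets[k] for k in sorted(targets, key=float)]
        assert counts == sorted(counts)

    def test_summary_json_round_trips(self, pipeline_runs):
        outdir, summary, _ = pipeline_runs[1]
        on_disk = json.loads((outdir / "summary.json").read_text())
        assert on_disk["preprocess"] == summary["preprocess"]
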