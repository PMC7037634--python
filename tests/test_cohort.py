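import numpy as np
import pandas as pd
import pytest

from gibbsnet.cohort import (
    DEFAULT_BINNING,
    AgeBinning,
    assign_age_bins,
    average_over_regions,
    detect_crossover,
    summarize_bins,
    trend_extrema,
)

BINNING = AgeBinning(edges=(-0.75, 0.0, 1.0, 4.0, 8.0, 23.0, 40.0, 90.0))


def _meta(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "age_years", "sex", "region", "hemisphere"]
    )


def _gibbs(pairs):
    return pd.DataFrame(pairs, columns=["sample_id", "total_G"])


class TestAgeBinning:
    def test_edges_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AgeBinning(edges=(0.0, 1.0, 1.0))

    def test_default_binning_has_eleven_intervals(self):
        assert DEFAULT_BINNING.n_bins == 11
        assert DEFAULT_BINNING.labels[3] == "0–1"

    @pytest.mark.parametrize(
        "age, label",
        [(-0.4, "-0.75–0"), (0.5, "0–1"), (15.0, "8–23"), (0.0, "0–1"), (90.0, "40–90")],
    )
    def test_interval_assignment_left_closed(self, age, label):
        assert BINNING.bin_of(age) == label

    def test_out_of_range_samples_excluded(self):
        meta = _meta([("s1", "d1", 95.0, "female", "HIP", "L"),
                      ("s2", "d2", 3.0, "male", "HIP", "L")])
        assigned = assign_age_bins(meta, BINNING)
        assert list(assigned.index) == ["s2"]


class TestSummarizeBins:
    def test_mean_and_standard_error(self):
        meta = _meta([("s1", "d1", 2.0, "female", "HIP", "L"),
                      ("s2", "d2", 2.5, "female", "HIP", "R")])
        out = summarize_bins(_gibbs([("s1", -2.0), ("s2", -4.0)]), meta, BINNING)
        (row,) = out.to_dict("records")
        assert row["mean_G"] == -3.0
        assert row["se_G"] == pytest.approx(1.0)  # sd(n-1)=sqrt(2), /sqrt(2)
        assert row["n"] == 2

    def test_single_sample_group_has_missing_se(self):
        meta = _meta([("s1", "d1", 2.0, "female", "HIP", "L")])
        out = summarize_bins(_gibbs([("s1", -5.0)]), meta, BINNING)
        assert out.loc[0, "mean_G"] == -5.0
        assert np.isnan(out.loc[0, "se_G"])

    def test_pooled_grouping_partitions_samples(self):
        meta = _meta([("s1", "d1", 2.0, "female", "HIP", "L"),
                      ("s2", "d2", 10.0, "male", "AMY", "R"),
                      ("s3", "d3", 2.2, "male", "DFC", "L")])
        out = summarize_bins(_gibbs([("s1", -1.0), ("s2", -2.0), ("s3", -3.0)]),
                             meta, BINNING, ())
        assert out["n"].sum() == 3
        assert out["region"].unique().tolist() == ["ALL"]
        assert out["sex"].unique().tolist() == ["pooled"]

    def test_pooled_mean_is_count_weighted_mean_of_sex_means(self):
        meta = _meta([("s1", "d1", 2.0, "female", "HIP", "L"),
                      ("s2", "d2", 2.5, "female", "HIP", "R"),
                      ("s3", "d3", 2.2, "male", "HIP", "L")])
        gibbs = _gibbs([("s1", -1.0), ("s2", -3.0), ("s3", -8.0)])
        by_sex = summarize_bins(gibbs, meta, BINNING, ("sex",)).set_index("sex")
        pooled = summarize_bins(gibbs, meta, BINNING, ())
        weighted = np.average(by_sex["mean_G"], weights=by_sex["n"])
        assert pooled.loc[0, "mean_G"] == pytest.approx(weighted)

    def test_duplicated_input_keeps_means_and_doubles_n(self):
        meta = _meta([("s1", "d1", 2.0, "female", "HIP", "L"),
                      ("s2", "d2", 2.5, "female", "HIP", "R")])
        gibbs = _gibbs([("s1", -2.0), ("s2", -4.0)])
        meta2 = pd.concat([meta, meta.assign(sample_id=["s1b", "s2b"])])
        gibbs2 = pd.concat([gibbs, gibbs.assign(sample_id=["s1b", "s2b"])])
        base = summarize_bins(gibbs, meta, BINNING)
        doubled = summarize_bins(gibbs2, meta2, BINNING)
        assert doubled.loc[0, "mean_G"] == base.loc[0, "mean_G"]
        assert doubled.loc[0, "n"] == 2 * base.loc[0, "n"]


class TestAverageOverRegions:
    def _summaries(self):
        return pd.DataFrame(
            {
                "bin": ["0–1", "0–1", "1–4"],
                "region": ["HIP", "AMY", "HIP"],
                "sex": ["female"] * 3,
                "mean_G": [-3.0, -5.0, -2.0],
                "se_G": [0.1, 0.2, 0.3],
                "n": [4, 2, 3],
            }
        )

    def test_unweighted_region_mean(self):
        out = average_over_regions(self._summaries())
        row = out[out["bin"] == "0–1"].iloc[0]
        assert row["mean_G"] == -4.0
        assert row["n_regions"] == 2

    def test_region_absent_from_bin_is_excluded(self):
        out = average_over_regions(self._summaries())
        row = out[out["bin"] == "1–4"].iloc[0]
        assert row["mean_G"] == -2.0
        assert row["n_regions"] == 1

    def test_single_region_is_identity(self):
        single = self._summaries().query("region == 'HIP'")
        out = average_over_regions(single)
        assert out["mean_G"].tolist() == [-3.0, -2.0]


class TestDetectCrossover:
    BINS = ["b1", "b2", "b3"]

    def test_single_sign_flip_located(self):
        report = detect_crossover(
            {"b1": -3.0, "b2": -2.0, "b3": -5.0},
            {"b1": -4.0, "b2": -3.0, "b3": -4.0},
            self.BINS,
        )
        assert report.crossovers == [("b2", "b3")]

    def test_identical_curves_converge_without_crossover(self):
        curve = {"b1": -3.0, "b2": -2.0, "b3": -5.0}
        report = detect_crossover(curve, curve, self.BINS, tolerance=0.0)
        assert report.crossovers == []
        assert report.converged

    def test_zero_difference_is_a_tie_not_a_flip(self):
        report = detect_crossover(
            {"b1": -1.0, "b2": -2.0, "b3": -1.0},
            {"b1": -2.0, "b2": -2.0, "b3": -2.0},
            self.BINS,
        )
        assert report.crossovers == []
        assert report.ties == ["b2"]

    def test_antisymmetric_under_curve_swap(self):
        f = {"b1": -3.0, "b2": -2.0, "b3": -5.0}
        m = {"b1": -4.0, "b2": -3.0, "b3": -4.0}
        assert (
            detect_crossover(f, m, self.BINS).crossovers
            == detect_crossover(m, f, self.BINS).crossovers
        )

    def test_fewer_than_two_shared_bins_is_an_error(self):
        with pytest.raises(ValueError, match="two shared bins"):
            detect_crossover({"b1": -1.0}, {"b1": -2.0}, self.BINS)


class TestTrendExtrema:
    BINS = ["fetal", "birth", "adolescent", "adult"]

    def test_peak_and_post_peak_trough(self):
        curve = dict(zip(self.BINS, [-6.0, -2.0, -4.0, -3.0]))
        result = trend_extrema(curve, self.BINS)
        assert result.peak_bin == "birth"
        assert result.trough_bin == "adolescent"
        assert not result.degenerate

    def test_monotone_increasing_curve_is_degenerate(self):
        curve = dict(zip(self.BINS, [-6.0, -5.0, -4.0, -3.0]))
        result = trend_extrema(curve, self.BINS)
        assert result.peak_bin == result.trough_bin == "adult"
        assert result.degenerate

    def test_flat_curve_ties_break_to_first_bin(self):
        curve = dict.fromkeys(self.BINS, -3.0)
        result = trend_extrema(curve, self.BINS)
        assert result.peak_bin == "fetal"
        assert result.degenerate

    def test_fewer_than_three_bins_is_an_error(self):
        with pytest.raises(ValueError, match="three bins"):
            trend_extrema({"b1": -1.0, "b2": -2.0}, ["b1", "b2"])
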