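import numpy as np
import pandas as pd
import pytest

from polyarray import mapping as mp
from polyarray import synthetic as syn


class TestSegregationChiSquare:
    @pytest.mark.parametrize(
        "n_a, n_b, stat, p",
        [
            (50, 50, 0.0, 1.0),
            (60, 40, 4.0, 0.0455),
            (70, 30, 16.0, 6.33e-5),
        ],
    )
    def test_closed_form_values(self, n_a, n_b, stat, p):
        s, pv = mp.segregation_chi_square(mp.SegregationCounts(n_a, n_b))
        assert s == pytest.approx(stat, abs=1e-9)
        assert pv == pytest.approx(p, rel=0.01)

    def test_zero_informative_raises(self):
        with pytest.raises(ValueError):
            mp.segregation_chi_square(mp.SegregationCounts(0, 0, n_het=10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mp.SegregationCounts(-1, 5)

    def test_type_one_error_rate_under_true_null(self):
        """1:1 segregation of 430 RILs: rejection at P<=0.01 happens ~1% of the time."""
        rng = np.random.default_rng(7)
        n_markers, n_ind = 10_000, 430
        n_a = rng.binomial(n_ind, 0.5, n_markers)
        rejected = 0
        for a in n_a:
            _, p = mp.segregation_chi_square(mp.SegregationCounts(int(a), n_ind - int(a)))
            rejected += p <= 0.01
        rate = rejected / n_markers
        se = np.sqrt(0.01 * 0.99 / n_markers)
        assert abs(rate - 0.01) <= 3 * se


class TestMarkerFilter:
    def _matrix(self, progeny_cols, parents=("AA", "BB")):
        rows = {f"RIL{i}": [col[i] for col in progeny_cols] for i in range(len(progeny_cols[0]))}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"M{j}" for j in range(len(progeny_cols))])
        pr = pd.DataFrame(
            [[parents[0]] * len(progeny_cols), [parents[1]] * len(progeny_cols)],
            index=["P1", "P2"], columns=df.columns,
        )
        return pd.concat([pr, df])

    def test_excess_missing_rejected_above_15_percent(self):
        n = 430
        col_bad = ["AA"] * 182 + ["BB"] * 183 + ["NN"] * 65  # 65/430 = 15.1%
        col_ok = ["AA"] * 183 + ["BB"] * 183 + ["NN"] * 64   # 64/430 = 14.9%
        m = self._matrix([col_bad, col_ok])
        cats = pd.Series("PHR", index=m.columns)
        reports = {r.marker: r for r in mp.filter_mapping_markers(m, cats)}
        assert "excess_missing" in reports["M0"].rejection_reasons
        assert reports["M1"].kept

    def test_heterozygous_or_missing_parent_rejected(self):
        col = ["AA"] * 50 + ["BB"] * 50
        m = self._matrix([col, col])
        m.loc["P1", "M0"] = "AB"
        m.loc["P2", "M1"] = "NN"
        cats = pd.Series("PHR", index=m.columns)
        reports = {r.marker: r for r in mp.filter_mapping_markers(m, cats)}
        assert reports["M0"].rejection_reasons == ["parent_missing_or_het"]
        assert reports["M1"].rejection_reasons == ["parent_missing_or_het"]

    def test_identical_parents_rejected(self):
        col = ["AA"] * 50 + ["BB"] * 50
        m = self._matrix([col], parents=("AA", "AA"))
        reports = mp.filter_mapping_markers(m, pd.Series("PHR", index=m.columns))
        assert "parent_missing_or_het" in reports[0].rejection_reasons

    def test_distorted_marker_rejected(self):
        col = ["AA"] * 80 + ["BB"] * 20
        m = self._matrix([col])
        reports = mp.filter_mapping_markers(m, pd.Series("PHR", index=m.columns))
        assert "distorted" in reports[0].rejection_reasons

    def test_non_phr_and_not_diploidized_recorded(self):
        col = ["AA"] * 50 + ["BB"] * 50
        m = self._matrix([col, col])
        cats = pd.Series({"M0": "NMH", "M1": "PHR"})
        dip = pd.Series({"M0": True, "M1": False})
        reports = {r.marker: r for r in mp.filter_mapping_markers(m, cats, diploidized=dip)}
        assert "not_PHR" in reports["M0"].rejection_reasons
        assert reports["M1"].rejection_reasons == ["not_diploidized"]

    def test_clean_marker_kept_with_no_reasons(self):
        col = ["AA"] * 50 + ["BB"] * 50
        m = self._matrix([col])
        reports = mp.filter_mapping_markers(m, pd.Series("PHR", index=m.columns))
        assert reports[0].kept and reports[0].rejection_reasons == []

    def test_absent_parent_rows_raise(self):
        m = pd.DataFrame({"M0": ["AA", "BB"]}, index=["RIL1", "RIL2"])
        with pytest.raises(ValueError):
            mp.filter_mapping_markers(m, pd.Series("PHR", index=m.columns))

    def test_reports_are_exhaustive(self, ril_population):
        matrix, truth = ril_population
        cats = pd.Series("PHR", index=matrix.columns)
        reports = mp.filter_mapping_markers(matrix, cats)
        assert len(reports) == matrix.shape[1]
        for r in reports:
            assert r.kept == (len(r.rejection_reasons) == 0)

    def test_distortion_locus_is_caught(self, ril_population):
        matrix, truth = ril_population
        cats = pd.Series("PHR", index=matrix.columns)
        reports = {r.marker: r for r in mp.filter_mapping_markers(matrix, cats)}
        for marker in truth.extra["distortion_markers"]:
            assert "distorted" in reports[marker].rejection_reasons


class TestCosegregationBins:
    def test_identical_columns_share_a_bin(self):
        m = pd.DataFrame({"A": ["AA", "BB", "AA"], "B": ["AA", "BB", "AA"]},
                         index=["i1", "i2", "i3"])
        bins = mp.cosegregation_bins(m)
        assert len(bins) == 1 and bins[0].members == ["A", "B"]

    def test_one_conflicting_individual_separates(self):
        m = pd.DataFrame({"A": ["AA", "BB"], "B": ["AA", "AA"]}, index=["i1", "i2"])
        bins = mp.cosegregation_bins(m)
        assert len(bins) == 2

    def test_known_grouping_and_nonredundant_count(self):
        cols = {
            "A": ["AA", "BB", "AA", "BB"],
            "B": ["AA", "BB", "AA", "BB"],
            "C": ["BB", "AA", "BB", "AA"],
            "D": ["BB", "AA", "BB", "AA"],
            "E": ["AA", "AA", "BB", "BB"],
        }
        bins = mp.cosegregation_bins(pd.DataFrame(cols, index=["i1", "i2", "i3", "i4"]))
        members = sorted(tuple(b.members) for b in bins)
        assert members == [("A", "B"), ("C", "D"), ("E",)]
        assert sum(len(b.members) == 1 for b in bins) == 1

    def test_representative_has_fewest_missing(self):
        m = pd.DataFrame({"A": ["AA", "NN", "AA"], "B": ["AA", "BB", "AA"]},
                         index=["i1", "i2", "i3"])
        bins = mp.cosegregation_bins(m)
        assert len(bins) == 1
        assert bins[0].representative == "B"

    def test_bins_partition_markers(self, ril_population):
        matrix, _ = ril_population
        progeny = matrix.drop(index=["P1", "P2"])
        bins = mp.cosegregation_bins(progeny)
        all_members = [m for b in bins for m in b.members]
        assert sorted(all_members) == sorted(progeny.columns)

    def test_markers_at_identical_positions_share_bins(self):
        cfg = syn.RilScenarioConfig(
            n_individuals=100, n_chromosomes=1, markers_per_chromosome=(4,),
            chromosome_length_cM=(100.0,), marker_positions=((10.0, 10.0, 50.0, 50.0),),
            missing_rate=0.05, seed=3,
        )
        matrix, _ = syn.generate_ril_f6(cfg)
        progeny = matrix.drop(index=["P1", "P2"])
        # identical positions give bitwise-identical columns
        assert progeny["chr1_m001"].equals(progeny["chr1_m002"])
        bins = mp.cosegregation_bins(progeny)
        by_marker = {m: i for i, b in enumerate(bins) for m in b.members}
        assert by_marker["chr1_m001"] == by_marker["chr1_m002"]
        assert by_marker["chr1_m003"] == by_marker["chr1_m004"]


class TestMapSummary:
    def test_direct_computation(self):
        gmap = pd.DataFrame(
            {
                "marker": list("ABCDE"),
                "chromosome": ["1"] * 5,
                "position_cM": [0.0, 0.0, 10.0, 10.0, 20.0],
            }
        )
        bins = [
            mp.CosegregationBin(members=["A", "B"], representative="A"),
            mp.CosegregationBin(members=["C", "D"], representative="C"),
            mp.CosegregationBin(members=["E"], representative="E"),
        ]
        s = mp.map_summary(gmap, bins)
        row = s.loc["1"]
        assert row["n_markers"] == 5
        assert row["map_length_cM"] == 20.0
        assert row["n_unique_positions"] == 3
        assert row["n_nonredundant"] == 1
        assert row["bin_length_cM"] == pytest.approx(6.67)

    def test_single_marker_chromosome(self):
        gmap = pd.DataFrame({"marker": ["A"], "chromosome": ["1"], "position_cM": [5.0]})
        s = mp.map_summary(gmap)
        assert s.loc["1", "map_length_cM"] == 0.0
        assert s.loc["1", "n_unique_positions"] == 1
        assert s.loc["1", "bin_length_cM"] == 0.0

    def test_published_style_totals(self):
        # totals entered as a two-chromosome stand-in reproducing the printed
        # whole-map arithmetic: 3,308 cM over 6,769 unique positions -> 0.49 cM
        total_length, total_unique = 3308.0, 6769
        gmap_rows = []
        pos = np.concatenate([
            np.linspace(0, 1088, 2434),
            np.linspace(0, total_length - 1088, total_unique - 2434),
        ])
        chroms = ["A"] * 2434 + ["B"] * (total_unique - 2434)
        for i, (c, p) in enumerate(zip(chroms, pos)):
            gmap_rows.append({"marker": f"m{i}", "chromosome": c, "position_cM": p})
        s = mp.map_summary(pd.DataFrame(gmap_rows))
        assert s.loc["Total", "n_unique_positions"] == total_unique
        assert s.loc["Total", "map_length_cM"] == pytest.approx(total_length)
        assert s.loc["Total", "bin_length_cM"] == pytest.approx(round(3308 / 6769, 2))
        assert s.loc["Total", "bin_length_cM"] == 0.49

    def test_missing_position_raises(self):
        gmap = pd.DataFrame({"marker": ["A"], "chromosome": ["1"], "position_cM": [np.nan]})
        with pytest.raises(ValueError):
            mp.map_summary(gmap)

    def test_unique_positions_match_generator_truth(self, ril_population):
        _, truth = ril_population
        gmap = truth.genetic_map
        s = mp.map_summary(gmap)
        for chrom, grp in gmap.groupby("chromosome"):
            assert s.loc[chrom, "n_unique_positions"] == grp["position_cM"].nunique()


class TestCompareMaps:
    def _map(self, positions):
        return pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(len(positions))],
                "chromosome": ["1"] * len(positions),
                "position_cM": positions,
            }
        )

    def test_identical_maps_correlate_perfectly(self):
        a = self._map(np.arange(10.0))
        per_chrom, avg = mp.compare_maps(a, a)
        assert per_chrom["1"] == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)

    def test_reversed_map_anticorrelates(self):
        a = self._map(np.arange(10.0))
        b = self._map(np.arange(10.0)[::-1])
        per_chrom, _ = mp.compare_maps(a, b)
        assert per_chrom["1"] == pytest.approx(-1.0)

    def test_inverted_segment_matches_hand_computed_spearman(self):
        from scipy.stats import spearmanr

        pos_a = np.arange(10.0)
        pos_b = pos_a.copy()
        pos_b[3:6] = pos_b[3:6][::-1]  # one 3-marker inversion
        per_chrom, _ = mp.compare_maps(self._map(pos_a), self._map(pos_b))
        expect, _ = spearmanr(pos_a, pos_b)
        assert per_chrom["1"] == pytest.approx(expect, abs=1e-12)

    def test_insufficient_overlap_skipped_with_warning(self):
        a = self._map([0.0, 1.0])
        b = self._map([0.0, 1.0])
        with pytest.warns(UserWarning):
            per_chrom, avg = mp.compare_maps(a, b)
        assert len(per_chrom) == 0 and np.isnan(avg)
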