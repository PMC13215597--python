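"""Benchmark metrics: binning, confusion, BACC, RMSE, dispersion, breakpoints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecn import evaluate as ev


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])


CHROMS = {"chr1": 1_000_000}


class TestBinAndClassify:
    def test_identical_profiles_perfect_scores(self):
        truth = seg_frame([("chr1", 0, 400_000, 3), ("chr1", 400_000, 1_000_000, 2)])
        out = ev.bin_and_classify(truth, truth, CHROMS)
        assert out["fp"] == out["fn"] == 0
        assert out["precision"] == out["recall"] == 1.0

    def test_hand_confusion_table(self):
        # 10 bins of 100 kb; truth CNV bins 0-3, inferred CNV bins 2-5;
        # the breakpoint bins are exactly at segment edges so none straddle
        truth = seg_frame(
            [("chr1", 0, 400_000, 3), ("chr1", 400_000, 1_000_000, 2)]
        )
        pred = seg_frame(
            [
                ("chr1", 0, 200_000, 2),
                ("chr1", 200_000, 600_000, 3),
                ("chr1", 600_000, 1_000_000, 2),
            ]
        )
        out = ev.bin_and_classify(truth, pred, CHROMS)
        # hand tally over bins 0..9: truth + = {0,1,2,3}, pred + = {2,3,4,5}
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (2, 2, 2, 4)
        assert out["precision"] == pytest.approx(0.5)
        assert out["recall"] == pytest.approx(0.5)
        assert out["accuracy"] == pytest.approx(0.6)

    def test_all_diploid_degenerate_rates_default_to_one(self):
        truth = seg_frame([("chr1", 0, 1_000_000, 2)])
        out = ev.bin_and_classify(truth, truth, CHROMS)
        assert out["accuracy"] == 1.0
        assert out["precision"] == 1.0
        assert out["recall"] == 1.0

    def test_breakpoint_bins_excluded(self):
        truth = seg_frame(
            [("chr1", 0, 450_000, 3), ("chr1", 450_000, 1_000_000, 2)]
        )
        out = ev.bin_and_classify(truth, truth, CHROMS)
        # the bin [400k,500k) straddles the 450k breakpoint in both profiles
        assert out["bins_excluded"] == 1
        assert out["n_bins"] == 9


class TestBaccSubclones:
    def _profiles(self):
        a = seg_frame([("chr1", 0, 500_000, 3), ("chr1", 500_000, 1_000_000, 2)])
        b = seg_frame([("chr1", 0, 500_000, 2), ("chr1", 500_000, 1_000_000, 1)])
        c = seg_frame([("chr1", 0, 1_000_000, 2)])
        return a, b, c

    def test_perfect_three_clone_recovery(self):
        a, b, c = self._profiles()
        cells = pd.Series(
            [0] * 30 + [1] * 20 + [2] * 50,
            index=[f"c{i}" for i in range(100)],
        )
        out = ev.bacc_subclones(
            cells, cells, {0: a, 1: b, 2: c}, {0: a, 1: b, 2: c}, CHROMS
        )
        assert out == pytest.approx(1.0)

    def test_split_clone_matches_hand_value(self):
        a, b, _ = self._profiles()
        truth_cells = pd.Series([0] * 40, index=[f"c{i}" for i in range(40)])
        # inferred splits the clone 50/50; clone 0 matched to inferred 0
        inf_cells = pd.Series(
            [0] * 20 + [1] * 20, index=[f"c{i}" for i in range(40)]
        )
        out = ev.bacc_subclones(
            truth_cells, inf_cells, {0: a}, {0: a, 1: b}, CHROMS
        )
        # matched profile identical -> BACC 1.0 with weight 1.0
        assert out == pytest.approx(1.0)

    def test_wrong_profile_scores_half(self):
        a, b, c = self._profiles()
        cells = pd.Series([0] * 10, index=[f"c{i}" for i in range(10)])
        # inferred calls everything diploid: TPR 0 on CNV bins, TNR 1
        out = ev.bacc_subclones(cells, cells, {0: a}, {0: c}, CHROMS)
        assert out == pytest.approx(0.5)

    def test_single_clone_equal_profiles(self):
        a, _, _ = self._profiles()
        cells = pd.Series([0] * 5, index=list("abcde"))
        assert ev.bacc_subclones(cells, cells, {0: a}, {0: a}, CHROMS) == 1.0

    def test_hungarian_matching_maximizes_overlap(self):
        truth = pd.Series([0] * 60 + [1] * 40, index=[f"c{i}" for i in range(100)])
        # inferred labels swapped relative to truth ids
        inferred = pd.Series([1] * 60 + [0] * 40, index=[f"c{i}" for i in range(100)])
        m = ev.match_clones(truth, inferred)
        assert m == {0: 1, 1: 0}


class TestRmse:
    def test_exact_integer_match_zero(self):
        assert ev.rmse_integer_cn([2, 3, 2], [2, 3, 2]) == 0.0

    def test_centering_aligns_scores(self):
        # scores (0.1,0.1,0.9) with truth (2,2,3) center to exactly (2,2,3)
        out = ev.rmse_integer_cn([2, 2, 3], [0.1, 0.1, 0.9], method_kind="score")
        assert out == pytest.approx(0.0)

    def test_constant_bias_closed_form(self):
        assert ev.rmse_integer_cn([2, 2, 4], [2.5, 2.5, 4.5]) == pytest.approx(0.5)


class TestDispersionScore:
    def test_separated_point_masses_score_one(self):
        values = np.array([1.0] * 20 + [2.0] * 20)
        cn = np.array([2] * 20 + [3] * 20)
        assert ev.dispersion_score(values, cn) == pytest.approx(1.0)

    def test_identical_distributions_score_zero(self, rng):
        values = np.concatenate([rng.normal(0, 1, 500), rng.normal(0, 1, 500)])
        cn = np.array([2] * 500 + [3] * 500)
        assert ev.dispersion_score(values, cn) == pytest.approx(0.0, abs=0.1)

    def test_two_sigma_separation_matches_quadrature(self, rng):
        a = rng.normal(0, 1, 4000)
        b = rng.normal(2, 1, 4000)
        score = ev.dispersion_score(
            np.concatenate([a, b]), np.array([2] * 4000 + [3] * 4000)
        )
        # quadrature oracle: overlap of N(0,1) and N(2,1) densities
        from scipy.stats import norm

        grid = np.linspace(-6, 8, 4000)
        overlap = np.trapezoid(
            np.minimum(norm.pdf(grid, 0, 1), norm.pdf(grid, 2, 1)), grid
        )
        assert score == pytest.approx(1.0 - overlap, abs=0.05)

    def test_monotone_in_separation(self, rng):
        scores = []
        for sep in (0.5, 1.0, 2.0, 4.0):
            a = rng.normal(0, 1, 2000)
            b = rng.normal(sep, 1, 2000)
            scores.append(
                ev.dispersion_score(
                    np.concatenate([a, b]), np.array([2] * 2000 + [3] * 2000)
                )
            )
        assert scores == sorted(scores)

    def test_single_state_undefined(self):
        assert ev.dispersion_score(np.ones(10), np.full(10, 2)) is None


class TestBreakpointDeviation:
    def test_exact_recovery_zero(self):
        bp = pd.DataFrame({"chrom": ["chr1"], "pos": [30_000_000]})
        mean, devs, unmatched = ev.breakpoint_deviation(bp, bp)
        assert mean == 0.0 and unmatched == 0

    def test_one_megabase_offset(self):
        t = pd.DataFrame({"chrom": ["chr1"], "pos": [30_000_000]})
        p = pd.DataFrame({"chrom": ["chr1"], "pos": [31_000_000]})
        mean, _, _ = ev.breakpoint_deviation(t, p)
        assert mean == pytest.approx(1.0)

    def test_matches_brute_force_nearest_neighbor(self, rng):
        t = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=20),
                "pos": rng.integers(0, 10**8, size=20),
            }
        )
        p = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=15),
                "pos": rng.integers(0, 10**8, size=15),
            }
        )
        mean, devs, unmatched = ev.breakpoint_deviation(t, p, max_match_mb=None)
        expected = []
        for _, row in t.iterrows():
            cand = p.loc[p["chrom"] == row["chrom"], "pos"].to_numpy()
            if len(cand):
                expected.append(np.min(np.abs(cand - row["pos"])) / 1e6)
        assert mean == pytest.approx(np.mean(expected))

    def test_matching_radius_reclassifies_distant_breakpoints(self):
        t = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10**7, 9 * 10**7]})
        p = pd.DataFrame({"chrom": ["chr1"], "pos": [10**7 + 500_000]})
        mean, devs, unmatched = ev.breakpoint_deviation(t, p, max_match_mb=10.0)
        assert devs == [pytest.approx(0.5)]
        assert unmatched == 1

    def test_unmatched_chromosome_counted(self):
        t = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos": [10, 20]})
        p = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        mean, devs, unmatched = ev.breakpoint_deviation(t, p)
        assert unmatched == 1 and len(devs) == 1


class TestClassifyPeaks:
    def test_overlap_rules(self):
        cnv = seg_frame([("chr1", 1000, 2000, 3)])
        chrom = np.array(["chr1", "chr1", "chr2", "chr1"], dtype=object)
        start = np.array([1200, 5000, 1200, 900])
        end = np.array([1300, 5100, 1300, 1100])  # last one straddles 1000
        out = ev.classify_peaks_by_cnv(chrom, start, end, cnv)
        assert list(out) == [
            "cnv_driven",
            "cre_regulated",
            "cre_regulated",
            "cnv_driven",
        ]

    def test_matches_brute_force_overlap(self, rng):
        cnv = seg_frame(
            [("chr1", int(s), int(s) + 50_000, 3) for s in rng.integers(0, 10**6, 5)]
        )
        start = rng.integers(0, 1_100_000, 200)
        end = start + 500
        chrom = np.array(["chr1"] * 200, dtype=object)
        out = ev.classify_peaks_by_cnv(chrom, start, end, cnv)
        for i in range(200):
            hit = any(
                start[i] < r["end"] and end[i] > r["start"]
                for _, r in cnv.iterrows()
            )
            assert (out[i] == "cnv_driven") == hit


@settings(max_examples=50, deadline=None)
@given(
    bins=st.lists(
        st.tuples(st.sampled_from([1, 2, 3, 4]), st.sampled_from([1, 2, 3, 4])),
        min_size=1,
        max_size=40,
    )
)
def test_confusion_rate_identities(bins):
    """bin_and_classify rates satisfy their definitional identities on
    arbitrary bin-aligned truth/prediction pairs."""
    bin_size = 100_000
    chroms = {"chr1": len(bins) * bin_size}
    truth = seg_frame(
        [("chr1", i * bin_size, (i + 1) * bin_size, t) for i, (t, _) in enumerate(bins)]
    )
    pred = seg_frame(
        [("chr1", i * bin_size, (i + 1) * bin_size, p) for i, (_, p) in enumerate(bins)]
    )
    out = ev.bin_and_classify(truth, pred, chroms)
    tp, fp, fn, tn = out["tp"], out["fp"], out["fn"], out["tn"]
    # hand tally
    t_pos = np.array([t != 2 for t, _ in bins])
    p_pos = np.array([p != 2 for _, p in bins])
    assert tp == np.sum(t_pos & p_pos)
    assert fp == np.sum(~t_pos & p_pos)
    assert fn == np.sum(t_pos & ~p_pos)
    assert tn == np.sum(~t_pos & ~p_pos)
    assert out["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 1.0)
    assert out["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 1.0)
    assert out["accuracy"] == pytest.approx((tp + tn) / len(bins))
    if out["precision"] + out["recall"]:
        assert out["f1"] == pytest.approx(
            2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
        )
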