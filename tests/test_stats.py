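import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from dmsort import library as lib
from dmsort import simulate as sim
from dmsort import stats as st

from conftest import counts_from_truth
from mw_oracle import exact_two_sided_p


def make_counts(manifest, low, high):
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in manifest.clones],
            "clone_id": [c.clone_id for c in manifest.clones],
            "count_low": low,
            "count_high": high,
        }
    )


class TestBarcodeScores:
    def test_direct_arithmetic(self, small_manifest):
        n = len(small_manifest)
        counts = make_counts(small_manifest, [2] * n, [8] * n)
        scores = st.barcode_scores(counts, small_manifest, pseudocount=0.5)
        assert scores["score"].iloc[0] == pytest.approx(
            np.log2(8.5) - np.log2(2.5), abs=1e-12
        )
        assert scores["score"].iloc[0] == pytest.approx(1.7655, abs=5e-4)

    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0])
    def test_equal_counts_score_zero(self, small_manifest, c):
        n = len(small_manifest)
        counts = make_counts(small_manifest, [7] * n, [7] * n)
        scores = st.barcode_scores(counts, small_manifest, pseudocount=c)
        assert np.allclose(scores["score"], 0.0)

    def test_zero_count_barcodes_score_zero(self, small_manifest):
        n = len(small_manifest)
        counts = make_counts(small_manifest, [0] * n, [0] * n)
        scores = st.barcode_scores(counts, small_manifest, pseudocount=0.5)
        assert len(scores) == n
        assert np.allclose(scores["score"], 0.0)

    def test_unknown_barcode_is_consistency_error(self, small_manifest):
        counts = pd.DataFrame(
            {"barcode": ["T" * 15], "clone_id": ["x"], "count_low": [1], "count_high": [1]}
        )
        with pytest.raises(st.StatsError):
            st.barcode_scores(counts, small_manifest)

    def test_low_total_filter_drops_barcodes(self, small_manifest):
        n = len(small_manifest)
        low = [0] * n
        low[0] = 10
        counts = make_counts(small_manifest, low, [0] * n)
        scores = st.barcode_scores(counts, small_manifest, min_total_reads=5)
        assert len(scores) == 1


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        u, p = st.mann_whitney_two_sided([1, 2, 3], [4, 5, 6], method="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one_on_approx_path(self):
        _u, p = st.mann_whitney_two_sided([1, 2, 3], [1, 2, 3], method="approx")
        assert p == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n, m = rng.integers(1, 6), rng.integers(1, 6)
            values = rng.permutation(50)[: n + m].astype(float)
            x, y = values[:n], values[n:]
            _u, p = st.mann_whitney_two_sided(x, y, method="exact")
            assert p == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)

    def test_auto_selects_exact_only_without_ties_and_small_n(self):
        x, y = [1.0, 2.0], [3.0, 4.0, 5.0]
        auto = st.mann_whitney_two_sided(x, y, method="auto")
        exact = st.mann_whitney_two_sided(x, y, method="exact")
        assert auto == exact
        tied = st.mann_whitney_two_sided([1.0, 1.0], [1.0, 2.0], method="auto")
        approx = st.mann_whitney_two_sided([1.0, 1.0], [1.0, 2.0], method="approx")
        assert tied == approx

    def test_empty_sample_rejected(self):
        with pytest.raises(st.StatsError):
            st.mann_whitney_two_sided([], [1.0])


class TestVariantTest:
    NULL = np.linspace(-1, 1, 289)

    def test_complete_separation_has_positive_direction_and_four_stars(self):
        variant = lib.Variant(171, "A", "L")
        scores = np.linspace(5, 6, 11)
        res = st.variant_test(variant, scores, self.NULL)
        assert res.direction == 1
        assert res.p_two_sided < 1e-4
        assert res.stars == "****"
        assert res.signed_logp > 4

    def test_null_draw_scores_near_zero_signed_logp(self):
        rng = np.random.default_rng(8)
        variant = lib.Variant(171, "A", "L")
        logps = [
            st.variant_test(variant, rng.choice(self.NULL, 11), self.NULL).signed_logp
            for _ in range(50)
        ]
        assert abs(np.mean(logps)) < 0.5

    @pytest.mark.parametrize(
        "p,expected",
        [(0.049, "*"), (0.05, "ns"), (0.009, "**"), (0.0009, "***"), (0.00009, "****"), (1.0, "ns")],
    )
    def test_star_thresholds_are_strict(self, p, expected):
        assert st._stars(p) == expected

    def test_stars_never_strengthen_as_p_increases(self):
        order = {"ns": 0, "*": 1, "**": 2, "***": 3, "****": 4}
        grid = np.logspace(-6, 0, 200)
        strengths = [order[st._stars(p)] for p in grid]
        assert strengths == sorted(strengths, reverse=True)

    def test_low_barcode_count_flagged_not_dropped(self):
        variant = lib.Variant(171, "A", "L")
        res = st.variant_test(variant, [2.0], self.NULL)
        assert res.flags == "low_n"
        assert res.n_barcodes == 1


class TestAntisymmetry:
    @given(data=hs.data())
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_swapping_bins_negates_scores_flips_directions(self, data, small_manifest):
        n = len(small_manifest)
        low = data.draw(hs.lists(hs.integers(0, 500), min_size=n, max_size=n))
        high = data.draw(hs.lists(hs.integers(0, 500), min_size=n, max_size=n))
        fwd = st.run_screen(make_counts(small_manifest, low, high), small_manifest)[0]
        rev = st.run_screen(make_counts(small_manifest, high, low), small_manifest)[0]
        assert np.allclose(fwd["p"], rev["p"], rtol=1e-12)
        assert (fwd["direction"] == -rev["direction"]).all()
        assert np.allclose(fwd["signed_logp"], -rev["signed_logp"], atol=1e-12)


class TestRunScreen:
    def test_programmed_positive_variant_tops_signed_logp(self, small_manifest):
        target = next(
            c.variant for c in small_manifest.clones
            if c.variant.clazz == lib.CLASS_MISSENSE
        )
        effects = sim.EffectTable.null(small_manifest).with_effects({target.label: 3.0})
        cfg = sim.SimConfig(n_cells=40_000, reads_per_bin=100_000, rng_seed=17)
        truth = sim.simulate_counts(small_manifest, effects, cfg)
        results, heatmap = st.run_screen(counts_from_truth(truth), small_manifest)
        best = results.loc[results["signed_logp"].idxmax()]
        assert (best["position"], best["sub_aa"]) == (target.position, target.sub_aa)
        key = "STOP" if target.sub_aa == lib.STOP else target.sub_aa
        assert heatmap.loc[key, target.position] == best["signed_logp"]

    def test_empty_counts_empty_results(self):
        manifest = lib.LibraryManifest(clones=())
        results, heatmap = st.run_screen(
            pd.DataFrame(columns=["barcode", "clone_id", "count_low", "count_high"]),
            manifest,
        )
        assert len(results) == 0
        assert heatmap.isna().all().all()

    def test_one_result_per_distinct_non_wt_variant(self, small_manifest):
        n = len(small_manifest)
        truth = sim.simulate_counts(
            small_manifest, sim.EffectTable.null(small_manifest),
            sim.SimConfig(n_cells=5_000, reads_per_bin=20_000, rng_seed=19),
        )
        results, _ = st.run_screen(counts_from_truth(truth), small_manifest)
        distinct = {
            c.variant.key() for c in small_manifest.clones
            if c.variant.clazz != lib.CLASS_WT_SYN
        }
        assert len(results) == len(distinct)

    def test_missing_null_set_is_configuration_error(self):
        design = lib.LibraryDesign(
            n_wt_syn=0, n_stop=0, n_missense_clones=2,
            barcodes_per_missense={(171, "L"): 2}, rng_seed=0,
        )
        manifest = lib.build_manifest(design)
        counts = make_counts(manifest, [1, 2], [3, 4])
        with pytest.raises(st.StatsError, match="null"):
            st.run_screen(counts, manifest)

    def test_bh_column_never_alters_stars(self, small_manifest):
        truth = sim.simulate_counts(
            small_manifest, sim.EffectTable.null(small_manifest),
            sim.SimConfig(n_cells=5_000, reads_per_bin=20_000, rng_seed=23),
        )
        counts = counts_from_truth(truth)
        with_bh, _ = st.run_screen(counts, small_manifest, st.StatsConfig(include_bh=True))
        without, _ = st.run_screen(counts, small_manifest, st.StatsConfig(include_bh=False))
        assert "q_bh" in with_bh.columns and "q_bh" not in without.columns
        assert (with_bh["stars"] == without["stars"]).all()


class TestHeatmap:
    def test_shape_rows_and_wild_type_cells_missing(self, small_manifest):
        truth = sim.simulate_counts(
            small_manifest, sim.EffectTable.null(small_manifest),
            sim.SimConfig(n_cells=5_000, reads_per_bin=20_000, rng_seed=29),
        )
        results, heatmap = st.run_screen(counts_from_truth(truth), small_manifest)
        assert heatmap.shape == (21, 16)
        assert list(heatmap.index) == list(lib.AA20) + ["STOP"]
        # wild-type identity cells are never populated
        for pos in range(lib.WINDOW_START, lib.WINDOW_END + 1):
            wt = lib.DEFAULT_REFERENCE_SEGMENT[pos - lib.WINDOW_START]
            assert np.isnan(heatmap.loc[wt, pos])
        # cell present iff the variant was tested
        tested = {(r.sub_aa if r.sub_aa != lib.STOP else "STOP", r.position)
                  for r in results.itertuples()}
        present = {
            (row, col)
            for row in heatmap.index for col in heatmap.columns
            if not np.isnan(heatmap.loc[row, col])
        }
        assert present == tested

    def test_round_trip_tsv(self, tmp_path, small_manifest):
        truth = sim.simulate_counts(
            small_manifest, sim.EffectTable.null(small_manifest),
            sim.SimConfig(n_cells=5_000, reads_per_bin=20_000, rng_seed=31),
        )
        _results, heatmap = st.run_screen(counts_from_truth(truth), small_manifest)
        path = tmp_path / "heatmap.tsv"
        st.write_heatmap(heatmap, path)
        back = pd.read_csv(path, sep="\t", index_col="substitution")
        back.columns = back.columns.astype(int)
        assert np.allclose(back.to_numpy(), heatmap.to_numpy(), equal_nan=True)


class TestCrosslinkFraction:
    @pytest.mark.parametrize(
        "crosslinked,total,expected",
        [(30, (30, 70), 30.0), (0, (0, 50), 0.0), (12.5, (12.5,), 100.0)],
    )
    def test_printed_ratio(self, crosslinked, total, expected):
        assert st.crosslink_fraction(crosslinked, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(st.StatsError):
            st.crosslink_fraction(1.0, (0.0, 0.0))
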