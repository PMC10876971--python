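import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from focalamp import cohort_stats as cs
from focalamp.focal_typing import SampleCall
from focalamp.genome_io import CircleMapRecord
from focalamp.simulate import simulate_expression_study


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        got = cs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert cs.benjamini_hochberg([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(cs.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_idempotent(self, pvals):
        adj = cs.benjamini_hochberg(pvals)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestOddsRatio:
    def test_cross_product_worked_examples(self):
        or_, p = cs.odds_ratio([[101, 63], [353, 478]])
        assert or_ == pytest.approx(2.17, abs=0.005)
        assert p < 0.001
        or2, p2 = cs.odds_ratio([[7, 157], [7, 824]])
        assert or2 == pytest.approx(5.2484, abs=1e-3)
        assert p2 < 0.01

    def test_conditional_mle_matches_fisher_convention(self):
        or_, _ = cs.odds_ratio([[7, 157], [7, 824]], estimator="fisher_cmle")
        assert or_ == pytest.approx(5.24, abs=0.005)

    def test_unit_table_is_symmetric(self):
        assert cs.odds_ratio([[1, 1], [1, 1]])[0] == 1.0

    def test_zero_cell_suggests_cmle(self):
        with pytest.raises(ValueError, match="fisher_cmle"):
            cs.odds_ratio([[0, 5], [3, 7]])

    def test_swap_invariances(self, rng):
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2))
            base = cs.odds_ratio(t)[0]
            both_swapped = t[::-1, ::-1]
            assert cs.odds_ratio(both_swapped)[0] == pytest.approx(base)
            rows_swapped = t[::-1, :]
            assert cs.odds_ratio(rows_swapped)[0] == pytest.approx(1 / base)


class TestMutualExclusivity:
    def test_exclusive_flags_give_or_below_one(self):
        a = np.array([True] * 50 + [False] * 50)
        b = np.array([False] * 50 + [True] * 48 + [False] * 2)
        table, or_, p = cs.mutual_exclusivity(a, b)
        assert or_ < 1 and p < 0.05
        assert table[0, 0] == 0

    def test_independent_flags_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a = rng.random(60) < 0.4
            b = rng.random(60) < 0.4
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue
            ps.append(cs.mutual_exclusivity(a, b)[2])
        # Fisher p under the null: conservative, so only a sanity band
        assert 0.2 < np.mean(np.array(ps) < 0.5) < 0.8

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cs.mutual_exclusivity([True, True], [True, False])


class TestFoldChange:
    def test_direct_evaluation(self):
        expr = pd.DataFrame(
            {
                "sample_id": ["A", "B", "C"],
                "gene_id": "G",
                "TPM": [9.0, 1.0, 3.0],
            }
        )
        fc = cs.fold_change_uq(expr, {"G": {"A"}})
        assert fc["fold_change"].iloc[0] == pytest.approx(10 / 3)

    def test_identical_expression_gives_unit_fold_change(self):
        expr = pd.DataFrame(
            {"sample_id": list("ABC"), "gene_id": "G", "TPM": [4.0, 4.0, 4.0]}
        )
        fc = cs.fold_change_uq(expr, {"G": {"B"}})
        assert fc["fold_change"].iloc[0] == 1.0

    def test_zero_tpm_boundary(self):
        expr = pd.DataFrame(
            {"sample_id": list("ABC"), "gene_id": "G", "TPM": [0.0, 1.0, 1.0]}
        )
        fc = cs.fold_change_uq(expr, {"G": {"A"}})
        assert fc["fold_change"].iloc[0] == 0.5

    def test_no_reference_sample_skips_gene(self):
        expr = pd.DataFrame({"sample_id": ["A"], "gene_id": "G", "TPM": [5.0]})
        assert cs.fold_change_uq(expr, {"G": {"A"}}).empty


class TestCompareFcModels:
    @staticmethod
    def _data(slope_a, slope_b, n, noise, seed):
        rng = np.random.default_rng(seed)
        cn = rng.uniform(5, 50, size=2 * n)
        klass = np.array(["circular"] * n + ["noncircular"] * n)
        slope = np.where(klass == "circular", slope_a, slope_b)
        fc = slope * cn + 1.0 + rng.normal(0, noise, size=2 * n)
        return pd.DataFrame({"fold_change": fc, "CN": cn, "klass": klass})

    def test_null_rarely_significant(self):
        hits = 0
        for seed in range(20):
            fit = cs.compare_fc_models(self._data(1.0, 1.0, 60, 2.0, seed))
            hits += fit.p_value < 0.05
        assert hits <= 2  # >= 90% of null seeds stay non-significant

    def test_distinct_slopes_detected(self):
        fit = cs.compare_fc_models(self._data(1.0, 3.0, 100, 1.0, 0))
        assert fit.p_value < 1e-3
        assert fit.slopes["noncircular"] > fit.slopes["circular"]

    def test_per_class_fits_match_standalone_ols(self):
        df = self._data(1.0, 2.0, 50, 1.0, 1)
        fit = cs.compare_fc_models(df)
        for klass, sub in df.groupby("klass"):
            m, b = np.polyfit(sub["CN"], sub["fold_change"], 1)
            assert fit.slopes[klass] == pytest.approx(m)
            assert fit.intercepts[klass] == pytest.approx(b)

    def test_missing_class_rejected(self):
        df = self._data(1, 1, 10, 1, 0)
        with pytest.raises(ValueError, match="class"):
            cs.compare_fc_models(df[df["klass"] == "circular"])


class TestRegression:
    def test_recovers_planted_boost(self):
        df = simulate_expression_study(
            n_samples=500, n_signal_genes=2, n_null_genes=3, b=50.0, seed=4
        )
        res = {r.gene_id: r for r in cs.ecdna_oncogene_regression(df)}
        for gid, r in res.items():
            if gid.startswith("SIG"):
                assert abs(r.coef_circular - 50) / 50 < 0.15
                assert r.is_ecdna_associated
            else:
                assert not np.isnan(r.p_circular)

    def test_single_level_gene_gets_missing_p(self):
        df = simulate_expression_study(n_samples=80, n_signal_genes=1, n_null_genes=1, seed=0)
        df.loc[df["gene_id"] == "NULL001", "circular"] = 0
        res = {r.gene_id: r for r in cs.ecdna_oncogene_regression(df)}
        assert np.isnan(res["NULL001"].p_circular)
        assert not res["NULL001"].is_ecdna_associated

    def test_no_testable_gene_rejected(self):
        df = simulate_expression_study(n_samples=30, n_signal_genes=0, n_null_genes=2, seed=0)
        df["circular"] = 0
        with pytest.raises(ValueError, match="testable"):
            cs.ecdna_oncogene_regression(df)

    def test_coefficients_within_three_standard_errors(self):
        """Parameter recovery for a=5, b=50, d=10 on the generative model."""
        ok = 0
        for seed in range(10):
            df = simulate_expression_study(
                n_samples=400, n_signal_genes=1, n_null_genes=0, seed=seed
            )
            (r,) = cs.ecdna_oncogene_regression(df)
            close = (
                abs(r.coef_cn - 5) < 1.0
                and abs(r.coef_circular - 50) < 7.5
                and abs(r.coef_purity - 10) < 6.0
            )
            ok += close
        assert ok >= 9


class TestWindows:
    LENGTHS = {"1": 3_000_000}

    def test_single_window_entry(self):
        entries = pd.DataFrame(
            [{"chrom": "1", "start": 500_001, "end": 600_000, "klass": "circular"}]
        )
        w = cs.windowed_frequency(entries, self.LENGTHS)
        assert w.loc[0, "circular_count"] == 1
        assert w["circular_count"].sum() == 1

    def test_straddling_entry_counted_in_both(self):
        entries = pd.DataFrame(
            [{"chrom": "1", "start": 999_001, "end": 1_001_000, "klass": "noncircular"}]
        )
        w = cs.windowed_frequency(entries, self.LENGTHS)
        assert w["noncircular_count"].tolist() == [1, 1, 0]

    def test_empty_input_gives_zero_tiling(self):
        w = cs.windowed_frequency(pd.DataFrame(columns=["chrom", "start", "end", "klass"]), self.LENGTHS)
        assert len(w) == 3
        assert (w[["circular_count", "noncircular_count"]] == 0).all().all()

    def test_out_of_bounds_rejected(self):
        entries = pd.DataFrame(
            [{"chrom": "1", "start": 2_999_999, "end": 3_000_001, "klass": "circular"}]
        )
        with pytest.raises(ValueError, match="outside"):
            cs.windowed_frequency(entries, self.LENGTHS)

    def test_mass_conserved_for_single_window_entries(self, rng):
        rows = []
        for _ in range(50):
            w_idx = int(rng.integers(0, 3))
            start = w_idx * 1_000_000 + int(rng.integers(1, 900_000))
            rows.append(
                {
                    "chrom": "1",
                    "start": start,
                    "end": start + int(rng.integers(1, 90_000)),
                    "klass": "circular" if rng.random() < 0.5 else "noncircular",
                }
            )
        entries = pd.DataFrame(rows)
        w = cs.windowed_frequency(entries, self.LENGTHS)
        assert w["circular_count"].sum() + w["noncircular_count"].sum() == 50


def _record(**kw):
    base = dict(
        chrom="1",
        start=0,
        end=20_000,
        discordant_reads=2,
        split_reads=4,
        circle_score=60.0,
        mean_coverage=5.0,
        coverage_sd=1.0,
        coverage_continuity=0.05,
    )
    base.update(kw)
    return CircleMapRecord(**base)


class TestCircleMapFilter:
    def test_each_criterion_boundary(self):
        records = [
            _record(),  # passes everything
            _record(circle_score=50.0),  # strict >
            _record(discordant_reads=1),  # strict >
            _record(split_reads=3),  # >= 4
            _record(mean_coverage=4.0),  # strict >
            _record(coverage_continuity=0.1),  # strict <
            _record(end=10_000),  # length strict > 10 kb
        ]
        kept = cs.filter_circle_map(records)
        assert kept == [records[0]]

    def test_subset_and_idempotent(self, rng):
        records = [
            _record(
                circle_score=float(rng.uniform(0, 100)),
                discordant_reads=int(rng.integers(0, 5)),
                split_reads=int(rng.integers(0, 8)),
                mean_coverage=float(rng.uniform(0, 10)),
                coverage_continuity=float(rng.uniform(0, 0.3)),
                end=int(rng.integers(1, 30_000)),
            )
            for _ in range(50)
        ]
        kept = cs.filter_circle_map(records)
        assert all(r in records for r in kept)
        assert cs.filter_circle_map(kept) == kept


class TestCohortSummary:
    @staticmethod
    def _cohort(n_circ, n_noncirc, n_total):
        calls = []
        for i in range(n_circ):
            calls.append(SampleCall(f"C{i}", "circular", ("G",)))
        for i in range(n_noncirc):
            calls.append(SampleCall(f"N{i}", "noncircular"))
        for i in range(n_total - n_circ - n_noncirc):
            calls.append(SampleCall(f"F{i}", "nofocal"))
        return calls

    def test_printed_percentage_arithmetic(self):
        summary = cs.cohort_summary(self._cohort(164, 246, 1015))
        assert summary["circular"] == {"count": 164, "percent": 16.2}
        assert summary["noncircular"] == {"count": 246, "percent": 24.2}

    def test_zero_class(self):
        summary = cs.cohort_summary(self._cohort(0, 0, 10))
        assert summary["circular"]["percent"] == 0.0
        assert summary["nofocal"]["count"] == 10

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.cohort_summary([])
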