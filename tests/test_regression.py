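"""Per-class binomial regressions, concordance and the GC-content trend."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats

from _oracles import irls_logit_fit, random_nondegenerate_table
from hetspec.classes import MutationClass, class_labels, enumerate_classes, gc_content
from hetspec.regression import (
    ClassCountTable,
    SlopeEstimate,
    TripletSpectrumModel,
    cross_region_concordance,
    fit_class_regression,
    gc_trend,
    slope_table,
    tabulate_counts,
)
from hetspec.selection import FocalVariant


def make_variant(label, region="Africa", copy=1, het_bin=1, pos=100):
    return FocalVariant(
        chrom="ctg1", pos=pos, region=region, copy_number=copy,
        major_allele="A", minor_allele="G", carrier_samples=(0,),
        mutation_class=MutationClass.from_label(label), het_score=float(het_bin),
        het_bin=het_bin,
    )


def table_from_counts(rows):
    """rows: (region, copy, bin, {label: count})"""
    labels = list(class_labels())
    idx = pd.MultiIndex.from_tuples(
        [(r, c, b) for r, c, b, _ in rows], names=["region", "copy_number", "het_bin"]
    )
    df = pd.DataFrame(0, index=idx, columns=labels)
    for i, (_, _, _, counts) in enumerate(rows):
        for lbl, n in counts.items():
            df.iloc[i, df.columns.get_loc(lbl)] = n
    return ClassCountTable(df)


class TestTabulate:
    def test_counts_and_margins(self):
        variants = [
            make_variant("ACA(T)", pos=1),
            make_variant("ACA(T)", pos=2),
            make_variant("TCC(T)", pos=3),
        ]
        table = tabulate_counts(variants)
        row = table.counts.loc[("Africa", 1, 1)]
        assert row["ACA(T)"] == 2 and row["TCC(T)"] == 1
        assert table.margins.loc[("Africa", 1, 1)] == 3
        assert set(table.counts.columns) == set(class_labels())

    def test_empty_input_gives_empty_table(self):
        table = tabulate_counts([])
        assert table.total == 0
        assert list(table.counts.columns) == list(class_labels())

    def test_total_conservation(self, smoke_analysis):
        table = smoke_analysis.counts
        assert table.total == len(smoke_analysis.focal)
        # per-row proportions sum to exactly 1
        props = table.counts.div(table.margins, axis=0)
        assert np.allclose(props.sum(axis=1), 1.0)


class TestFitClassRegression:
    def test_flat_proportions_give_zero_slope(self):
        rows = [
            ("Africa", 1, b, {"ACA(T)": 50, "TCC(T)": 450}) for b in range(1, 11)
        ]
        est = fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)
        assert est.status == "ok"
        assert abs(est.slope) < 1e-8

    def test_two_bin_closed_form_logit_difference(self):
        """Bins 1,2 with proportions 0.10 and 0.20: the saturated-model slope
        is logit(0.2) - logit(0.1) ~ 0.8109."""
        rows = [
            ("Africa", 1, 1, {"ACA(T)": 10, "TCC(T)": 90}),
            ("Africa", 1, 2, {"ACA(T)": 20, "TCC(T)": 80}),
        ]
        est = fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)
        expected = scipy.special.logit(0.2) - scipy.special.logit(0.1)
        assert expected == pytest.approx(0.8109, abs=1e-4)
        assert est.slope == pytest.approx(expected, abs=1e-6)

    def test_matches_independent_irls_oracle(self):
        """statsmodels-backed fit vs hand-written Newton-Raphson IRLS on
        20+ random small tables, to 1e-6 in the slope."""
        rng = np.random.default_rng(1234)
        max_diff = 0.0
        for _ in range(25):
            bins, successes, trials = random_nondegenerate_table(rng)
            rows = [
                ("Africa", 1, int(b),
                 {"ACA(T)": int(s), "TCC(T)": int(t - s)})
                for b, s, t in zip(bins, successes, trials)
            ]
            est = fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)
            icpt, slope = irls_logit_fit(bins, successes, trials)
            assert est.slope == pytest.approx(slope, abs=1e-6)
            assert est.intercept == pytest.approx(icpt, abs=1e-6)
            max_diff = max(max_diff, abs(est.slope - slope))
        assert max_diff < 1e-6

    def test_simulated_slope_recovered_within_three_se(self):
        rng = np.random.default_rng(77)
        true_slope, true_icpt = 0.05, -3.0
        bins = np.arange(1, 31)
        trials = np.full(30, 100_000)
        p = 1 / (1 + np.exp(-(true_icpt + true_slope * bins)))
        successes = rng.binomial(trials, p)
        rows = [
            ("Africa", 1, int(b), {"ACA(T)": int(s), "TCC(T)": int(t - s)})
            for b, s, t in zip(bins, successes, trials)
        ]
        est = fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)
        assert abs(est.slope - true_slope) < 3 * est.std_err

    def test_unobserved_class_flagged_not_zero(self):
        rows = [
            ("Africa", 1, 1, {"TCC(T)": 100}),
            ("Africa", 1, 2, {"TCC(T)": 100}),
        ]
        est = fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)
        assert est.status == "no_successes"
        assert np.isnan(est.slope)

    def test_single_bin_raises(self):
        rows = [("Africa", 1, 1, {"ACA(T)": 10, "TCC(T)": 90})]
        with pytest.raises(ValueError, match="bins"):
            fit_class_regression(table_from_counts(rows), "ACA(T)", "Africa", 1)

    def test_gaussian_family_comparison_variant(self):
        rows = [
            ("Africa", 1, b, {"ACA(T)": 10 * b, "TCC(T)": 1000 - 10 * b})
            for b in range(1, 6)
        ]
        est = fit_class_regression(
            table_from_counts(rows), "ACA(T)", "Africa", 1, family="gaussian"
        )
        assert est.slope == pytest.approx(0.01, abs=1e-9)


class TestSlopeTable:
    def test_cardinality_and_determinism(self):
        rng = np.random.default_rng(5)
        variants = []
        labels = list(class_labels())
        for i in range(2000):
            variants.append(
                make_variant(
                    labels[rng.integers(0, 96)],
                    region=["Africa", "Europe"][rng.integers(0, 2)],
                    copy=int(rng.integers(1, 3)),
                    het_bin=int(rng.integers(1, 11)),
                    pos=i + 1,
                )
            )
        table = tabulate_counts(variants)
        slopes1 = slope_table(table)
        slopes2 = slope_table(table)
        assert len(slopes1) == 96 * 2 * 2
        from hetspec.regression import slopes_to_frame
        pd.testing.assert_frame_equal(slopes_to_frame(slopes1), slopes_to_frame(slopes2))
        keys = [(s.mutation_class, s.region, s.copy_number) for s in slopes1]
        assert keys == sorted(keys, key=lambda k: (k[0], k[1], k[2]))

    def test_model_results_facade(self):
        variants = [
            make_variant("ACA(T)", het_bin=b, pos=i)
            for i, b in enumerate([1, 1, 2, 2, 3, 3], start=1)
        ] + [
            make_variant("TCC(T)", het_bin=b, pos=100 + i)
            for i, b in enumerate([1, 2, 3] * 4, start=1)
        ]
        res = TripletSpectrumModel.from_variants(variants).fit()
        assert len(res.frame) == 96
        summary = res.summary()
        assert "binomial" in summary
        pooled = TripletSpectrumModel.from_variants(variants).fit(
            copy_numbers=[None]
        )
        assert {s.copy_number for s in pooled.slopes} == {None}


def constant_slopes(values_by_label, regions=("Africa", "Europe"), copy=1):
    out = []
    for region in regions:
        for label, slope in values_by_label.items():
            out.append(
                SlopeEstimate(label, region, copy, slope, 0.01, -3.0, 1000, "ok")
            )
    return out


class TestConcordance:
    def test_identical_slopes_give_zero_dispersion_unit_correlation(self):
        rng = np.random.default_rng(8)
        values = {c.label: float(v) for c, v in
                  zip(enumerate_classes(), rng.normal(0, 0.05, 96))}
        conc = cross_region_concordance(constant_slopes(values), 1)
        assert np.allclose(conc.per_class["slope_sd"], 0.0)
        assert conc.mean_pairwise_r == pytest.approx(1.0)

    def test_single_region_errors(self):
        values = {c.label: 0.01 for c in enumerate_classes()}
        with pytest.raises(ValueError):
            cross_region_concordance(constant_slopes(values, regions=("Africa",)), 1)

    def test_independent_region_decorrelates(self):
        rng = np.random.default_rng(21)
        shared = rng.normal(0, 0.05, 96)
        rogue = rng.normal(0, 0.05, 96)
        slopes = []
        for region, vec in [("Africa", shared), ("Europe", shared), ("America", rogue)]:
            for c, v in zip(enumerate_classes(), vec):
                slopes.append(SlopeEstimate(c.label, region, 1, float(v), 0.01, -3, 1000, "ok"))
        conc = cross_region_concordance(slopes, 1)
        assert conc.pairwise_r.loc["Africa", "Europe"] == pytest.approx(1.0)
        assert abs(conc.pairwise_r.loc["Africa", "America"]) < 0.3


class TestGCTrend:
    def test_perfect_gc_dependence_gives_unit_correlation(self):
        values = {
            c.label: 0.1 * gc_content(c) for c in enumerate_classes()
        }
        trends = gc_trend(constant_slopes(values), 1)
        assert len(trends) == 6
        for t in trends:
            assert t.n_classes == 16
            assert t.pearson_r == pytest.approx(1.0)
            assert t.p_value < 1e-6
            assert t.slope_per_gc == pytest.approx(0.1)

    def test_p_value_uses_t_distribution_14_df(self):
        rng = np.random.default_rng(6)
        values = {c.label: float(v) for c, v in
                  zip(enumerate_classes(), rng.normal(0, 0.02, 96))}
        trends = gc_trend(constant_slopes(values), 1)
        for t in trends:
            r, n = t.pearson_r, t.n_classes
            tt = r * np.sqrt((n - 2) / (1 - r * r))
            expected = 2 * scipy.stats.t.sf(abs(tt), n - 2)
            assert t.p_value == pytest.approx(expected, rel=1e-6)

    def test_null_p_values_approximately_uniform(self):
        """Slopes independent of GC content: p-values over repeats are
        uniform (KS test, seeded)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(250):
            values = {c.label: float(v) for c, v in
                      zip(enumerate_classes(), rng.normal(0, 0.02, 96))}
            pvals.extend(t.p_value for t in gc_trend(constant_slopes(values), 1))
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_missing_class_slopes_reported_pairwise_complete(self):
        values = {
            c.label: 0.1 * gc_content(c)
            for c in enumerate_classes()
            if c.label not in ("ACA(T)", "ACA(G)")
        }
        trends = {t.base_change: t for t in gc_trend(constant_slopes(values), 1)}
        assert trends["A>C"].n_classes == 16
        assert trends["C>T"].n_classes == 15
        assert trends["C>G"].n_classes == 15
        assert trends["C>T"].pearson_r == pytest.approx(1.0)
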