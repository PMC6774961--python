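"""Synthetic-data generator: determinism, landscape calibration, selection
fidelity and end-to-end parameter recovery."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import recovered_vs_true_slopes
from hetspec.pipeline import analyze_sites
from hetspec.selection import select_focal_variants
from hetspec.simulate import (
    SimulationConfig,
    default_class_slopes,
    generate_reference,
    simulate,
    smoke_config,
    write_fixture_bundle,
)
from hetspec.windows import HetLandscape


class TestReference:
    def test_deterministic_given_seed(self):
        cfg = smoke_config(4)
        a = generate_reference(cfg)
        b = generate_reference(cfg)
        assert np.array_equal(a, b)
        assert a.size == cfg.contig_length

    def test_base_composition_near_uniform(self):
        cfg = replace(smoke_config(2), contig_length=1_000_000)
        codes = generate_reference(cfg)
        counts = np.bincount(codes, minlength=4)
        # binomial 3-sigma bound around 0.25
        sigma = np.sqrt(0.25 * 0.75 / cfg.contig_length)
        assert np.all(np.abs(counts / cfg.contig_length - 0.25) < 3 * sigma + 1e-9)


class TestDeterminism:
    def test_bundle_byte_identical_for_same_seed(self, tmp_path):
        cfg = replace(smoke_config(21), n_focal_variants=120)
        p1 = write_fixture_bundle(cfg, tmp_path / "a")
        p2 = write_fixture_bundle(cfg, tmp_path / "b")
        for key in ("fasta", "fai", "vcf", "panel", "truth", "controls", "config"):
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_overwrite_guard(self, tmp_path):
        cfg = replace(smoke_config(21), n_focal_variants=50)
        write_fixture_bundle(cfg, tmp_path / "a")
        with pytest.raises(FileExistsError):
            write_fixture_bundle(cfg, tmp_path / "a")
        write_fixture_bundle(cfg, tmp_path / "a", overwrite=True)


class TestBundleContents:
    def test_truth_rows_match_requested_focal_count(self, smoke_bundle, smoke_dataset):
        truth = pd.read_csv(smoke_bundle["truth"])
        assert len(truth) == smoke_dataset.config.n_focal_variants
        assert set(truth["region"]) <= set(smoke_dataset.config.regions)

    def test_vcf_parses_sorted_and_consistent_with_fasta(self, smoke_bundle):
        import pysam

        positions = []
        with pysam.VariantFile(str(smoke_bundle["vcf"])) as vcf, pysam.FastaFile(
            str(smoke_bundle["fasta"])
        ) as fasta:
            for rec in vcf:
                positions.append(rec.pos)
                ref_here = fasta.fetch(rec.chrom, rec.pos - 1, rec.pos - 1 + len(rec.ref))
                assert rec.ref == ref_here.upper()
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)

    def test_truth_classes_recoverable_from_reference(
        self, smoke_bundle, smoke_dataset
    ):
        """The written reference triplet around each focal site, collapsed,
        equals the truth class (strand flips included)."""
        from hetspec.classes import classify_variant
        from hetspec.io import fetch_reference_triplet

        truth = smoke_dataset.truth
        by_pos = {s.pos: s for s in smoke_dataset.sites}
        for row in truth.to_dict("records"):
            site = by_pos[row["pos"]]
            triplet = fetch_reference_triplet(
                smoke_dataset.reference, row["chrom"], row["pos"]
            )
            # ref allele is the major (ancestral) allele by construction
            cls = classify_variant(triplet, site.ref_allele, site.alt_alleles[0])
            assert cls.label == row["class"]


class TestLandscapeCalibration:
    def test_zero_density_means_all_bin_one(self):
        cfg = replace(
            smoke_config(3),
            background_segment_densities=(0.0,),
            n_focal_variants=100,
            indel_rate=0.0,
            n_cross_region_controls=0,
            n_high_copy_controls=0,
        )
        ds = simulate(cfg)
        assert (ds.truth["het_score"] == 0).all()
        assert (ds.truth["het_bin"] == 1).all()

    def test_constant_density_mean_score_matches_analytic_expectation(self):
        """Constant density d: E[score] = 2·half_width·d·E[2p(1-p)], with
        E[2p(1-p)] = 0.365 for p ~ U(0.05, 0.5)."""
        d = 0.01
        cfg = SimulationConfig(
            seed=10,
            contig_length=2_000_000,
            n_samples_per_region=30,
            background_segment_densities=(d,),
            n_focal_variants=2_000,
        )
        ds = simulate(cfg)
        expected = 2000 * d * 0.365
        observed = ds.truth["het_score"].mean()
        # loose 3-sigma-ish band; sampling of p and positions both contribute
        assert abs(observed - expected) < 0.15 * expected

    def test_two_level_density_gives_bimodal_bins(self):
        cfg = SimulationConfig(
            seed=11,
            contig_length=2_000_000,
            n_samples_per_region=30,
            background_segment_densities=(0.002, 0.03),
            n_focal_variants=4_000,
        )
        ds = simulate(cfg)
        bins = ds.truth["het_bin"]
        low = (bins <= 4).mean()
        high = (bins >= 15).mean()
        middle = ((bins > 8) & (bins < 15)).mean()
        assert low > 0.3 and high > 0.3
        assert middle < 0.2


class TestSelectionFidelity:
    def test_all_focal_retained_no_planted_violations(self, smoke_dataset):
        focal, _ = select_focal_variants(
            smoke_dataset.sites, smoke_dataset.panel,
            max_copies=smoke_dataset.config.max_copies,
        )
        retained_pos = {v.pos for v in focal}
        truth_pos = set(smoke_dataset.truth["pos"])
        assert truth_pos <= retained_pos  # 100% of generated focal retained
        control_pos = set(smoke_dataset.controls["pos"])
        assert len(control_pos) > 0
        assert retained_pos & control_pos == set()  # 0% of planted violations
        # retained region/copy match truth exactly
        by_pos = {v.pos: v for v in focal}
        for row in smoke_dataset.truth.itertuples():
            v = by_pos[row.pos]
            assert v.region == row.region
            assert v.copy_number == row.copy_number


class TestParameterRecovery:
    def test_recovered_slopes_regress_on_truth(self, recovery_run):
        """At the full recovery scale, estimated per-class slopes regress on
        the generating slopes with slope 1 +- 0.1 and R^2 > 0.9; rank
        agreement (Spearman) > 0.9."""
        config, _, result = recovery_run
        both = recovered_vs_true_slopes(config, result)
        assert len(both) >= 90
        lr = scipy.stats.linregress(both["true"], both["est"])
        assert abs(lr.slope - 1.0) < 0.1
        assert lr.rvalue ** 2 > 0.9
        rho = scipy.stats.spearmanr(both["true"], both["est"]).statistic
        assert rho > 0.9

    def test_negative_slope_class_recovered_negative(self, recovery_run):
        """ACA(T) is generated with a clearly negative slope; the fitted
        slope is negative in every region."""
        config, _, result = recovery_run
        from hetspec.classes import enumerate_classes

        labels = [c.label for c in enumerate_classes()]
        true_aca_t = float(
            np.asarray(config.class_het_slopes)[labels.index("ACA(T)")]
        )
        assert true_aca_t < -0.02
        frame = result.results.frame
        rows = frame[
            (frame["class"] == "ACA(T)")
            & (frame["status"] == "ok")
            & (frame["copy_number"] == -1)
        ]
        assert len(rows) == 5
        assert (rows["slope"] < 0).all()

    def test_null_slopes_give_frequencies_matching_weights(self):
        """All generating slopes zero: class frequencies match the base
        weights within multinomial error."""
        cfg = SimulationConfig(
            seed=14,
            contig_length=2_000_000,
            n_samples_per_region=20,
            background_segment_densities=(0.005,),
            n_focal_variants=50_000,
            class_het_slopes=np.zeros(96),
        )
        ds = simulate(cfg)
        freqs = ds.truth["class"].value_counts(normalize=True)
        n = len(ds.truth)
        p0 = 1.0 / 96.0
        sigma = np.sqrt(p0 * (1 - p0) / n)
        assert len(freqs) == 96
        assert np.all(np.abs(freqs.to_numpy() - p0) < 5 * sigma)


def test_default_slopes_have_documented_sign_structure():
    """C>T transitions mostly negative, A>G mostly positive, positive GC
    gradient in every type — the structure the human data show."""
    from hetspec.classes import enumerate_classes, gc_content

    slopes = default_class_slopes()
    classes = list(enumerate_classes())
    c_to_t = [s for s, c in zip(slopes, classes) if c.base_change == "C>T"]
    a_to_g = [s for s, c in zip(slopes, classes) if c.base_change == "A>G"]
    assert np.mean(np.array(c_to_t) < 0) > 0.75
    assert np.mean(np.array(a_to_g) > 0) > 0.75
    for change in ("A>G", "C>T", "A>C", "C>A", "A>T", "C>G"):
        gc = [gc_content(c) for c in classes if c.base_change == change]
        vals = [s for s, c in zip(slopes, classes) if c.base_change == change]
        r = scipy.stats.pearsonr(gc, vals).statistic
        assert r > 0.5
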