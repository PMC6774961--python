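"""End-to-end orchestration: selection → classification → heterozygosity →
regression → reports.

``analyze_sites`` is the pure in-memory pipeline; ``run_pipeline`` wraps it
with file I/O (FASTA/VCF/panel in, CSV tables and a run manifest out).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classes import InvalidBaseError, classify_variant
from .io import (
    SamplePanel,
    SiteRecord,
    TripletUnavailable,
    AmbiguousBaseError,
    ContigEdgeError,
    fetch_reference_triplet,
    read_panel,
    stream_sites,
)
from .regression import (
    ClassCountTable,
    ConcordanceSummary,
    GCTrend,
    TripletSpectrumModel,
    TripletSpectrumResults,
    gc_trend_frame,
    slopes_to_frame,
)
from .selection import (
    FocalVariant,
    SelectionCounters,
    indel_proximity_fraction,
    select_focal_variants,
)
from .windows import HetBinning, annotate_heterozygosity, build_landscapes

logger = logging.getLogger("hetspec")


@dataclass
class PipelineConfig:
    """Run configuration; the defaults reproduce the primary analysis
    (2 kb window, 30 bins, copy numbers 1–5)."""

    fasta: str | Path | None = None
    vcf: str | Path | None = None
    panel: str | Path | None = None
    outdir: str | Path = "hetspec_out"
    window_half_width: int = 1000
    n_bins: int = 30
    max_copies: int = 5
    contigs: tuple[str, ...] | None = None  # allowlist; None = all
    regions: tuple[str, ...] | None = None  # fixed region order; None = infer
    family: str = "binomial"
    label: str | None = None
    seed: int | None = None
    log_level: str = "INFO"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("contigs", "regions"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("fasta", "vcf", "panel", "outdir"):
            if d[key] is not None:
                d[key] = str(d[key])
        for key in ("contigs", "regions"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    focal: list[FocalVariant]
    counts: ClassCountTable
    results: TripletSpectrumResults
    concordance: ConcordanceSummary | None
    gc_trends: dict[int, list[GCTrend]]  # keyed by copy number
    indel_fraction: float | None
    counters: SelectionCounters

    @property
    def focal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "class": v.mutation_class.label,
                    "region": v.region,
                    "copy_number": v.copy_number,
                    "het_score": v.het_score,
                    "het_bin": v.het_bin,
                }
                for v in self.focal
            ]
        )


def classify_focal_variants(
    focal: Sequence[FocalVariant],
    reference,
    counters: SelectionCounters,
) -> list[FocalVariant]:
    """Attach mutation classes; variants with unusable triplet context
    (contig edge, ambiguous base) are dropped and counted."""
    kept: list[FocalVariant] = []
    for v in focal:
        try:
            triplet = fetch_reference_triplet(reference, v.chrom, v.pos)
            v.mutation_class = classify_variant(
                triplet, v.major_allele, v.minor_allele
            )
        except ContigEdgeError:
            counters.n_triplet_edge += 1
            continue
        except (AmbiguousBaseError, InvalidBaseError):
            counters.n_triplet_ambiguous += 1
            continue
        kept.append(v)
    return kept


def analyze_sites(
    sites: Iterable[SiteRecord],
    panel: SamplePanel,
    reference,
    *,
    window_half_width: int = 1000,
    n_bins: int = 30,
    max_copies: int = 5,
    contigs: Sequence[str] | None = None,
    family: str = "binomial",
    copy_numbers: Sequence[int | None] | None = None,
    fit: bool = True,
) -> PipelineResult:
    """The full in-memory analysis on an iterable of site records.

    ``reference`` is a ``pysam.FastaFile`` or a mapping chrom → sequence.
    ``copy_numbers`` selects which per-copy fits to run (``None`` entries
    pool copies); default is every copy number present.
    """
    site_list = list(sites)
    if contigs is not None:
        allow = set(contigs)
        site_list = [s for s in site_list if s.chrom in allow]
    logger.info("loaded %d site records", len(site_list))

    focal, counters = select_focal_variants(site_list, panel, max_copies=max_copies)
    logger.info("selected %d focal variants (%s)", len(focal), counters.as_dict())

    focal = classify_focal_variants(focal, reference, counters)

    landscapes = build_landscapes(site_list, panel)
    binning = HetBinning(n_bins)
    annotate_heterozygosity(
        focal, landscapes, half_width=window_half_width, binning=binning
    )

    from .regression import tabulate_counts

    counts = tabulate_counts(focal, n_bins)
    model = TripletSpectrumModel(counts, family=family)
    results = model.fit(copy_numbers=copy_numbers) if fit else model.fit(
        copy_numbers=[]
    )

    concordance: ConcordanceSummary | None = None
    gc_trends: dict[int, list[GCTrend]] = {}
    if fit:
        fitted_copies = sorted(
            {s.copy_number for s in results.slopes if s.copy_number is not None}
        )
        primary = 1 if 1 in fitted_copies else (
            fitted_copies[0] if fitted_copies else None
        )
        if primary is not None and len(counts.regions) >= 2:
            try:
                concordance = results.cross_region_concordance(primary)
            except ValueError:
                concordance = None
        from .regression import gc_trend as _gc_trend

        for copy in (1, 2):
            if copy in fitted_copies:
                gc_trends[copy] = _gc_trend(results.slopes, copy)

    n_indels = sum(1 for s in site_list if s.is_indel)
    indel_fraction = (
        indel_proximity_fraction(site_list) if n_indels else None
    )

    return PipelineResult(
        focal=focal,
        counts=counts,
        results=results,
        concordance=concordance,
        gc_trends=gc_trends,
        indel_fraction=indel_fraction,
        counters=counters,
    )


def write_report(
    result: PipelineResult, outdir: str | Path, config: PipelineConfig | None = None
) -> dict[str, Path]:
    """Write the CSV report bundle and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["focal_variants"] = outdir / "focal_variants.csv"
    result.focal_frame.to_csv(paths["focal_variants"], index=False)

    paths["binned_proportions"] = outdir / "binned_proportions.csv"
    if len(result.counts.counts):
        result.counts.proportions_x1000().to_csv(
            paths["binned_proportions"], index=False
        )
    else:
        pd.DataFrame(
            columns=[
                "region", "copy_number", "het_bin", "class", "count",
                "margin", "proportion_x1000",
            ]
        ).to_csv(paths["binned_proportions"], index=False)

    paths["slopes"] = outdir / "slopes.csv"
    slopes_to_frame(result.results.slopes).to_csv(paths["slopes"], index=False)

    paths["concordance"] = outdir / "concordance.csv"
    if result.concordance is not None:
        result.concordance.per_class.to_csv(paths["concordance"], index=False)
        paths["concordance_pairwise"] = outdir / "concordance_pairwise.csv"
        result.concordance.pairwise_r.to_csv(paths["concordance_pairwise"])
    else:
        pd.DataFrame(columns=["class", "n_regions", "slope_mean", "slope_sd"]).to_csv(
            paths["concordance"], index=False
        )

    paths["gc_trend"] = outdir / "gc_trend.csv"
    gc_rows = []
    for copy, trends in sorted(result.gc_trends.items()):
        frame = gc_trend_frame(trends)
        frame.insert(0, "copy_number", copy)
        gc_rows.append(frame)
    (
        pd.concat(gc_rows, ignore_index=True)
        if gc_rows
        else pd.DataFrame(
            columns=[
                "copy_number", "base_change", "n_classes", "pearson_r",
                "p_value", "intercept", "slope_per_gc",
            ]
        )
    ).to_csv(paths["gc_trend"], index=False)

    paths["indel_proximity"] = outdir / "indel_proximity.txt"
    with open(paths["indel_proximity"], "w", encoding="utf-8") as fh:
        if result.indel_fraction is None:
            fh.write("no indel records in input; fraction undefined\n")
        else:
            fh.write(
                f"fraction_snps_within_5bp_of_indel\t{result.indel_fraction:.6f}\n"
                f"percent\t{100.0 * result.indel_fraction:.4f}\n"
            )

    manifest = {
        "package": "hetspec",
        "version": __version__,
        "config": config.to_dict() if config is not None else None,
        "counters": result.counters.as_dict(),
        "n_focal": len(result.focal),
        "outputs": {k: str(p) for k, p in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def run_pipeline(config: PipelineConfig) -> tuple[PipelineResult, dict[str, Path]]:
    """File-based run: read FASTA/VCF/panel, analyse, write the report."""
    import pysam

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    for key in ("fasta", "vcf", "panel"):
        if getattr(config, key) is None:
            raise ValueError(f"pipeline config missing required path: {key}")
    panel = read_panel(config.panel, regions=config.regions)
    outdir = Path(config.outdir)
    if config.label:
        outdir = outdir / config.label
    with pysam.FastaFile(str(config.fasta)) as fasta:
        result = analyze_sites(
            stream_sites(config.vcf, panel),
            panel,
            fasta,
            window_half_width=config.window_half_width,
            n_bins=config.n_bins,
            max_copies=config.max_copies,
            contigs=config.contigs,
            family=config.family,
        )
    paths = write_report(result, outdir, config)
    if config.make_plots:
        from . import plots

        plots.render_all(result, outdir)
    return result, paths
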