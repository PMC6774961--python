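"""Synthetic reference + variant-call generator with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every stage of the pipeline is testable without any external download:

* a uniform-random reference contig;
* background common SNPs whose piecewise-constant density creates a
  spatially varying heterozygosity landscape (HWE genotypes per sample,
  alt-allele frequency drawn from a configurable range);
* rare focal variants (1–``max_copies`` allele copies, carriers confined to
  one region) whose 96-class mutation probabilities are logit-linear in the
  local heterozygosity *bin* — exactly the estimand of the regression stage,
  so parameter recovery is an identity test of the estimator rather than a
  model-mismatch test;
* optional planted violations (cross-region doubletons, high-copy variants)
  as negative controls for the selection rule, and sparse indels to
  exercise the indel-proximity diagnostic.

To make any class drawable at any position, the reference is rewritten so
that the ancestral triplet at the focal site equals the drawn class's
triplet, on a randomly chosen strand (exercising strand collapse).
Determinism: identical config + seed ⇒ byte-identical fixture bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classes import BASES, MutationClass, class_labels, enumerate_classes, gc_content
from .io import (
    DEFAULT_REGIONS,
    DosageGenotypes,
    SamplePanel,
    SiteRecord,
    SparseGenotypes,
    write_panel,
)
from .windows import HetBinning, HetLandscape, assign_bin

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_class_slopes() -> np.ndarray:
    """Per-class logit slopes (per het-bin unit) used by default.

    Built to mirror the qualitative structure of the human data: C→T
    transitions mostly negative, A→G transitions mostly positive, a positive
    GC-content gradient within every base-change type, plus a small fixed
    per-class jitter so the 96 values are distinct. Deterministic.
    """
    type_base = {
        "A>C": 0.010, "A>G": 0.030, "A>T": -0.010,
        "C>A": -0.015, "C>G": 0.005, "C>T": -0.030,
    }
    jitter = np.random.default_rng(20190925).normal(0.0, 0.008, 96)
    slopes = np.empty(96, dtype=float)
    for i, c in enumerate(enumerate_classes()):
        slopes[i] = type_base[c.base_change] + 0.015 * (gc_content(c) - 1.5) + jitter[i]
    return slopes


DEFAULT_COPY_PROBS = (0.45, 0.25, 0.15, 0.10, 0.05)


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults define the study conditions."""

    seed: int = 0
    contig_name: str = "chr_sim"
    contig_length: int = 1_000_000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_samples_per_region: int = 20
    #: per-bp SNP rates over equal-length contig segments (low → high makes
    #: the window-score distribution span the bins)
    background_segment_densities: tuple[float, ...] = (
        0.002, 0.008, 0.015, 0.025, 0.035,
    )
    background_freq_range: tuple[float, float] = (0.05, 0.5)
    n_focal_variants: int = 5_000
    class_base_weights: np.ndarray | None = None  # default: uniform 1/96
    class_het_slopes: np.ndarray | None = None  # default: default_class_slopes()
    copy_number_probs: tuple[float, ...] = DEFAULT_COPY_PROBS
    indel_rate: float = 0.0
    window_half_width: int = 1000
    n_bins: int = 30
    n_cross_region_controls: int = 0
    n_high_copy_controls: int = 0
    #: if set, this region's variants are generated with an independent
    #: random slope vector (negative control for cross-region concordance)
    discordant_region: str | None = None
    margin: int = 1000

    def __post_init__(self) -> None:
        if self.class_base_weights is None:
            self.class_base_weights = np.full(96, 1.0 / 96.0)
        self.class_base_weights = np.asarray(self.class_base_weights, dtype=float)
        if self.class_base_weights.shape != (96,):
            raise ValueError("class_base_weights must have 96 entries")
        if np.any(self.class_base_weights < 0) or not math.isclose(
            float(self.class_base_weights.sum()), 1.0, abs_tol=1e-12
        ):
            raise ValueError("class_base_weights must be ≥ 0 and sum to 1")
        if self.class_het_slopes is None:
            self.class_het_slopes = default_class_slopes()
        self.class_het_slopes = np.asarray(self.class_het_slopes, dtype=float)
        if self.class_het_slopes.shape != (96,):
            raise ValueError("class_het_slopes must have 96 entries")
        if any(d < 0 for d in self.background_segment_densities):
            raise ValueError("densities must be ≥ 0")
        probs = np.asarray(self.copy_number_probs, dtype=float)
        if np.any(probs < 0) or not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("copy_number_probs must be a probability vector")
        n_wanted = (
            self.n_focal_variants
            + self.n_cross_region_controls
            + self.n_high_copy_controls
        )
        usable = self.contig_length - 2 * self.margin
        if usable < 4 * n_wanted:
            raise ValueError(
                f"contig too short: {self.contig_length} bp cannot host "
                f"{n_wanted} focal variants with {self.margin} bp margins"
            )
        if self.discordant_region is not None and (
            self.discordant_region not in self.regions
        ):
            raise ValueError(f"unknown discordant region {self.discordant_region!r}")

    @property
    def max_copies(self) -> int:
        return len(self.copy_number_probs)

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items()
            if k not in ("class_base_weights", "class_het_slopes")
        }
        d["regions"] = list(self.regions)
        d["background_segment_densities"] = list(self.background_segment_densities)
        d["background_freq_range"] = list(self.background_freq_range)
        d["copy_number_probs"] = list(self.copy_number_probs)
        d["class_base_weights"] = [float(x) for x in self.class_base_weights]
        d["class_het_slopes"] = [float(x) for x in self.class_het_slopes]
        return d


def smoke_config(seed: int = 0) -> SimulationConfig:
    """Tiny preset: full pipeline end-to-end in about a second."""
    return SimulationConfig(
        seed=seed,
        contig_length=150_000,
        n_samples_per_region=6,
        background_segment_densities=(0.002, 0.008, 0.015, 0.025),
        n_focal_variants=400,
        indel_rate=2e-4,
        n_cross_region_controls=8,
        n_high_copy_controls=5,
    )


def recovery_config(seed: int = 0) -> SimulationConfig:
    """Parameter-recovery preset: 10^6 focal variants on a 20 Mb contig.

    Densities are chosen so realised window scores spread across the whole
    1–30 bin range (mean per-site expected heterozygosity for frequencies
    uniform on (0.05, 0.5) is ≈ 0.365, so a density d gives window scores
    around 2000·d·0.365).
    """
    targets = (1.0, 5.0, 9.0, 13.0, 17.0, 21.0, 25.0, 29.0)
    densities = tuple(t / (2000.0 * 0.365) for t in targets)
    return SimulationConfig(
        seed=seed,
        contig_length=20_000_000,
        n_samples_per_region=60,
        background_segment_densities=densities,
        n_focal_variants=1_000_000,
        indel_rate=0.0,
    )


def discordant_config(seed: int = 0, region: str = "America") -> SimulationConfig:
    """Smaller recovery-style preset with one region given independent
    random slopes — the negative control for cross-region concordance."""
    cfg = recovery_config(seed)
    return replace(
        cfg,
        contig_length=5_000_000,
        n_focal_variants=250_000,
        discordant_region=region,
    )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """In-memory fixture bundle plus ground truth."""

    config: SimulationConfig
    panel: SamplePanel
    reference: dict[str, str]
    sites: list[SiteRecord]
    truth: pd.DataFrame  # one row per regular focal variant
    controls: pd.DataFrame  # planted selection-rule violations
    #: the slope vector actually used per region (differs for a discordant region)
    region_slopes: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """I.i.d. uniform A/C/G/T sequence as a uint8 code array (A=0..T=3)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng.integers(0, 4, config.contig_length, dtype=np.uint8)


def codes_to_sequence(codes: np.ndarray) -> str:
    return _BASE_CODES[codes].tobytes().decode("ascii")


def _make_panel(config: SimulationConfig) -> SamplePanel:
    samples, pops, regs = [], [], []
    for r_i, region in enumerate(config.regions):
        tag = "".join(w[0] for w in region.split()).upper()
        for s_i in range(config.n_samples_per_region):
            samples.append(f"S{r_i}{tag}{s_i:04d}")
            pops.append(f"{tag}P{r_i}")
            regs.append(region)
    return SamplePanel(
        samples=tuple(samples),
        populations=tuple(pops),
        sample_regions=tuple(regs),
        regions=tuple(config.regions),
    )


def generate_background_snps(
    config: SimulationConfig,
    ref_codes: np.ndarray,
    rng: np.random.Generator,
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Poisson-placed common SNPs with HWE genotypes.

    Returns (positions 1-based sorted, alt frequencies, alt base codes,
    dosage matrix of shape (n_snps, n_samples)).
    """
    L = config.contig_length
    densities = config.background_segment_densities
    n_seg = len(densities)
    bounds = np.linspace(0, L, n_seg + 1).astype(np.int64)
    pos_parts = []
    for d, lo, hi in zip(densities, bounds[:-1], bounds[1:]):
        n = rng.poisson(d * (hi - lo))
        if n > 0:
            pos_parts.append(rng.integers(lo + 1, hi + 1, n, dtype=np.int64))
    if pos_parts:
        positions = np.unique(np.concatenate(pos_parts))
    else:
        positions = np.empty(0, dtype=np.int64)
    lo_f, hi_f = config.background_freq_range
    freqs = rng.uniform(lo_f, hi_f, positions.size)
    alt_codes = (ref_codes[positions - 1] + rng.integers(1, 4, positions.size)) % 4
    dosages = rng.binomial(2, freqs[:, None], (positions.size, n_samples)).astype(
        np.int8
    )
    return positions, freqs, alt_codes.astype(np.uint8), dosages


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    forbidden_sorted: np.ndarray,
    min_gap: int = 3,
) -> np.ndarray:
    """``n`` sorted 1-based positions in [lo, hi], pairwise ≥ ``min_gap``
    apart and ≥ ``min_gap`` from every forbidden position."""
    kept = np.empty(0, dtype=np.int64)
    for _ in range(60):
        need = n - kept.size
        if need <= 0:
            break
        cand = np.unique(rng.integers(lo, hi + 1, int(need * 1.5) + 16, dtype=np.int64))
        pool = np.unique(np.concatenate([kept, cand]))
        # drop the later of any pair closer than min_gap (non-greedy but fine)
        keep_mask = np.ones(pool.size, dtype=bool)
        if pool.size > 1:
            keep_mask[1:] = np.diff(pool) >= min_gap
        pool = pool[keep_mask]
        if forbidden_sorted.size:
            left = np.searchsorted(forbidden_sorted, pool - (min_gap - 1), "left")
            right = np.searchsorted(forbidden_sorted, pool + (min_gap - 1), "right")
            pool = pool[left == right]
        kept = pool
    if kept.size < n:
        raise RuntimeError("could not place focal variants; contig too crowded")
    return np.sort(rng.choice(kept, n, replace=False))


def _sample_carrier_chromosomes(
    rng: np.random.Generator, copies: np.ndarray, n_chrom: int
) -> np.ndarray:
    """(n, max_copies) matrix of distinct within-row chromosome indices;
    entries beyond each row's copy count are -1. Vectorised rejection of
    rows with duplicates among their first ``copies`` draws."""
    n = copies.size
    cmax = int(copies.max()) if n else 0
    draws = rng.integers(0, n_chrom, (n, max(cmax, 1)), dtype=np.int64)
    col = np.arange(max(cmax, 1))
    mask = col[None, :] < copies[:, None]
    for _ in range(200):
        active = np.where(mask, draws, -1 - np.arange(max(cmax, 1))[None, :])
        srt = np.sort(active, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        if not bad.any():
            break
        draws[bad] = rng.integers(0, n_chrom, (int(bad.sum()), max(cmax, 1)))
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("carrier sampling failed to de-duplicate")
    return np.where(mask, draws, -1)


def _class_triplet_codes() -> tuple[np.ndarray, np.ndarray]:
    trip = np.empty((96, 3), dtype=np.uint8)
    der = np.empty(96, dtype=np.uint8)
    for i, c in enumerate(enumerate_classes()):
        trip[i] = [_CODE_OF[b] for b in c.triplet]
        der[i] = _CODE_OF[c.derived_base]
    return trip, der


def _bin_class_cdfs(
    weights: np.ndarray, slopes: np.ndarray, n_bins: int
) -> np.ndarray:
    """(n_bins, 96) CDF of P(class | bin) ∝ weight_t · exp(slope_t · bin)."""
    bins = np.arange(1, n_bins + 1, dtype=float)[:, None]
    logp = np.log(np.maximum(weights[None, :], 1e-300)) + slopes[None, :] * bins
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return np.cumsum(p, axis=1)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator; deterministic given ``config`` (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    panel = _make_panel(config)
    n_samples = panel.n_samples
    n_regions = len(config.regions)
    n_per_region = config.n_samples_per_region
    chrom = config.contig_name

    ref_codes = generate_reference(config, rng)
    bg_pos, bg_freq, bg_alt, bg_dos = generate_background_snps(
        config, ref_codes, rng, n_samples
    )

    # ---- focal (and control) positions --------------------------------
    n_cc = config.n_cross_region_controls
    n_hc = config.n_high_copy_controls
    n_foc = config.n_focal_variants
    n_all = n_foc + n_cc + n_hc
    positions = _draw_positions(
        rng, n_all, config.margin + 2, config.contig_length - config.margin - 1,
        bg_pos,
    )
    which = rng.permutation(n_all)
    foc_pos = np.sort(positions[which[:n_foc]])
    cc_pos = np.sort(positions[which[n_foc : n_foc + n_cc]])
    hc_pos = np.sort(positions[which[n_foc + n_cc :]])

    # ---- region / copy number assignment ------------------------------
    region_idx = rng.integers(0, n_regions, n_foc)
    copies = rng.choice(
        np.arange(1, config.max_copies + 1), size=n_foc,
        p=np.asarray(config.copy_number_probs, dtype=float),
    )

    # ---- true window heterozygosity from the background landscape -----
    region_ids = panel.region_ids
    binning = HetBinning(config.n_bins)
    # region alt counts for background SNPs, vectorised over the matrix
    onehot = np.zeros((n_samples, n_regions))
    onehot[np.arange(n_samples), region_ids] = 1.0
    bg_alt_per_region = bg_dos.astype(np.float64) @ onehot  # (S, R)
    true_scores = np.empty(n_foc, dtype=float)
    bg_landscapes: dict[str, HetLandscape] = {}
    for r_i, region in enumerate(config.regions):
        p = bg_alt_per_region[:, r_i] / (2.0 * n_per_region)
        poly = (p > 0.0) & (p < 1.0)
        het = 2.0 * p[poly] * (1.0 - p[poly])
        land = HetLandscape.from_arrays(region, {chrom: (bg_pos[poly], het)})
        bg_landscapes[region] = land
        sel = region_idx == r_i
        true_scores[sel] = land.window_scores(
            chrom, foc_pos[sel], config.window_half_width
        )
    true_bins = np.minimum(
        np.floor(true_scores).astype(np.int64) + 1, config.n_bins
    )

    # ---- class draw: logit-linear in bin ------------------------------
    shared_cdf = _bin_class_cdfs(
        config.class_base_weights, config.class_het_slopes, config.n_bins
    )
    region_slopes = {r: config.class_het_slopes for r in config.regions}
    cdf_of_region = {r: shared_cdf for r in config.regions}
    if config.discordant_region is not None:
        scale = float(np.std(config.class_het_slopes))
        disc = np.random.default_rng(config.seed + 104729).normal(0.0, scale, 96)
        region_slopes[config.discordant_region] = disc
        cdf_of_region[config.discordant_region] = _bin_class_cdfs(
            config.class_base_weights, disc, config.n_bins
        )
    u = rng.random(n_foc)
    class_idx = np.empty(n_foc, dtype=np.int64)
    for r_i, region in enumerate(config.regions):
        cdf = cdf_of_region[region]
        for b in range(1, config.n_bins + 1):
            sel = (region_idx == r_i) & (true_bins == b)
            if sel.any():
                class_idx[sel] = np.searchsorted(cdf[b - 1], u[sel], side="right")
    class_idx = np.minimum(class_idx, 95)

    # ---- write ancestral triplets into the reference ------------------
    trip_codes, der_codes = _class_triplet_codes()
    trip = trip_codes[class_idx].copy()
    der = der_codes[class_idx].copy()
    flip = rng.random(n_foc) < 0.5
    trip[flip] = 3 - trip[flip][:, ::-1]
    der[flip] = 3 - der[flip]
    ref_codes[foc_pos - 2] = trip[:, 0]
    ref_codes[foc_pos - 1] = trip[:, 1]
    ref_codes[foc_pos] = trip[:, 2]

    # ---- carriers ------------------------------------------------------
    carrier_chrom = _sample_carrier_chromosomes(rng, copies, 2 * n_per_region)

    labels = list(class_labels())
    base_lookup = np.array(list("ACGT"))

    focal_records: list[tuple[int, SiteRecord]] = []
    truth_rows = []
    region_offsets = {
        region: panel.region_sample_indices(region)[0] for region in config.regions
    }
    for i in range(n_foc):
        region = config.regions[region_idx[i]]
        offset = region_offsets[region]
        chroms_i = carrier_chrom[i, : copies[i]]
        sample_local = chroms_i // 2
        local, dos = np.unique(sample_local, return_counts=True)
        carriers = (local + offset).astype(np.int64)
        gt = SparseGenotypes(n_samples, carriers, dos.astype(np.int8))
        ref_base = base_lookup[trip[i, 1]]
        alt_base = base_lookup[der[i]]
        rec = SiteRecord(
            chrom=chrom, pos=int(foc_pos[i]), ref_allele=str(ref_base),
            alt_alleles=(str(alt_base),), genotypes=gt,
            is_snp=True, is_indel=False,
        )
        focal_records.append((int(foc_pos[i]), rec))
        truth_rows.append(
            (
                chrom, int(foc_pos[i]), labels[class_idx[i]], region,
                int(copies[i]), float(true_scores[i]), int(true_bins[i]),
                bool(flip[i]),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "class", "region", "copy_number",
            "het_score", "het_bin", "strand_flipped",
        ],
    )

    # ---- planted violations -------------------------------------------
    control_rows = []
    control_records: list[tuple[int, SiteRecord]] = []
    for j, pos in enumerate(cc_pos):
        # doubleton split across two distinct regions
        r_a, r_b = rng.choice(n_regions, 2, replace=False)
        s_a = region_offsets[config.regions[r_a]] + rng.integers(0, n_per_region)
        s_b = region_offsets[config.regions[r_b]] + rng.integers(0, n_per_region)
        gt = SparseGenotypes(
            n_samples, np.array([s_a, s_b]), np.array([1, 1], dtype=np.int8)
        )
        ref_base = str(base_lookup[ref_codes[pos - 1]])
        alt_base = str(base_lookup[(ref_codes[pos - 1] + 1) % 4])
        control_records.append(
            (
                int(pos),
                SiteRecord(chrom, int(pos), ref_base, (alt_base,), gt, True, False),
            )
        )
        control_rows.append((chrom, int(pos), "cross_region_doubleton", 2))
    for pos in hc_pos:
        r_i = int(rng.integers(0, n_regions))
        count = int(rng.integers(config.max_copies + 1, 2 * config.max_copies + 1))
        chroms_i = rng.choice(2 * n_per_region, count, replace=False)
        local, dos = np.unique(chroms_i // 2, return_counts=True)
        carriers = local + region_offsets[config.regions[r_i]]
        gt = SparseGenotypes(n_samples, carriers, dos.astype(np.int8))
        ref_base = str(base_lookup[ref_codes[pos - 1]])
        alt_base = str(base_lookup[(ref_codes[pos - 1] + 1) % 4])
        control_records.append(
            (
                int(pos),
                SiteRecord(chrom, int(pos), ref_base, (alt_base,), gt, True, False),
            )
        )
        control_rows.append((chrom, int(pos), "high_copy", count))
    controls = pd.DataFrame(
        control_rows, columns=["chrom", "pos", "kind", "copy_number"]
    )

    # ---- indels --------------------------------------------------------
    indel_records: list[tuple[int, SiteRecord]] = []
    if config.indel_rate > 0:
        n_ind = rng.poisson(config.indel_rate * config.contig_length)
        if n_ind > 0:
            occupied = np.sort(np.concatenate([bg_pos, positions]))
            ind_pos = _draw_positions(
                rng, n_ind, config.margin + 2,
                config.contig_length - config.margin - 2, occupied,
            )
            for pos in ind_pos:
                carrier = rng.integers(0, n_samples)
                gt = SparseGenotypes(
                    n_samples, np.array([carrier]), np.array([1], dtype=np.int8)
                )
                base = str(base_lookup[ref_codes[pos - 1]])
                if rng.random() < 0.5:  # insertion
                    ins = str(base_lookup[rng.integers(0, 4)])
                    ref_a, alt_a = base, base + ins
                else:  # 1 bp deletion
                    nxt = str(base_lookup[ref_codes[pos]])
                    ref_a, alt_a = base + nxt, base
                indel_records.append(
                    (
                        int(pos),
                        SiteRecord(chrom, int(pos), ref_a, (alt_a,), gt, False, True),
                    )
                )

    # ---- background records -------------------------------------------
    bg_records = [
        (
            int(bg_pos[k]),
            SiteRecord(
                chrom, int(bg_pos[k]), str(base_lookup[ref_codes[bg_pos[k] - 1]]),
                (str(base_lookup[bg_alt[k]]),), DosageGenotypes(bg_dos[k]),
                True, False,
            ),
        )
        for k in range(bg_pos.size)
    ]

    all_records = bg_records + focal_records + control_records + indel_records
    all_records.sort(key=lambda t: t[0])
    sites = [rec for _, rec in all_records]

    reference = {chrom: codes_to_sequence(ref_codes)}
    return SyntheticDataset(
        config=config, panel=panel, reference=reference, sites=sites,
        truth=truth, controls=controls, region_slopes=region_slopes,
    )


# ---------------------------------------------------------------------------
# File bundle
# ---------------------------------------------------------------------------


def _write_fasta(reference: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GT_STRINGS = ("0/0", "0/1", "1/1")


def write_vcf(
    sites: Sequence[SiteRecord],
    panel: SamplePanel,
    path: Path,
    contigs: dict[str, int],
) -> None:
    """Minimal deterministic VCF 4.2 with GT-only FORMAT."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetspec-simulate\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for site in sites:
            dosages = site.genotypes.dosages()
            gts = "\t".join(_GT_STRINGS[d] for d in dosages)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles)}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_fixture_bundle(
    config: SimulationConfig, outdir: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write a self-consistent FASTA(+.fai)/VCF/panel/truth bundle."""
    import pysam

    outdir = Path(outdir)
    paths = {
        "fasta": outdir / "reference.fa",
        "vcf": outdir / "sites.vcf",
        "panel": outdir / "panel.tsv",
        "truth": outdir / "truth.csv",
        "controls": outdir / "controls.csv",
        "config": outdir / "config.yaml",
    }
    if outdir.exists() and not overwrite:
        existing = [p for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"{existing[0]} exists; pass overwrite=True to replace"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)
    _write_fasta(ds.reference, paths["fasta"])
    fai = Path(str(paths["fasta"]) + ".fai")
    if fai.exists():
        fai.unlink()
    pysam.faidx(str(paths["fasta"]))
    write_vcf(
        ds.sites, ds.panel, paths["vcf"],
        {c: len(s) for c, s in ds.reference.items()},
    )
    write_panel(ds.panel, paths["panel"])
    ds.truth.to_csv(paths["truth"], index=False)
    ds.controls.to_csv(paths["controls"], index=False)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    paths["fai"] = fai
    return paths
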