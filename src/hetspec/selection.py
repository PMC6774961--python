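"""Selection of young, region-confined rare variants.

Rare variants (1–5 minor-allele copies) whose carriers all fall in a single
major geographical region proxy recent mutations that arose in that region:
copy number is an inverse proxy for allele age, and region confinement
filters out older, more widely dispersed alleles. No quality or
accessibility filtering is applied — the analysis deliberately runs on
unfiltered calls, with skip counters logged instead — and the indel-proximity
fraction quantifies the residual misalignment risk that choice leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .classes import MutationClass
from .io import SamplePanel, SiteRecord


@dataclass(slots=True)
class FocalVariant:
    """A selected rare variant (class/heterozygosity fields filled later)."""

    chrom: str
    pos: int
    region: str
    copy_number: int
    major_allele: str
    minor_allele: str
    carrier_samples: tuple[int, ...]
    mutation_class: MutationClass | None = None
    het_score: float | None = None
    het_bin: int | None = None


@dataclass
class SelectionCounters:
    """Bookkeeping so (input records) = (retained) + Σ(skips) is checkable."""

    n_records: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0
    n_monomorphic: int = 0
    n_allele_tie: int = 0
    n_copy_out_of_range: int = 0
    n_cross_region: int = 0
    n_retained: int = 0
    # filled during classification, not selection
    n_triplet_edge: int = 0
    n_triplet_ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def _minor_major(site: SiteRecord) -> tuple[int, int, int] | None:
    """(minor allele index, minor count, called chromosomes), or None on tie."""
    counts = site.genotypes.allele_counts(n_alleles=2)
    ref_n, alt_n = int(counts[0]), int(counts[1])
    if ref_n == alt_n:
        return None
    minor = 1 if alt_n < ref_n else 0
    return minor, min(ref_n, alt_n), ref_n + alt_n


def select_focal_variants(
    sites: Iterable[SiteRecord],
    panel: SamplePanel,
    max_copies: int = 5,
    counters: SelectionCounters | None = None,
) -> tuple[list[FocalVariant], SelectionCounters]:
    """Retain biallelic SNPs with 1–``max_copies`` minor-allele copies whose
    carrier samples all belong to one region.

    Copies are counted as minor-allele chromosomes (a homozygous-rare sample
    contributes 2, and trivially satisfies region confinement). Sites where
    the minor allele is the *reference* allele are retained — the ancestral
    state is always the panel-wide major allele. Exact 50/50 allele-count
    ties leave the mutation direction undefined and are skipped with a
    counter.
    """
    if counters is None:
        counters = SelectionCounters()
    sample_regions = panel.sample_regions
    retained: list[FocalVariant] = []
    for site in sites:
        counters.n_records += 1
        if site.is_indel:
            counters.n_indel += 1
            continue
        if not site.is_snp:
            counters.n_non_snp += 1
            continue
        if not site.is_biallelic:
            counters.n_multiallelic += 1
            continue
        mm = _minor_major(site)
        if mm is None:
            counters.n_allele_tie += 1
            continue
        minor_idx, minor_count, called = mm
        if minor_count == 0:
            counters.n_monomorphic += 1
            continue
        if minor_count > max_copies:
            counters.n_copy_out_of_range += 1
            continue
        carriers = site.genotypes.carrier_samples(allele=minor_idx)
        regions = {sample_regions[int(i)] for i in carriers}
        if len(regions) != 1:
            counters.n_cross_region += 1
            continue
        minor_allele = site.alt_alleles[0] if minor_idx == 1 else site.ref_allele
        major_allele = site.ref_allele if minor_idx == 1 else site.alt_alleles[0]
        counters.n_retained += 1
        retained.append(
            FocalVariant(
                chrom=site.chrom,
                pos=site.pos,
                region=next(iter(regions)),
                copy_number=minor_count,
                major_allele=major_allele,
                minor_allele=minor_allele,
                carrier_samples=tuple(int(i) for i in carriers),
            )
        )
    return retained, counters


def indel_proximity_fraction(
    sites: Iterable[SiteRecord], distance: int = 5
) -> float:
    """Fraction of SNP records within ``distance`` bases of any indel record
    on the same contig (absolute position difference ≤ ``distance``).

    Raises ``ValueError`` on input containing no SNP records (undefined
    fraction).
    """
    snp_pos: dict[str, list[int]] = {}
    indel_pos: dict[str, list[int]] = {}
    for site in sites:
        if site.is_snp:
            snp_pos.setdefault(site.chrom, []).append(site.pos)
        elif site.is_indel:
            indel_pos.setdefault(site.chrom, []).append(site.pos)
    n_snps = sum(len(v) for v in snp_pos.values())
    if n_snps == 0:
        raise ValueError("no SNP records: indel-proximity fraction undefined")
    n_near = 0
    for chrom, positions in snp_pos.items():
        indels = np.sort(np.asarray(indel_pos.get(chrom, []), dtype=np.int64))
        if indels.size == 0:
            continue
        pos = np.asarray(positions, dtype=np.int64)
        left = np.searchsorted(indels, pos - distance, side="left")
        right = np.searchsorted(indels, pos + distance, side="right")
        n_near += int((right > left).sum())
    return n_near / n_snps
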