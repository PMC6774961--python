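"""Readers and containers for the standard formats the pipeline touches.

Coordinate convention: all positions are 1-based, matching VCF. Reference
slicing for a triplet centred on ``pos`` therefore covers the 0-based
half-open interval ``[pos - 2, pos + 1)``.

Genotypes are stored per site in one of three interchangeable layouts — VCF
allele-index pairs, per-sample alt-allele dosages (used by the synthetic
generator), or a sparse carrier list for rare variants — all exposing the same
counting interface, so downstream code never branches on the representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("hetspec")

#: The five major geographical regions used for the human panel.
DEFAULT_REGIONS = (
    "Africa",
    "Europe",
    "Central Southern Asia",
    "East Asia",
    "America",
)


class PanelError(ValueError):
    """Malformed or inconsistent sample panel."""


class TripletUnavailable(Exception):
    """The reference triplet at a position cannot be used; skip the variant."""


class ContigEdgeError(TripletUnavailable):
    """Focal position lacks a flanking base (contig edge)."""


class AmbiguousBaseError(TripletUnavailable):
    """Reference triplet contains an N or other ambiguity code."""


# ---------------------------------------------------------------------------
# Sample panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplePanel:
    """Sample → population → major geographical region mapping.

    ``regions`` is the ordered list of region names; every sample belongs to
    exactly one region and every region has at least one sample.
    """

    samples: tuple[str, ...]
    populations: tuple[str, ...]
    sample_regions: tuple[str, ...]
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            seen, dups = set(), []
            for s in self.samples:
                if s in seen:
                    dups.append(s)
                seen.add(s)
            raise PanelError(f"duplicate sample IDs in panel: {sorted(set(dups))}")
        if not (len(self.samples) == len(self.populations) == len(self.sample_regions)):
            raise PanelError("samples, populations and regions differ in length")
        bad = [
            (s, r)
            for s, r in zip(self.samples, self.sample_regions)
            if r not in self.regions
        ]
        if bad:
            raise PanelError(f"rows with region outside configured list: {bad[:10]}")
        present = set(self.sample_regions)
        empty = [r for r in self.regions if r not in present]
        if empty:
            raise PanelError(f"regions with no samples: {empty}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_index(self) -> Mapping[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    @property
    def region_ids(self) -> np.ndarray:
        """Per-sample integer region id (index into ``regions``)."""
        rid = {r: i for i, r in enumerate(self.regions)}
        return np.array([rid[r] for r in self.sample_regions], dtype=np.int32)

    def region_sample_indices(self, region: str) -> np.ndarray:
        if region not in self.regions:
            raise PanelError(f"unknown region {region!r}")
        return np.array(
            [i for i, r in enumerate(self.sample_regions) if r == region],
            dtype=np.int64,
        )

    def region_of(self, sample: str) -> str:
        return self.sample_regions[self.sample_index[sample]]


_PANEL_HEADER = ("sample", "population", "region")


def read_panel(path: str | Path, regions: Sequence[str] | None = None) -> SamplePanel:
    """Read a tab-separated panel (sample, population, region; header optional).

    If ``regions`` is given it fixes the region order and any row naming a
    region outside it is an error; otherwise regions are taken in order of
    first appearance.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelError(f"{path}:{ln}: expected 3 tab-separated columns")
            if ln == 1 and tuple(p.strip().lower() for p in parts[:3]) == _PANEL_HEADER:
                continue  # header line
            sample, pop, region = (p.strip() for p in parts[:3])
            if not region:
                raise PanelError(f"{path}:{ln}: empty region for sample {sample!r}")
            rows.append((sample, pop, region))
    if not rows:
        raise PanelError(f"{path}: no samples")
    if regions is None:
        ordered: list[str] = []
        for _, _, r in rows:
            if r not in ordered:
                ordered.append(r)
        regions = tuple(ordered)
    else:
        regions = tuple(regions)
        offending = [(s, r) for s, _, r in rows if r not in regions]
        if offending:
            raise PanelError(
                f"{path}: rows with unknown region names: {offending[:10]}"
            )
    return SamplePanel(
        samples=tuple(s for s, _, _ in rows),
        populations=tuple(p for _, p, _ in rows),
        sample_regions=tuple(r for _, _, r in rows),
        regions=regions,
    )


def write_panel(panel: SamplePanel, path: str | Path, header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("sample\tpopulation\tregion\n")
        for s, p, r in zip(panel.samples, panel.populations, panel.sample_regions):
            fh.write(f"{s}\t{p}\t{r}\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


class Genotypes:
    """Common interface over the genotype layouts (diploid, biallelic focus)."""

    n_samples: int

    def alt_count(self, sample_indices: np.ndarray | None = None) -> int:
        raise NotImplementedError

    def called_chromosomes(self, sample_indices: np.ndarray | None = None) -> int:
        raise NotImplementedError

    def allele_counts(self, n_alleles: int = 2) -> np.ndarray:
        raise NotImplementedError

    def carrier_samples(self, allele: int = 1) -> np.ndarray:
        """Indices of samples carrying ≥1 copy of ``allele``."""
        raise NotImplementedError

    def region_alt_counts(
        self, region_ids: np.ndarray, n_regions: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(alt copies, called chromosomes) per region — used for landscapes."""
        raise NotImplementedError

    def dosages(self) -> np.ndarray:
        """Per-sample count of the alt allele (missing counted as 0)."""
        raise NotImplementedError


class PairGenotypes(Genotypes):
    """(n_samples, 2) array of allele indices; -1 marks a missing allele."""

    __slots__ = ("arr", "n_samples")

    def __init__(self, arr: np.ndarray):
        arr = np.asarray(arr, dtype=np.int8)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("genotype array must have shape (n_samples, 2)")
        self.arr = arr
        self.n_samples = arr.shape[0]

    def alt_count(self, sample_indices=None) -> int:
        a = self.arr if sample_indices is None else self.arr[sample_indices]
        return int((a == 1).sum())

    def called_chromosomes(self, sample_indices=None) -> int:
        a = self.arr if sample_indices is None else self.arr[sample_indices]
        return int((a >= 0).sum())

    def allele_counts(self, n_alleles: int = 2) -> np.ndarray:
        flat = self.arr[self.arr >= 0]
        return np.bincount(flat, minlength=n_alleles)

    def carrier_samples(self, allele: int = 1) -> np.ndarray:
        return np.nonzero((self.arr == allele).any(axis=1))[0]

    def region_alt_counts(self, region_ids, n_regions):
        alt = np.bincount(
            region_ids, weights=(self.arr == 1).sum(axis=1), minlength=n_regions
        )
        called = np.bincount(
            region_ids, weights=(self.arr >= 0).sum(axis=1), minlength=n_regions
        )
        return alt, called

    def dosages(self) -> np.ndarray:
        return (self.arr == 1).sum(axis=1).astype(np.int64)


class DosageGenotypes(Genotypes):
    """Per-sample alt-allele dosage (0/1/2), fully called. Synthetic data."""

    __slots__ = ("dos", "n_samples")

    def __init__(self, dosages: np.ndarray):
        self.dos = np.asarray(dosages, dtype=np.int8)
        self.n_samples = self.dos.shape[0]

    def alt_count(self, sample_indices=None) -> int:
        d = self.dos if sample_indices is None else self.dos[sample_indices]
        return int(d.sum())

    def called_chromosomes(self, sample_indices=None) -> int:
        n = self.n_samples if sample_indices is None else len(sample_indices)
        return 2 * n

    def allele_counts(self, n_alleles: int = 2) -> np.ndarray:
        alt = int(self.dos.sum())
        counts = np.zeros(n_alleles, dtype=np.int64)
        counts[0] = 2 * self.n_samples - alt
        counts[1] = alt
        return counts

    def carrier_samples(self, allele: int = 1) -> np.ndarray:
        if allele == 1:
            return np.nonzero(self.dos > 0)[0]
        return np.nonzero(self.dos < 2)[0]

    def region_alt_counts(self, region_ids, n_regions):
        alt = np.bincount(region_ids, weights=self.dos, minlength=n_regions)
        called = 2.0 * np.bincount(region_ids, minlength=n_regions)
        return alt, called

    def dosages(self) -> np.ndarray:
        return self.dos.astype(np.int64)


class SparseGenotypes(Genotypes):
    """Rare-variant layout: everyone homozygous reference except listed carriers."""

    __slots__ = ("n_samples", "carrier_idx", "carrier_dosage")

    def __init__(
        self, n_samples: int, carrier_idx: np.ndarray, carrier_dosage: np.ndarray
    ):
        self.n_samples = int(n_samples)
        self.carrier_idx = np.asarray(carrier_idx, dtype=np.int64)
        self.carrier_dosage = np.asarray(carrier_dosage, dtype=np.int8)

    def alt_count(self, sample_indices=None) -> int:
        if sample_indices is None:
            return int(self.carrier_dosage.sum())
        sel = np.isin(self.carrier_idx, sample_indices)
        return int(self.carrier_dosage[sel].sum())

    def called_chromosomes(self, sample_indices=None) -> int:
        n = self.n_samples if sample_indices is None else len(sample_indices)
        return 2 * n

    def allele_counts(self, n_alleles: int = 2) -> np.ndarray:
        alt = int(self.carrier_dosage.sum())
        counts = np.zeros(n_alleles, dtype=np.int64)
        counts[0] = 2 * self.n_samples - alt
        counts[1] = alt
        return counts

    def carrier_samples(self, allele: int = 1) -> np.ndarray:
        if allele == 1:
            return self.carrier_idx.copy()
        mask = np.ones(self.n_samples, dtype=bool)
        mask[self.carrier_idx[self.carrier_dosage == 2]] = False
        return np.nonzero(mask)[0]

    def region_alt_counts(self, region_ids, n_regions):
        alt = np.bincount(
            region_ids[self.carrier_idx],
            weights=self.carrier_dosage,
            minlength=n_regions,
        )
        called = 2.0 * np.bincount(region_ids, minlength=n_regions)
        return alt, called

    def dosages(self) -> np.ndarray:
        d = np.zeros(self.n_samples, dtype=np.int64)
        d[self.carrier_idx] = self.carrier_dosage
        return d


# ---------------------------------------------------------------------------
# Site records
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class SiteRecord:
    """One VCF record restricted to the panel samples."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: Genotypes
    is_snp: bool
    is_indel: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be ≥ 1, got {self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def is_biallelic_snp(self) -> bool:
        return self.is_snp and self.is_biallelic


@dataclass(frozen=True)
class ReferenceWindow:
    """A contiguous stretch of reference sequence, 1-based inclusive ends."""

    chrom: str
    start: int
    end: int
    bases: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window [{self.start}, {self.end}]")
        if len(self.bases) != self.end - self.start + 1:
            raise ValueError("window length does not match coordinates")
        if any(b not in "ACGTN" for b in self.bases):
            raise ValueError("window bases must be A/C/G/T/N (uppercase)")


def _site_flags(ref: str, alts: tuple[str, ...]) -> tuple[bool, bool]:
    if not alts:
        return False, False
    is_snp = len(ref) == 1 and all(len(a) == 1 for a in alts)
    is_indel = any(len(a) != len(ref) for a in alts)
    return is_snp, is_indel


def stream_sites(vcf_path: str | Path, panel: SamplePanel) -> Iterator[SiteRecord]:
    """Stream VCF records as :class:`SiteRecord` in coordinate order.

    Genotypes are reordered to match ``panel.samples``. VCF samples absent
    from the panel are dropped (warning logged once); panel samples missing
    from the VCF header raise :class:`PanelError`.
    """
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = list(vcf.header.samples)
        header_set = set(header_samples)
        missing = [s for s in panel.samples if s not in header_set]
        if missing:
            raise PanelError(
                f"panel samples missing from VCF header: {missing[:10]}"
            )
        extra = [s for s in header_samples if s not in panel.sample_index]
        if extra:
            logger.warning(
                "dropping %d VCF sample(s) not in panel (e.g. %s)",
                len(extra),
                extra[:5],
            )
        names = list(panel.samples)
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            arr = np.full((len(names), 2), -1, dtype=np.int8)
            for i, s in enumerate(names):
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                for j, allele in enumerate(gt[:2]):
                    if allele is not None:
                        arr[i, j] = allele
            is_snp, is_indel = _site_flags(rec.ref or "", alts)
            yield SiteRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=(rec.ref or "").upper(),
                alt_alleles=tuple(a.upper() for a in alts),
                genotypes=PairGenotypes(arr),
                is_snp=is_snp,
                is_indel=is_indel,
            )


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------


def _contig_length(reference, chrom: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(chrom)
    return len(reference[chrom])


def fetch_reference_triplet(reference, chrom: str, pos: int) -> str:
    """Uppercase reference bases at ``pos - 1, pos, pos + 1`` (1-based).

    ``reference`` is either a ``pysam.FastaFile`` (or anything with a
    0-based ``fetch(chrom, start, end)``) or a plain mapping
    ``chrom -> sequence string``.

    Raises :class:`ContigEdgeError` at contig edges and
    :class:`AmbiguousBaseError` when the triplet contains a non-ACGT base;
    both signal that the variant should be skipped, not a fatal condition.
    """
    if pos < 2:
        raise ContigEdgeError(f"{chrom}:{pos}: no 5' flanking base")
    if pos + 1 > _contig_length(reference, chrom):
        raise ContigEdgeError(f"{chrom}:{pos}: no 3' flanking base")
    if hasattr(reference, "fetch"):
        seq = reference.fetch(chrom, pos - 2, pos + 1)
    else:
        seq = reference[chrom][pos - 2 : pos + 1]
    seq = seq.upper()
    if len(seq) != 3:
        raise ContigEdgeError(f"{chrom}:{pos}: truncated triplet {seq!r}")
    if any(b not in "ACGT" for b in seq):
        raise AmbiguousBaseError(f"{chrom}:{pos}: ambiguous triplet {seq!r}")
    return seq


def fetch_reference_window(
    reference, chrom: str, start: int, end: int
) -> ReferenceWindow:
    """Fetch ``[start, end]`` (1-based inclusive), truncated at contig edges."""
    length = _contig_length(reference, chrom)
    start = max(1, start)
    end = min(length, end)
    if hasattr(reference, "fetch"):
        bases = reference.fetch(chrom, start - 1, end)
    else:
        bases = reference[chrom][start - 1 : end]
    return ReferenceWindow(chrom=chrom, start=start, end=end, bases=bases.upper())
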