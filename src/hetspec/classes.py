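"""Strand-collapsed triplet (3-mer) mutation classes.

A single-base substitution is described by its *ancestral triplet* — the
mutating base together with its immediate 5' and 3' flanking bases — and the
derived base. Every such mutation has two equivalent representations, one per
DNA strand: the triplet on one strand corresponds to the reverse complement on
the other, with the derived base complemented. Collapsing the two so that the
central ancestral base is A or C leaves 32 distinct triplets, each with three
possible derived bases, i.e. 96 canonical mutation classes (192 raw
strand-specific (triplet, substitution) pairs map 2-to-1 onto them).

Class labels follow the ``XYZ(W)`` convention: ``ACA(T)`` means ACA → ATA.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
CANONICAL_CENTRAL_BASES = ("A", "C")

#: The six central-base substitution types; A>G and C>T are transitions.
BASE_CHANGE_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
TRANSITIONS = frozenset({"A>G", "C>T"})


class InvalidBaseError(ValueError):
    """A base outside {A, C, G, T} where an unambiguous base is required."""


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise InvalidBaseError(f"not an unambiguous DNA base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


@dataclass(frozen=True, order=True)
class MutationClass:
    """One of the 96 canonical triplet mutation classes.

    Attributes
    ----------
    triplet : str
        Ancestral triplet with central base A or C.
    derived_base : str
        The base the central position mutates to.
    """

    triplet: str
    derived_base: str

    def __post_init__(self) -> None:
        if len(self.triplet) != 3 or any(b not in BASES for b in self.triplet):
            raise InvalidBaseError(f"invalid triplet {self.triplet!r}")
        if self.derived_base not in BASES:
            raise InvalidBaseError(f"invalid derived base {self.derived_base!r}")
        if self.triplet[1] not in CANONICAL_CENTRAL_BASES:
            raise ValueError(
                f"central base of canonical triplet must be A or C, got {self.triplet!r}"
            )
        if self.derived_base == self.triplet[1]:
            raise ValueError(f"derived base equals central base in {self.triplet!r}")

    @property
    def central_base(self) -> str:
        return self.triplet[1]

    @property
    def label(self) -> str:
        """Serialized form, e.g. ``"ACA(T)"`` for ACA → ATA."""
        return f"{self.triplet}({self.derived_base})"

    @property
    def base_change(self) -> str:
        """The central substitution type, e.g. ``"C>T"``."""
        return f"{self.central_base}>{self.derived_base}"

    @property
    def is_transition(self) -> bool:
        return self.base_change in TRANSITIONS

    @property
    def gc_count(self) -> int:
        return gc_content(self)

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        label = label.strip()
        if len(label) != 6 or label[3] != "(" or label[5] != ")":
            raise ValueError(f"malformed mutation class label {label!r}")
        return cls(label[:3], label[4])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def collapse_to_canonical(triplet: str, derived_base: str) -> MutationClass:
    """Map a raw (triplet, derived base) pair to its canonical class.

    If the central base is already A or C the pair is returned as-is;
    otherwise both the triplet (reverse-complemented) and the derived base
    (complemented) are flipped to the opposite strand.
    """
    if len(triplet) != 3:
        raise InvalidBaseError(f"triplet must have 3 bases, got {triplet!r}")
    for b in triplet:
        if b not in BASES:
            raise InvalidBaseError(f"invalid base {b!r} in triplet {triplet!r}")
    if derived_base not in BASES:
        raise InvalidBaseError(f"invalid derived base {derived_base!r}")
    if derived_base == triplet[1]:
        raise ValueError(
            f"derived base {derived_base!r} equals ancestral central base of {triplet!r}"
        )
    if triplet[1] in CANONICAL_CENTRAL_BASES:
        return MutationClass(triplet, derived_base)
    return MutationClass(reverse_complement(triplet), complement(derived_base))


@lru_cache(maxsize=1)
def enumerate_classes() -> tuple[MutationClass, ...]:
    """All 96 canonical classes in the fixed output order.

    Order: triplet lexicographic over the 32 canonical triplets, then derived
    base lexicographic — so every output table is deterministic.
    """
    classes = []
    for left in BASES:
        for central in CANONICAL_CENTRAL_BASES:
            for right in BASES:
                triplet = left + central + right
                for derived in BASES:
                    if derived != central:
                        classes.append(MutationClass(triplet, derived))
    return tuple(sorted(classes))


@lru_cache(maxsize=1)
def class_labels() -> tuple[str, ...]:
    return tuple(c.label for c in enumerate_classes())


@lru_cache(maxsize=1)
def _canonical_lookup() -> dict[tuple[str, str], MutationClass]:
    # all 192 raw pairs -> 96 canonical classes, precomputed once
    table: dict[tuple[str, str], MutationClass] = {}
    for left in BASES:
        for central in BASES:
            for right in BASES:
                for derived in BASES:
                    if derived == central:
                        continue
                    table[(left + central + right, derived)] = collapse_to_canonical(
                        left + central + right, derived
                    )
    return table


class MajorAlleleTieError(ValueError):
    """Major and minor allele counts are equal: mutation direction undefined."""


def classify_variant(
    ref_triplet: str, major_allele: str, minor_allele: str
) -> MutationClass:
    """Classify a biallelic SNP given its reference triplet context.

    The ancestral triplet is the reference flanking bases around the
    panel-wide *major* allele (which replaces the central reference base when
    the reference carries the minor allele); the derived base is the minor
    allele. The result is strand-collapsed to canonical form.

    Raises
    ------
    InvalidBaseError
        If any base involved is not one of A/C/G/T (e.g. an N in the
        reference context) — the caller should exclude the variant and count
        the skip.
    """
    ref_triplet = ref_triplet.upper()
    major_allele = major_allele.upper()
    minor_allele = minor_allele.upper()
    if len(ref_triplet) != 3:
        raise InvalidBaseError(f"triplet must have 3 bases, got {ref_triplet!r}")
    for b in (*ref_triplet, major_allele, minor_allele):
        if b not in BASES:
            raise InvalidBaseError(f"ambiguous or invalid base {b!r}")
    if major_allele == minor_allele:
        raise ValueError("major and minor alleles are identical")
    ancestral = ref_triplet[0] + major_allele + ref_triplet[2]
    try:
        return _canonical_lookup()[(ancestral, minor_allele)]
    except KeyError:  # pragma: no cover - guarded above
        raise InvalidBaseError(f"cannot classify {ancestral!r} -> {minor_allele!r}")


def gc_content(mutation_class: MutationClass) -> int:
    """Number of G or C bases (0–3) in the ancestral triplet."""
    return sum(1 for b in mutation_class.triplet if b in "GC")


def classes_of_type(base_change: str) -> tuple[MutationClass, ...]:
    """The 16 classes sharing a central substitution type, e.g. ``"C>T"``."""
    if base_change not in BASE_CHANGE_TYPES:
        raise ValueError(f"unknown base change type {base_change!r}")
    return tuple(c for c in enumerate_classes() if c.base_change == base_change)


def labels_to_classes(labels: Iterable[str]) -> list[MutationClass]:
    return [MutationClass.from_label(lbl) for lbl in labels]
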