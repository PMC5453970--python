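"""Novelty annotation against a known-variant catalog, allele-frequency
classes, and common-SV flagging.

A SNP/indel is *known* iff its exact ``(chrom, pos, ref, alt)`` key appears
in the catalog (a dbSNP-style lookup) and *novel* otherwise. A structural
variant is known iff the catalog holds an SV of the same type with
reciprocal overlap at or above a configurable threshold (a DGV-style match).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from intervaltree import IntervalTree

from .core_io import CallSet, MalformedInputError, VariantRecord, read_vcf

__all__ = [
    "Catalog",
    "AnnotatedVariant",
    "AnnotatedCallSet",
    "mark_novelty",
    "sv_novelty",
    "novelty_rate",
    "compute_aaf",
    "freq_class",
    "flag_common_sv",
]

#: AAF above this is a common variant; at or below, low-frequency.
COMMON_AAF = 0.05

#: Cohort fraction at/above which an SV counts as common (16 of 48 samples).
COMMON_SV_FRACTION = 1 / 3


@dataclass
class Catalog:
    """A known-variant catalog: exact keys for SNPs/indels, typed intervals
    for SVs (0-based half-open)."""

    entries: set[tuple[str, int, str, str]] = field(default_factory=set)
    sv_entries: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, svtype in self.sv_entries:
            if end <= start:
                raise ValueError(f"invalid SV interval {chrom}:{start}-{end}")
        self._sv_trees: Optional[dict[tuple[str, str], IntervalTree]] = None

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def sv_trees(self) -> dict[tuple[str, str], IntervalTree]:
        """(chrom, svtype)-keyed interval trees over catalog SVs."""
        if self._sv_trees is None:
            trees: dict[tuple[str, str], IntervalTree] = {}
            for chrom, start, end, svtype in self.sv_entries:
                trees.setdefault((chrom, svtype.upper()), IntervalTree()).addi(start, end)
            self._sv_trees = trees
        return self._sv_trees

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Catalog":
        """Load a 4-column TSV (chrom, pos [1-based], ref, alt)."""
        path = Path(path)
        entries = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise MalformedInputError(f"{path.name}:{lineno}: expected 4 columns")
                try:
                    pos = int(parts[1])
                except ValueError as exc:
                    raise MalformedInputError(f"{path.name}:{lineno}: non-integer pos") from exc
                entries.add((parts[0], pos, parts[2], parts[3]))
        return cls(entries=entries)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "Catalog":
        cs = read_vcf(path)
        return cls(entries={v.key for v in cs.variants})

    @classmethod
    def from_sv_bed(cls, path: str | Path) -> "Catalog":
        """Load an SV catalog from BED + type column (chrom, start, end, type)."""
        path = Path(path)
        sv_entries = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise MalformedInputError(f"{path.name}:{lineno}: expected 4 columns")
                try:
                    sv_entries.append((parts[0], int(parts[1]), int(parts[2]), parts[3].upper()))
                except ValueError as exc:
                    raise MalformedInputError(f"{path.name}:{lineno}: bad coordinates") from exc
        return cls(sv_entries=sv_entries)


@dataclass(frozen=True, slots=True)
class AnnotatedVariant:
    """A variant plus its novelty flag and cohort frequency annotations."""

    base: VariantRecord
    novel: bool
    aaf: Optional[float]
    freq_class: Optional[str]  # "COMMON" or "LOW"
    n_samples_present: int


@dataclass
class AnnotatedCallSet:
    label: str
    n_samples: int
    variants: list[AnnotatedVariant]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def n_novel(self) -> int:
        return sum(1 for v in self.variants if v.novel)

    def novelty_rate(self) -> float:
        return novelty_rate(self.n_novel, len(self.variants))


def compute_aaf(record: VariantRecord) -> float:
    """Alternative allele frequency over non-missing diploid calls.

    Raises if every genotype is missing.
    """
    alt_alleles = 0
    n_called = 0
    for call in record.per_sample:
        if call.gt is None:
            continue
        n_called += 1
        alt_alleles += sum(1 for a in call.gt if a == 1)
    if n_called == 0:
        raise ValueError("AAF undefined: all genotypes missing")
    return alt_alleles / (2 * n_called)


def freq_class(aaf: float, common_aaf: float = COMMON_AAF) -> str:
    """COMMON iff AAF strictly exceeds the threshold (default 5%)."""
    return "COMMON" if aaf > common_aaf else "LOW"


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Smaller of the two mutual overlap fractions (0 if disjoint)."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def sv_novelty(sv: VariantRecord, cat: Catalog, min_reciprocal: float = 0.5) -> bool:
    """True (novel) unless the catalog holds a same-type SV with reciprocal
    overlap >= ``min_reciprocal``."""
    if not sv.var_class.is_sv:
        raise ValueError(f"sv_novelty requires an SV record, got {sv.var_class}")
    svtype = sv.var_class.value.removeprefix("SV_")
    interval = sv.interval0
    tree = cat.sv_trees().get((sv.chrom, svtype))
    if tree is None:
        return True
    for hit in tree.overlap(interval[0], interval[1]):
        if _reciprocal_overlap(interval, (hit.begin, hit.end)) >= min_reciprocal:
            return False
    return True


def mark_novelty(
    cs: CallSet,
    cat: Catalog,
    min_reciprocal: float = 0.5,
    common_aaf: float = COMMON_AAF,
) -> AnnotatedCallSet:
    """Annotate every record with novelty, AAF, frequency class and carrier
    count. Deterministic and independent of record order.

    SNPs/indels match the catalog by exact key; SVs by same-type reciprocal
    overlap. Records without any called genotype get ``aaf=None``.
    """
    out: list[AnnotatedVariant] = []
    for v in cs.variants:
        if v.var_class.is_sv:
            novel = sv_novelty(v, cat, min_reciprocal=min_reciprocal)
        else:
            novel = v.key not in cat
        try:
            aaf = compute_aaf(v)
            fclass = freq_class(aaf, common_aaf)
        except ValueError:
            aaf, fclass = None, None
        out.append(
            AnnotatedVariant(
                base=v,
                novel=novel,
                aaf=aaf,
                freq_class=fclass,
                n_samples_present=v.n_samples_present,
            )
        )
    return AnnotatedCallSet(label=cs.label, n_samples=cs.n_samples, variants=out)


def novelty_rate(n_novel: int, n_total: int) -> float:
    """Novelty rate as a percentage: 100 * n_novel / n_total."""
    if n_total <= 0:
        raise ValueError("novelty rate undefined for empty set")
    if not 0 <= n_novel <= n_total:
        raise ValueError("n_novel must lie in [0, n_total]")
    return 100.0 * n_novel / n_total


def flag_common_sv(n_present: int, n_samples: int, fraction: float = COMMON_SV_FRACTION) -> bool:
    """Common iff carried by at least ceil(fraction * n_samples) samples.

    The ceiling makes one third of 48 samples a threshold of 16 carriers.
    """
    if not 0 <= n_present <= n_samples:
        raise ValueError("n_present must lie in [0, n_samples]")
    return n_present >= math.ceil(fraction * n_samples)
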