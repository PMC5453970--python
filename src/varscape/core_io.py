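"""Variant and interval containers, standard-format I/O, and hard filtering.

Coordinate conventions
----------------------
VCF positions are 1-based and stay 1-based on :class:`VariantRecord`.
All interval containers (:class:`FeatureSet`, genome bins) are 0-based
half-open, the BED convention. Conversion between the two happens exactly
once, at the point where a variant is placed into an interval: a variant at
1-based position ``p`` occupies the 0-based coordinate ``p - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from intervaltree import IntervalTree

__all__ = [
    "VarClass",
    "SampleCall",
    "VariantRecord",
    "CallSet",
    "FilterThresholds",
    "FeatureSet",
    "MalformedInputError",
    "MultiAllelicError",
    "classify_variant",
    "compute_mrr",
    "filter_callset",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

#: Largest length difference between REF and ALT that still counts as an
#: indel; anything longer is a structural variant.
INDEL_MAX_BP = 50


class MalformedInputError(ValueError):
    """A line of an input file could not be parsed; carries the line number."""


class MultiAllelicError(ValueError):
    """Raised for multi-allelic records: the pipeline operates on bi-allelic
    records, so multi-allelic sites must be split upstream."""


class VarClass(str, Enum):
    SNP = "SNP"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    SV_DEL = "SV_DEL"
    SV_DUP = "SV_DUP"
    SV_INV = "SV_INV"

    @property
    def is_sv(self) -> bool:
        return self in (VarClass.SV_DEL, VarClass.SV_DUP, VarClass.SV_INV)

    @property
    def is_indel(self) -> bool:
        return self in (VarClass.INSERTION, VarClass.DELETION)


_SV_BY_TYPE = {"DEL": VarClass.SV_DEL, "DUP": VarClass.SV_DUP, "INV": VarClass.SV_INV}


@dataclass(frozen=True, slots=True)
class SampleCall:
    """One sample's genotype call at one site.

    ``gt`` is an unordered pair of allele indices (0 = REF, 1 = ALT) or
    ``None`` for a missing genotype (``./.``). ``ad`` is the pair of
    (reference-supporting, alternate-supporting) read counts.
    """

    gt: Optional[tuple[int, int]]
    dp: Optional[int] = None
    gq: Optional[int] = None
    ad: Optional[tuple[int, int]] = None

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]

    @property
    def is_hom_alt(self) -> bool:
        return self.gt is not None and self.gt[0] == self.gt[1] == 1

    @property
    def carries_alt(self) -> bool:
        return self.gt is not None and 1 in self.gt


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single bi-allelic called variant.

    ``pos`` is the 1-based VCF position. ``sv_end`` is the 1-based inclusive
    end for structural variants and ``None`` otherwise.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    per_sample: tuple[SampleCall, ...] = ()
    var_class: VarClass = VarClass.SNP
    sv_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.var_class.is_sv:
            if self.sv_end is not None and self.sv_end <= self.pos:
                raise ValueError("sv_end must be > pos for SVs")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact-match identity used for novelty and concordance."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def start0(self) -> int:
        """0-based coordinate of the (leftmost) affected base."""
        return self.pos - 1

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open footprint; for SVs, pos..sv_end."""
        if self.var_class.is_sv and self.sv_end is not None:
            return (self.pos - 1, self.sv_end)
        return (self.pos - 1, self.pos - 1 + max(1, len(self.ref)))

    @property
    def n_samples_present(self) -> int:
        """Number of samples carrying at least one alternate allele."""
        return sum(1 for c in self.per_sample if c.carries_alt)


@dataclass
class CallSet:
    """An ordered collection of variants for one labelled population."""

    label: str
    n_samples: int
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.variants)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def subset(self, indices: Sequence[int], label: Optional[str] = None) -> "CallSet":
        return CallSet(
            label=label or self.label,
            n_samples=self.n_samples,
            variants=[self.variants[i] for i in indices],
        )

    def select(self, classes: Iterable[VarClass], label: Optional[str] = None) -> "CallSet":
        wanted = set(classes)
        return CallSet(
            label=label or self.label,
            n_samples=self.n_samples,
            variants=[v for v in self.variants if v.var_class in wanted],
        )


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds. All comparisons are inclusive (``>=``).

    Defaults are the standard deep-WGS hard-filter set: per-sample read depth
    >= 20X and genotype quality >= 20, site quality >= 30, and minor-read
    ratio >= 0.2 at heterozygous calls.
    """

    min_dp: float = 20
    min_gq: float = 20
    min_qual: float = 30
    min_mrr: float = 0.2

    def __post_init__(self) -> None:
        if min(self.min_dp, self.min_gq, self.min_qual, self.min_mrr) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_mrr > 0.5:
            raise ValueError("min_mrr cannot exceed 0.5 (MRR is bounded by 0.5)")


@dataclass
class FeatureSet:
    """Named strand-less genomic intervals, 0-based half-open.

    ``scores`` (parallel to ``intervals``) holds per-interval values in
    [0, 1] for scored tracks such as regulatory-potential scores; ``names``
    holds per-interval labels for gene models. Either may be ``None``.
    """

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    scores: Optional[list[float]] = None
    names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        if self.scores is not None:
            if len(self.scores) != len(self.intervals):
                raise ValueError("scores must parallel intervals")
            if any(not (0.0 <= s <= 1.0) for s in self.scores):
                raise ValueError("scores must lie in [0, 1]")
        if self.names is not None and len(self.names) != len(self.intervals):
            raise ValueError("names must parallel intervals")
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees; built lazily, data = interval index."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, (chrom, start, end) in enumerate(self.intervals):
                trees.setdefault(chrom, IntervalTree()).addi(start, end, i)
            self._trees = trees
        return self._trees

    def total_span(self) -> int:
        """Total covered bases after merging overlaps."""
        total = 0
        for tree in self.trees().values():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total


# ---------------------------------------------------------------------------
# classification and filtering
# ---------------------------------------------------------------------------

def classify_variant(
    ref: Optional[str],
    alt: Optional[str],
    sv_type: Optional[str] = None,
    sv_len: Optional[int] = None,
) -> VarClass:
    """Assign a variant class from its alleles or its SV annotation.

    Sequence-resolved records: equal length-1 alleles are SNPs; a length
    difference of 1-50 bp is an insertion or deletion; beyond 50 bp the
    record is promoted to the corresponding SV class (long deletions to
    SV_DEL, long insertions to SV_DUP — the SV vocabulary is the caller-style
    DEL/DUP/INV triple, which has no separate insertion class).

    Records tagged with ``sv_type`` (DEL/DUP/INV) are SVs regardless of
    allele strings.

    Raises
    ------
    MultiAllelicError
        If ``alt`` contains multiple alleles; bi-allelic records only —
        split required.
    """
    if sv_type is not None:
        try:
            return _SV_BY_TYPE[sv_type.upper()]
        except KeyError:
            raise ValueError(f"unknown SV type {sv_type!r}") from None
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty for sequence-resolved records")
    if "," in alt:
        raise MultiAllelicError(f"multi-allelic ALT {alt!r}: split required")
    size = abs(len(ref) - len(alt))
    if size == 0:
        if len(ref) == 1:
            return VarClass.SNP
        raise ValueError(f"equal-length multi-base substitution {ref}>{alt} unsupported")
    if len(alt) > len(ref):
        return VarClass.INSERTION if size <= INDEL_MAX_BP else VarClass.SV_DUP
    return VarClass.DELETION if size <= INDEL_MAX_BP else VarClass.SV_DEL


def compute_mrr(ad: tuple[int, int]) -> float:
    """Minor-read ratio: min(ref_reads, alt_reads) / total reads, in [0, 0.5].

    Undefined (raises) at zero total depth; callers treat that as a failed
    filter criterion.
    """
    ref_reads, alt_reads = ad
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    total = ref_reads + alt_reads
    if total == 0:
        raise ValueError("MRR undefined at zero total depth")
    return min(ref_reads, alt_reads) / total


def _call_passes(call: SampleCall, th: FilterThresholds) -> bool:
    if call.is_missing:
        return False
    if call.dp is None or call.dp < th.min_dp:
        return False
    if call.gq is None or call.gq < th.min_gq:
        return False
    if call.is_het:
        # MRR applies to heterozygous calls only; a het call without usable
        # AD cannot demonstrate allele balance and fails.
        if call.ad is None or sum(call.ad) == 0:
            return False
        if compute_mrr(call.ad) < th.min_mrr:
            return False
    return True


def filter_callset(cs: CallSet, th: FilterThresholds = FilterThresholds()) -> CallSet:
    """Apply hard filters; a record is retained iff its site quality passes
    and at least one sample call passes all per-sample criteria.

    All boundaries are inclusive. Output preserves record order and is a
    subset of the input; the operation is idempotent.
    """
    kept = [
        v
        for v in cs.variants
        if v.qual >= th.min_qual and any(_call_passes(c, th) for c in v.per_sample)
    ]
    return CallSet(label=cs.label, n_samples=cs.n_samples, variants=kept)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_sample(sample) -> SampleCall:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        gt_pair = None
    else:
        gt_pair = (int(gt[0]), int(gt[1])) if len(gt) == 2 else (int(gt[0]), int(gt[0]))
    dp = sample.get("DP")
    gq = sample.get("GQ")
    ad = sample.get("AD")
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ad_pair = (int(ad[0]), int(ad[1]))
    else:
        ad_pair = None
    return SampleCall(
        gt=gt_pair,
        dp=int(dp) if dp is not None else None,
        gq=int(gq) if gq is not None else None,
        ad=ad_pair,
    )


def read_vcf(path: str | Path, label: Optional[str] = None) -> CallSet:
    """Read a (possibly multi-sample) VCF v4.x into a :class:`CallSet`.

    Bi-allelic records only: a record with more than one ALT allele raises
    :class:`MultiAllelicError`. Symbolic SV ALTs (``<DEL>``, ``<DUP>``,
    ``<INV>``) are classified from INFO SVTYPE/END.
    """
    path = Path(path)
    variants: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        n_samples = max(1, len(samples))
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                raise MultiAllelicError(
                    f"{path.name}: multi-allelic record at {rec.chrom}:{rec.pos}: split required"
                )
            if not alts:
                continue
            alt = alts[0]
            sv_type = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
            if sv_type is None and alt.startswith("<") and alt.endswith(">"):
                sv_type = alt.strip("<>")
            if sv_type is not None:
                var_class = classify_variant(None, None, sv_type=str(sv_type))
                sv_end = int(rec.stop)  # pysam's stop honours INFO END
            else:
                var_class = classify_variant(rec.ref, alt)
                # sequence-resolved records promoted to SV classes span the
                # length difference on the reference
                sv_end = rec.pos + abs(len(rec.ref) - len(alt)) if var_class.is_sv else None
            calls = tuple(_parse_sample(rec.samples[s]) for s in samples)
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    per_sample=calls,
                    var_class=var_class,
                    sv_end=sv_end,
                )
            )
    return CallSet(label=label or path.stem, n_samples=n_samples, variants=variants)


def _fmt_qual(q: float) -> str:
    # Canonical qual rendering: integers bare, otherwise 2 decimals. Chosen so
    # that write -> read (float32 in htslib) -> write is byte-stable.
    if float(q) == int(q):
        return str(int(q))
    return f"{q:.2f}"


def _fmt_call(c: SampleCall) -> str:
    gt = "./." if c.gt is None else f"{c.gt[0]}/{c.gt[1]}"
    dp = "." if c.dp is None else str(c.dp)
    gq = "." if c.gq is None else str(c.gq)
    ad = "." if c.ad is None else f"{c.ad[0]},{c.ad[1]}"
    return f"{gt}:{dp}:{gq}:{ad}"


def write_vcf(
    cs: CallSet,
    path: str | Path,
    chrom_sizes: Optional[dict[str, int]] = None,
    sample_names: Optional[Sequence[str]] = None,
) -> Path:
    """Write a CallSet as an uncompressed VCF v4.2 with GT:DP:GQ:AD calls."""
    path = Path(path)
    if sample_names is None:
        sample_names = [f"S{i + 1:03d}" for i in range(cs.n_samples)]
    lines = ["##fileformat=VCFv4.2", "##source=varscape"]
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            lines.append(f"##contig=<ID={chrom},length={size}>")
    else:
        for chrom in dict.fromkeys(v.chrom for v in cs.variants):
            lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names),
    ]
    for v in cs.variants:
        if v.var_class.is_sv:
            alt = f"<{v.var_class.value.removeprefix('SV_')}>"
            info = f"SVTYPE={v.var_class.value.removeprefix('SV_')};END={v.sv_end}"
        else:
            alt = v.alt
            info = "."
        row = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            alt,
            _fmt_qual(v.qual),
            "PASS",
            info,
            "GT:DP:GQ:AD",
        ] + [_fmt_call(c) for c in v.per_sample]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# BED and chromosome sizes
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    name: Optional[str] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
    score_column: bool = False,
) -> FeatureSet:
    """Read BED3/BED4/BED5 into a :class:`FeatureSet` (0-based half-open).

    With ``score_column=True`` the 5th column is parsed as a [0, 1] score
    (regulatory-potential style track). If ``chrom_sizes`` is given, lines on
    chromosomes absent from it are skipped with a warning.
    """
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    names: list[str] = []
    scores: list[float] = []
    any_name = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedInputError(f"{path.name}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MalformedInputError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise MalformedInputError(f"{path.name}:{lineno}: invalid interval {start}-{end}")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                warnings.warn(
                    f"{path.name}:{lineno}: chromosome {chrom!r} not in genome table; skipped",
                    stacklevel=2,
                )
                continue
            intervals.append((chrom, start, end))
            if len(parts) >= 4 and parts[3] != ".":
                any_name = True
                names.append(parts[3])
            else:
                names.append(f"{chrom}:{start}-{end}")
            if score_column:
                if len(parts) < 5:
                    raise MalformedInputError(f"{path.name}:{lineno}: missing score column")
                try:
                    scores.append(float(parts[4]))
                except ValueError as exc:
                    raise MalformedInputError(f"{path.name}:{lineno}: non-numeric score") from exc
    return FeatureSet(
        name=name or path.stem,
        intervals=intervals,
        scores=scores if score_column else None,
        names=names if any_name else None,
    )


def write_bed(features: FeatureSet, path: str | Path) -> Path:
    """Write a FeatureSet as BED3/BED4/BED5 (as much as the set carries)."""
    path = Path(path)
    lines = []
    for i, (chrom, start, end) in enumerate(features.intervals):
        parts = [chrom, str(start), str(end)]
        if features.names is not None or features.scores is not None:
            parts.append(features.names[i] if features.names is not None else ".")
        if features.scores is not None:
            parts.append(f"{features.scores[i]:g}")
        lines.append("\t".join(parts))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-size TSV into an ordered dict."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MalformedInputError(f"{path.name}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise MalformedInputError(f"{path.name}:{lineno}: non-integer size") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{c}\t{s}\n" for c, s in sizes.items()))
    return path
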