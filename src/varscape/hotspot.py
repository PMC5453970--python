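"""Genome-binned variant-density comparison between a cohort and a reference
population.

The genome is tiled with non-overlapping bins (1 Mb by default). For bin
``i`` the density fold is the ratio of in-bin proportions,

    fold_i = (n_cohort_bin_i / total_cohort) / (n_ref_bin_i / total_ref),

and significance comes from a one-sided Fisher exact test on the 2x2 table
(cohort in-bin, cohort out-of-bin; reference in-bin, reference out-of-bin).
A bin is a hotspot when fold >= 1.5 and p <= 0.05 (both thresholds
inclusive and configurable). Hotspot genes are those whose interval
intersects the bin expanded by a 5 kb flank on each side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import CallSet, FeatureSet

__all__ = [
    "GenomeBins",
    "BinCounts",
    "HotspotCall",
    "make_bins",
    "count_per_bin",
    "fold_ratio",
    "fisher_exact_greater",
    "call_hotspots",
    "associate_genes",
    "write_hotspot_bed",
]

DEFAULT_BIN_WIDTH = 1_000_000
DEFAULT_FOLD_MIN = 1.5
DEFAULT_P_MAX = 0.05
DEFAULT_GENE_FLANK = 5_000


@dataclass(frozen=True)
class GenomeBins:
    """Non-overlapping bins tiling each chromosome, 0-based half-open; the
    terminal bin of a chromosome may be shorter than ``width``."""

    chrom_sizes: dict[str, int]
    width: int
    bins: tuple[tuple[str, int, int], ...]

    def __len__(self) -> int:
        return len(self.bins)

    def bin_index(self, chrom: str, pos: int) -> Optional[int]:
        """Global bin index for a 1-based variant position, or None if the
        chromosome is not binned."""
        if chrom not in self._offsets:
            return None
        offset, size = self._offsets[chrom]
        p0 = pos - 1
        if not 0 <= p0 < size:
            return None
        return offset + p0 // self.width

    @property
    def _offsets(self) -> dict[str, tuple[int, int]]:
        offsets: dict[str, tuple[int, int]] = {}
        acc = 0
        for chrom, size in self.chrom_sizes.items():
            offsets[chrom] = (acc, size)
            acc += math.ceil(size / self.width)
        return offsets


def make_bins(chrom_sizes: dict[str, int], width: int = DEFAULT_BIN_WIDTH) -> GenomeBins:
    """Tile every chromosome with ceil(size/width) bins; the last bin is
    clipped at the chromosome end so the bins exactly span the genome."""
    if width <= 0:
        raise ValueError("bin width must be > 0")
    bins: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive size")
        for start in range(0, size, width):
            bins.append((chrom, start, min(start + width, size)))
    return GenomeBins(chrom_sizes=dict(chrom_sizes), width=width, bins=tuple(bins))


def count_per_bin(cs: CallSet, bins: GenomeBins) -> np.ndarray:
    """Per-bin variant counts aligned with ``bins.bins``.

    A variant at 1-based position p falls in the bin containing coordinate
    p-1; each variant counts exactly once. Variants on chromosomes absent
    from the bins are excluded with a warning.
    """
    counts = np.zeros(len(bins), dtype=np.int64)
    n_skipped = 0
    for v in cs.variants:
        idx = bins.bin_index(v.chrom, v.pos)
        if idx is None:
            n_skipped += 1
            continue
        counts[idx] += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} variant(s) on chromosomes outside the genome table were excluded",
            stacklevel=2,
        )
    return counts


@dataclass
class BinCounts:
    """Per-bin counts for the cohort (a) and the reference (b), plus
    genome-wide totals used to normalise the densities."""

    bins: GenomeBins
    per_bin_a: np.ndarray
    total_a: int
    per_bin_b: np.ndarray
    total_b: int

    @classmethod
    def from_callsets(cls, cohort: CallSet, reference: CallSet, bins: GenomeBins) -> "BinCounts":
        a = count_per_bin(cohort, bins)
        b = count_per_bin(reference, bins)
        return cls(bins=bins, per_bin_a=a, total_a=int(a.sum()), per_bin_b=b, total_b=int(b.sum()))


def fold_ratio(n_a_bin: int, total_a: int, n_b_bin: int, total_b: int) -> float:
    """Ratio of in-bin proportions; +inf when the reference proportion is
    zero but the cohort's is not, 0 when the cohort count is zero."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("genome-wide totals must be > 0")
    if n_a_bin == 0:
        return 0.0
    if n_b_bin == 0:
        return math.inf
    return (n_a_bin / total_a) / (n_b_bin / total_b)


def fisher_exact_greater(a, b, c, d):
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the hypergeometric tail P(X >= a) with the table's margins fixed.

    Returns a value in (0, 1]; ``a = 0`` gives exactly 1. Accepts equal-shape
    integer arrays for any argument and then returns an array of p-values.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    d = np.asarray(d)
    if min(a.min(), b.min(), c.min(), d.min()) < 0:
        raise ValueError("counts must be >= 0")
    if (a + b == 0).any() or (c + d == 0).any():
        raise ValueError("both rows must have positive margin")
    # P(X >= a) where X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c)
    p = stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class HotspotCall:
    """One bin's density comparison: fold, exact p, and the hotspot flag."""

    chrom: str
    start: int
    end: int
    n_cohort: int
    n_reference: int
    fold: float
    p: float
    is_hotspot: bool
    fdr: Optional[float] = None


def call_hotspots(
    counts: BinCounts,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
    with_fdr: bool = True,
) -> list[HotspotCall]:
    """Score every bin and flag hotspots (fold >= fold_min and p <= p_max,
    both inclusive).

    The optional Benjamini-Hochberg column is informational only and never
    gates hotspot status.
    """
    a = np.asarray(counts.per_bin_a, dtype=np.int64)
    b = np.asarray(counts.per_bin_b, dtype=np.int64)
    ta, tb = counts.total_a, counts.total_b
    if ta <= 0 or tb <= 0:
        raise ValueError("cannot call hotspots with an empty population")
    # one-sided Fisher per bin on the table [[a_i, ta - a_i], [b_i, tb - b_i]]
    p = np.asarray(fisher_exact_greater(a, ta - a, b, tb - b), dtype=float)
    fdr = stats.false_discovery_control(p) if with_fdr and len(p) else None
    out: list[HotspotCall] = []
    for i, (chrom, start, end) in enumerate(counts.bins.bins):
        fold = fold_ratio(int(a[i]), ta, int(b[i]), tb)
        pi = float(p[i])
        out.append(
            HotspotCall(
                chrom=chrom,
                start=start,
                end=end,
                n_cohort=int(a[i]),
                n_reference=int(b[i]),
                fold=fold,
                p=pi,
                is_hotspot=bool(fold >= fold_min and pi <= p_max),
                fdr=float(fdr[i]) if fdr is not None else None,
            )
        )
    return out


def associate_genes(
    hotspots: Sequence[HotspotCall],
    genes: FeatureSet,
    flank: int = DEFAULT_GENE_FLANK,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> dict[tuple[str, int, int], list[str]]:
    """Genes intersecting each hotspot expanded by ``flank`` bp on both
    sides (5 kb upstream/downstream by default), clipped at chromosome
    bounds. Only bins flagged as hotspots are reported.

    Boundary rule: a gene that exactly abuts the expanded window (its
    half-open end equals the window start, or vice versa) still counts as
    associated — the flank is a distance bound, so a gene ending exactly
    ``flank`` bp away is within it.
    """
    trees = genes.trees()
    names = genes.names or [f"{c}:{s}-{e}" for c, s, e in genes.intervals]
    out: dict[tuple[str, int, int], list[str]] = {}
    for h in hotspots:
        if not h.is_hotspot:
            continue
        lo = max(0, h.start - flank)
        hi = h.end + flank
        if chrom_sizes and h.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[h.chrom])
        hits = trees.get(h.chrom, None)
        # query [lo-1, hi+1) so that touching intervals (gene_end == lo or
        # gene_start == hi) are included
        idx = sorted({iv.data for iv in hits.overlap(lo - 1, hi + 1)}) if hits is not None else []
        out[(h.chrom, h.start, h.end)] = [names[i] for i in idx]
    return out


def write_hotspot_bed(
    hotspots: Sequence[HotspotCall],
    path: str | Path,
    genes: Optional[dict[tuple[str, int, int], list[str]]] = None,
) -> Path:
    """BED5+ output: chrom, start, end, name, -log10 p, fold, hotspot flag,
    associated genes (comma-joined)."""
    path = Path(path)
    lines = []
    for i, h in enumerate(hotspots):
        neglog = 999.0 if h.p == 0 else -math.log10(h.p)
        gene_list = ",".join((genes or {}).get((h.chrom, h.start, h.end), [])) or "."
        fold = "inf" if math.isinf(h.fold) else f"{h.fold:.4f}"
        lines.append(
            "\t".join(
                [
                    h.chrom,
                    str(h.start),
                    str(h.end),
                    f"bin_{i:05d}",
                    f"{neglog:.4f}",
                    fold,
                    "hotspot" if h.is_hotspot else ".",
                    gene_list,
                ]
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
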