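"""Cohort and per-sample quality-control metrics.

Het/Hom (heterozygous to homozygous-alternate calls per sample, expected
near 1.5 genome-wide), Ti/Tv (transition to transversion SNP ratio, expected
near 2.0 genome-wide), per-chromosome variant counts, singleton counts, and
the between-call-set concordance rate. The Het/Hom denominator counts
homozygous-alternate calls only: a call set of variant sites carries no
hom-ref information.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .core_io import CallSet, VarClass

__all__ = [
    "QCMetrics",
    "het_hom_ratio",
    "titv_ratio",
    "is_transition",
    "concordance_rate",
    "per_chrom_counts",
    "singleton_counts",
    "qc_report",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class QCMetrics:
    """Cohort-level QC summary."""

    het_hom: Optional[float]
    titv: Optional[float]
    per_chrom: dict[str, int]
    n_singletons: int


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in _TRANSITIONS


def het_hom_ratio(genotypes: Iterable[tuple[int, int] | None]) -> float:
    """(# het calls) / (# hom-alt calls) for one sample's genotypes.

    Missing genotypes are ignored. Undefined (raises) without any hom-alt
    call.
    """
    n_het = n_hom = 0
    for gt in genotypes:
        if gt is None:
            continue
        if gt[0] != gt[1]:
            n_het += 1
        elif gt[0] == gt[1] == 1:
            n_hom += 1
    if n_hom == 0:
        raise ValueError("Het/Hom undefined: no homozygous-alternate calls")
    return n_het / n_hom


def titv_ratio(snps: Iterable[tuple[str, str]]) -> float:
    """Transitions (A<->G, C<->T) over transversions for (ref, alt) pairs.

    Undefined (raises) without any transversion.
    """
    ti = tv = 0
    for ref, alt in snps:
        if is_transition(ref, alt):
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError("Ti/Tv undefined: no transversions")
    return ti / tv


def concordance_rate(observed: CallSet, other: CallSet) -> float:
    """100 x |shared (chrom,pos,ref,alt) keys| / |observed set|.

    Asymmetric by construction: the denominator is the observed set.
    """
    obs_keys = observed.keys
    if not obs_keys:
        raise ValueError("concordance undefined for an empty observed set")
    return 100.0 * len(obs_keys & other.keys) / len(obs_keys)


def per_chrom_counts(cs: CallSet) -> dict[str, int]:
    """Exact variant counts per chromosome; values sum to len(cs)."""
    return dict(Counter(v.chrom for v in cs.variants))


def singleton_counts(cs: CallSet) -> dict[int, int]:
    """Per-sample count of singletons: variants whose only carrier is that
    sample (a private mutation). Keys are sample indices."""
    out: Counter[int] = Counter()
    for v in cs.variants:
        carriers = [i for i, c in enumerate(v.per_sample) if c.carries_alt]
        if len(carriers) == 1:
            out[carriers[0]] += 1
    return dict(out)


def _sample_genotypes(cs: CallSet, i: int) -> list[tuple[int, int] | None]:
    return [v.per_sample[i].gt for v in cs.variants]


def qc_report(cs: CallSet, sample_names: Optional[list[str]] = None) -> pd.DataFrame:
    """Tab-ready QC table: one row per sample plus a cohort summary row.

    Columns: sample, n_variants (sites where the sample carries ALT),
    het_hom, titv (over the sample's carried SNPs), n_singletons. Ratios that
    are undefined for a sample (no hom-alt calls, no transversions) are NaN.
    """
    if sample_names is None:
        sample_names = [f"S{i + 1:03d}" for i in range(cs.n_samples)]
    singles = singleton_counts(cs)
    rows = []
    for i, name in enumerate(sample_names):
        gts = _sample_genotypes(cs, i)
        carried_snps = [
            (v.ref, v.alt)
            for v in cs.variants
            if v.var_class is VarClass.SNP and v.per_sample[i].carries_alt
        ]
        try:
            hh = het_hom_ratio(gts)
        except ValueError:
            hh = math.nan
        try:
            tt = titv_ratio(carried_snps)
        except ValueError:
            tt = math.nan
        rows.append(
            {
                "sample": name,
                "n_variants": sum(1 for v in cs.variants if v.per_sample[i].carries_alt),
                "het_hom": hh,
                "titv": tt,
                "n_singletons": singles.get(i, 0),
            }
        )
    snps = [(v.ref, v.alt) for v in cs.variants if v.var_class is VarClass.SNP]
    all_gts = [c.gt for v in cs.variants for c in v.per_sample]
    try:
        cohort_hh = het_hom_ratio(all_gts)
    except ValueError:
        cohort_hh = math.nan
    try:
        cohort_tt = titv_ratio(snps)
    except ValueError:
        cohort_tt = math.nan
    rows.append(
        {
            "sample": "COHORT",
            "n_variants": len(cs),
            "het_hom": cohort_hh,
            "titv": cohort_tt,
            "n_singletons": sum(singles.values()),
        }
    )
    return pd.DataFrame(rows)
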