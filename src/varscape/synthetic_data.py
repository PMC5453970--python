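"""Seeded synthetic cohort/reference data with the statistical structure the
pipeline assumes.

The generator emulates the *shape* of a deep-WGS case/control comparison:
two multi-sample call sets sharing a genome, per-sample GT/DP/GQ/AD fields,
a known-variant catalog controlling the novelty fraction, optional planted
high-density bins (cohort-side Poisson rate multipliers), and feature
interval sets with optional over-representation of novel variants. It does
not emulate haplotype structure, read-level errors, or locus-dependent
mutation rates; everything is drawn marginally.

Determinism: a single :class:`numpy.random.SeedSequence` keyed by the seed
is spawned into fixed per-stage substreams, so identical config + seed give
byte-identical fixture files and adding a stage never perturbs the output
of earlier stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotate import AnnotatedCallSet, AnnotatedVariant, Catalog
from .core_io import (
    CallSet,
    FeatureSet,
    SampleCall,
    VarClass,
    VariantRecord,
    write_bed,
    write_chrom_sizes,
    write_vcf,
)
from .hotspot import BinCounts, GenomeBins, make_bins

__all__ = [
    "FeatureConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "write_fixture",
    "simulate_bin_counts",
    "simulate_enrichment_experiment",
]

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class FeatureConfig:
    """One feature set's shape: interval count, mean length (bp), and the
    relative rate at which *novel* cohort variants land inside it (1.0 =
    no over-representation)."""

    n_intervals: int = 200
    mean_length: int = 2_000
    novel_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.novel_multiplier <= 0:
            raise ValueError("novel_multiplier must be > 0")


def _default_chroms() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


def _default_features() -> dict[str, FeatureConfig]:
    return {
        "ld_blocks": FeatureConfig(n_intervals=60, mean_length=20_000),
        "h3k4me3_peaks": FeatureConfig(n_intervals=400, mean_length=1_500),
        "dnase_sites": FeatureConfig(n_intervals=600, mean_length=600),
        "ctcf_sites": FeatureConfig(n_intervals=300, mean_length=400),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults: three 10 Mb chromosomes; background 1e-3 variants/bp per
    population; 48-sample cohort and reference; transition probability 2/3
    (expected Ti/Tv = 2.0); heterozygous fraction 0.6 among carriers
    (expected Het/Hom = 1.5); mean depth 38X; catalog membership 0.8
    (expected novelty rate 20%).
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chroms)
    bin_width: int = 1_000_000
    n_samples_cohort: int = 48
    n_samples_reference: int = 48
    background_rate: float = 1e-3
    planted_bins: tuple[tuple[int, float], ...] = ()
    catalog_prob: float = 0.8
    catalog_extra_fraction: float = 0.1
    transition_prob: float = 2 / 3
    indel_fraction: float = 0.1
    carrier_prob: float = 0.1
    het_fraction: float = 0.6
    depth_mean: float = 38.0
    gq_mean: float = 70.0
    qual_mean: float = 150.0
    feature_config: dict[str, FeatureConfig] = field(default_factory=_default_features)
    n_rp_intervals: int = 800
    rp_interval_length: int = 1_000
    n_genes: int = 300
    gene_length: int = 20_000
    n_sv: int = 150
    sv_catalog_prob: float = 0.7

    def __post_init__(self) -> None:
        for p in (self.catalog_prob, self.transition_prob, self.indel_fraction,
                  self.carrier_prob, self.het_fraction, self.sv_catalog_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for _, mult in self.planted_bins:
            if mult <= 0:
                raise ValueError("planted multipliers must be > 0")

    def bins(self) -> GenomeBins:
        return make_bins(self.chrom_sizes, self.bin_width)


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the generating truth."""

    cohort: CallSet
    reference: CallSet
    cohort_sv: CallSet
    catalog: Catalog
    feature_sets: dict[str, FeatureSet]
    rp_track: FeatureSet
    genes: FeatureSet
    truth: dict
    chrom_sizes: dict[str, int] = field(default_factory=dict)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["cohort_sites", "reference_sites", "alleles", "genotypes",
             "catalog", "features", "genes", "sv", "rp", "qual"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _draw_sites(
    rng: np.random.Generator,
    bins: GenomeBins,
    rate: float,
    multipliers: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Per-bin Poisson site counts with uniform unique positions in-bin.

    Returns chromosome labels and 1-based positions, sorted by bin order.
    """
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for i, (chrom, start, end) in enumerate(bins.bins):
        width = end - start
        count = rng.poisson(rate * width * multipliers[i])
        count = min(count, width)
        offsets = rng.choice(width, size=count, replace=False)
        offsets.sort()
        chroms.extend([chrom] * count)
        positions.append(start + offsets + 1)  # 1-based
    return chroms, (np.concatenate(positions) if positions else np.array([], dtype=np.int64))


def _snp_alleles(rng: np.random.Generator, n: int, transition_prob: float):
    refs = rng.choice(_BASES, size=n)
    is_ti = rng.random(n) < transition_prob
    alts = np.empty(n, dtype=object)
    pick = rng.integers(0, 2, size=n)
    for i in range(n):
        r = refs[i]
        alts[i] = _TRANSITION[r] if is_ti[i] else _TRANSVERSIONS[r][pick[i]]
    return refs, alts


def _indel_alleles(rng: np.random.Generator, n: int):
    """1-10 bp insertions/deletions with geometric-ish length distribution."""
    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    lengths = np.minimum(rng.geometric(0.5, size=n), 10)
    is_ins = rng.random(n) < 0.5
    for i in range(n):
        anchor = rng.choice(_BASES)
        tail = "".join(rng.choice(_BASES, size=lengths[i]))
        if is_ins[i]:
            refs[i], alts[i] = anchor, anchor + tail
        else:
            refs[i], alts[i] = anchor + tail, anchor
    return refs, alts


def _genotype_fields(
    rng: np.random.Generator, cfg: SyntheticConfig, n_samples: int
) -> tuple[SampleCall, ...]:
    """Per-sample GT/DP/GQ/AD for one variant; at least one carrier."""
    k = max(1, rng.binomial(n_samples, cfg.carrier_prob))
    carriers = set(rng.choice(n_samples, size=k, replace=False).tolist())
    dp = rng.poisson(cfg.depth_mean, size=n_samples)
    gq = np.minimum(99, rng.poisson(cfg.gq_mean, size=n_samples))
    calls = []
    for s in range(n_samples):
        d = int(dp[s])
        if s not in carriers:
            calls.append(SampleCall(gt=(0, 0), dp=d, gq=int(gq[s]), ad=(d, 0)))
        elif rng.random() < cfg.het_fraction:
            alt_reads = rng.binomial(d, 0.5) if d else 0
            calls.append(SampleCall(gt=(0, 1), dp=d, gq=int(gq[s]), ad=(d - alt_reads, alt_reads)))
        else:
            ref_reads = rng.binomial(d, 0.03) if d else 0
            calls.append(SampleCall(gt=(1, 1), dp=d, gq=int(gq[s]), ad=(ref_reads, d - ref_reads)))
    return tuple(calls)


def _make_features(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> dict[str, FeatureSet]:
    chrom_names = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    out: dict[str, FeatureSet] = {}
    for name, fc in cfg.feature_config.items():
        intervals = []
        which = rng.choice(len(chrom_names), size=fc.n_intervals, p=probs)
        lengths = np.maximum(100, rng.exponential(fc.mean_length, size=fc.n_intervals).astype(int))
        for j in range(fc.n_intervals):
            chrom = chrom_names[which[j]]
            size = cfg.chrom_sizes[chrom]
            length = int(min(lengths[j], size - 1))
            start = int(rng.integers(0, size - length))
            intervals.append((chrom, start, start + length))
        out[name] = FeatureSet(name=name, intervals=intervals)
    return out


def _relocate_novel(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    chroms: list[str],
    positions: np.ndarray,
    novel: np.ndarray,
    feature_sets: dict[str, FeatureSet],
) -> tuple[list[str], np.ndarray]:
    """Re-place novel variants so they fall inside multiplier>1 feature sets
    at the configured relative rate. Known variants keep uniform placement."""
    boosted = [(name, fc.novel_multiplier) for name, fc in cfg.feature_config.items()
               if fc.novel_multiplier != 1.0]
    if not boosted:
        return chroms, positions
    # union of boosted intervals (single multiplier assumed: take the max)
    mult = max(m for _, m in boosted)
    intervals = [iv for name, _ in boosted for iv in feature_sets[name].intervals]
    spans = np.array([e - s for _, s, e in intervals], dtype=float)
    total_span = spans.sum()
    genome = sum(cfg.chrom_sizes.values())
    f = total_span / genome
    p_in = mult * f / (mult * f + (1.0 - f))
    chroms = list(chroms)
    positions = positions.copy()
    idx_novel = np.flatnonzero(novel)
    go_in = rng.random(idx_novel.size) < p_in
    span_probs = spans / total_span
    for j, i in enumerate(idx_novel):
        if go_in[j]:
            k = rng.choice(len(intervals), p=span_probs)
            chrom, start, end = intervals[k]
            chroms[i] = chrom
            positions[i] = int(rng.integers(start, end)) + 1
        # not re-placed otherwise: uniform background already approximates
        # "outside" placement since f is small relative to the genome
    return chroms, positions


def _build_records(
    cfg: SyntheticConfig,
    chroms: list[str],
    positions: np.ndarray,
    rng_alleles: np.random.Generator,
    rng_geno: np.random.Generator,
    rng_qual: np.random.Generator,
    n_samples: int,
) -> list[VariantRecord]:
    n = len(chroms)
    is_indel = rng_alleles.random(n) < cfg.indel_fraction
    n_snp = int((~is_indel).sum())
    n_ind = n - n_snp
    snp_ref, snp_alt = _snp_alleles(rng_alleles, n_snp, cfg.transition_prob)
    ind_ref, ind_alt = _indel_alleles(rng_alleles, n_ind)
    qual = rng_qual.gamma(4.0, cfg.qual_mean / 4.0, size=n)
    records = []
    i_snp = i_ind = 0
    for i in range(n):
        if is_indel[i]:
            ref, alt = str(ind_ref[i_ind]), str(ind_alt[i_ind])
            vclass = VarClass.INSERTION if len(alt) > len(ref) else VarClass.DELETION
            i_ind += 1
        else:
            ref, alt = str(snp_ref[i_snp]), str(snp_alt[i_snp])
            vclass = VarClass.SNP
            i_snp += 1
        records.append(
            VariantRecord(
                chrom=chroms[i],
                pos=int(positions[i]),
                ref=ref,
                alt=alt,
                qual=round(float(qual[i]), 2),
                per_sample=_genotype_fields(rng_geno, cfg, n_samples),
                var_class=vclass,
            )
        )
    return records


def _make_svs(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> tuple[list[VariantRecord], list[tuple[str, int, int, str]]]:
    chrom_names = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    types = rng.choice(["DEL", "DUP", "INV"], size=cfg.n_sv, p=[0.7, 0.15, 0.15])
    records: list[VariantRecord] = []
    catalog_entries: list[tuple[str, int, int, str]] = []
    for j in range(cfg.n_sv):
        chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
        size = cfg.chrom_sizes[chrom]
        length = int(np.clip(rng.lognormal(math.log(5_000), 1.0), 100, size // 10))
        start0 = int(rng.integers(0, size - length))
        pos = start0 + 1
        k = max(1, rng.binomial(cfg.n_samples_cohort, 0.2))
        carriers = set(rng.choice(cfg.n_samples_cohort, size=k, replace=False).tolist())
        calls = tuple(
            SampleCall(
                gt=(0, 1) if s in carriers else (0, 0),
                dp=int(rng.poisson(cfg.depth_mean)),
                gq=int(min(99, rng.poisson(cfg.gq_mean))),
                ad=None,
            )
            for s in range(cfg.n_samples_cohort)
        )
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="N",
                alt=f"<{types[j]}>",
                qual=round(float(rng.gamma(4.0, cfg.qual_mean / 4.0)), 2),
                per_sample=calls,
                var_class=VarClass["SV_" + types[j]],
                sv_end=start0 + length,
            )
        )
        if rng.random() < cfg.sv_catalog_prob:
            # jittered same-type entry with reciprocal overlap well above 0.5
            shift = int(rng.integers(-length // 10, length // 10 + 1))
            scale = rng.uniform(0.9, 1.1)
            new_start = max(0, start0 + shift)
            new_end = min(size, new_start + max(100, int(length * scale)))
            catalog_entries.append((chrom, new_start, new_end, str(types[j])))
    return records, catalog_entries


def generate(cfg: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Generate one complete synthetic dataset.

    Cohort site counts per bin are Poisson(background_rate x bin width x
    multiplier); the reference population always has multiplier 1. Catalog
    membership of each cohort variant is Bernoulli(catalog_prob), so the
    expected novelty rate is 100 x (1 - catalog_prob)%.
    """
    rngs = _substreams(cfg.seed)
    bins = cfg.bins()
    mult = np.ones(len(bins))
    for idx, m in cfg.planted_bins:
        if not 0 <= idx < len(bins):
            raise ValueError(f"planted bin index {idx} outside the genome's {len(bins)} bins")
        mult[idx] = m

    feature_sets = _make_features(rngs["features"], cfg)

    co_chroms, co_pos = _draw_sites(rngs["cohort_sites"], bins, cfg.background_rate, mult)
    known = rngs["catalog"].random(len(co_chroms)) < cfg.catalog_prob
    co_chroms, co_pos = _relocate_novel(
        rngs["cohort_sites"], cfg, co_chroms, co_pos, ~known, feature_sets
    )
    cohort_variants = _build_records(
        cfg, co_chroms, co_pos, rngs["alleles"], rngs["genotypes"], rngs["qual"],
        cfg.n_samples_cohort,
    )
    cohort = CallSet("cohort", cfg.n_samples_cohort, cohort_variants)

    ref_chroms, ref_pos = _draw_sites(
        rngs["reference_sites"], bins, cfg.background_rate, np.ones(len(bins))
    )
    reference_variants = _build_records(
        cfg, ref_chroms, ref_pos, rngs["alleles"], rngs["genotypes"], rngs["qual"],
        cfg.n_samples_reference,
    )
    reference = CallSet("reference", cfg.n_samples_reference, reference_variants)

    entries = {v.key for v, k in zip(cohort_variants, known) if k}
    # decoy entries absent from the call set, so the catalog is not merely a
    # subset of observed variants
    rng_cat = rngs["catalog"]
    n_extra = int(cfg.catalog_extra_fraction * len(cohort_variants))
    chrom_names = list(cfg.chrom_sizes)
    for _ in range(n_extra):
        chrom = chrom_names[rng_cat.integers(0, len(chrom_names))]
        pos = int(rng_cat.integers(1, cfg.chrom_sizes[chrom] + 1))
        ref, alt = (str(x) for x in rng_cat.choice(_BASES, size=2, replace=False))
        entries.add((chrom, pos, ref, alt))

    sv_records, sv_catalog = _make_svs(rngs["sv"], cfg)
    cohort_sv = CallSet("cohort_sv", cfg.n_samples_cohort, sv_records)
    catalog = Catalog(entries=entries, sv_entries=sv_catalog)

    rng_rp = rngs["rp"]
    rp_intervals = []
    rp_scores = []
    sizes = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(cfg.n_rp_intervals):
        chrom = chrom_names[rng_rp.choice(len(chrom_names), p=probs)]
        start = int(rng_rp.integers(0, cfg.chrom_sizes[chrom] - cfg.rp_interval_length))
        rp_intervals.append((chrom, start, start + cfg.rp_interval_length))
        rp_scores.append(round(float(rng_rp.beta(0.8, 1.2)), 4))
    rp_track = FeatureSet(name="rp_track", intervals=rp_intervals, scores=rp_scores)

    rng_gene = rngs["genes"]
    gene_intervals = []
    gene_names = []
    for g in range(cfg.n_genes):
        chrom = chrom_names[rng_gene.choice(len(chrom_names), p=probs)]
        start = int(rng_gene.integers(0, cfg.chrom_sizes[chrom] - cfg.gene_length))
        gene_intervals.append((chrom, start, start + cfg.gene_length))
        gene_names.append(f"GENE{g + 1:04d}")
    genes = FeatureSet(name="genes", intervals=gene_intervals, names=gene_names)

    truth = {
        "seed": cfg.seed,
        "bin_width": cfg.bin_width,
        "planted_bins": [
            {
                "index": int(idx),
                "chrom": bins.bins[idx][0],
                "start": bins.bins[idx][1],
                "end": bins.bins[idx][2],
                "multiplier": float(m),
            }
            for idx, m in cfg.planted_bins
        ],
        "catalog_prob": cfg.catalog_prob,
        "expected_novelty_rate_pct": 100.0 * (1.0 - cfg.catalog_prob),
        "feature_multipliers": {
            name: fc.novel_multiplier for name, fc in cfg.feature_config.items()
        },
    }
    return SyntheticDataset(
        cohort=cohort,
        reference=reference,
        cohort_sv=cohort_sv,
        catalog=catalog,
        feature_sets=feature_sets,
        rp_track=rp_track,
        genes=genes,
        truth=truth,
        chrom_sizes=dict(cfg.chrom_sizes),
    )


def write_fixture(ds: SyntheticDataset, directory: str | Path,
                  chrom_sizes: Optional[dict[str, int]] = None) -> dict[str, Path]:
    """Write the dataset as the plain-text formats the readers consume.

    Returns a name -> path map. The files round-trip losslessly through
    the core readers (equal variant keys, intervals, and scores).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if chrom_sizes is None:
        chrom_sizes = ds.chrom_sizes
    paths: dict[str, Path] = {}
    paths["cohort_vcf"] = write_vcf(ds.cohort, directory / "cohort.vcf", chrom_sizes or None)
    paths["reference_vcf"] = write_vcf(ds.reference, directory / "reference.vcf", chrom_sizes or None)
    paths["cohort_sv_vcf"] = write_vcf(ds.cohort_sv, directory / "cohort_sv.vcf", chrom_sizes or None)
    cat_path = directory / "catalog.tsv"
    with open(cat_path, "w") as fh:
        for chrom, pos, ref, alt in sorted(ds.catalog.entries):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    paths["catalog_tsv"] = cat_path
    svcat_path = directory / "sv_catalog.bed"
    with open(svcat_path, "w") as fh:
        for chrom, start, end, svtype in ds.catalog.sv_entries:
            fh.write(f"{chrom}\t{start}\t{end}\t{svtype}\n")
    paths["sv_catalog_bed"] = svcat_path
    for name, fs in ds.feature_sets.items():
        paths[f"features_{name}"] = write_bed(fs, directory / f"{name}.bed")
    paths["rp_bed"] = write_bed(ds.rp_track, directory / "rp_track.bed")
    paths["genes_bed"] = write_bed(ds.genes, directory / "genes.bed")
    if chrom_sizes:
        paths["chrom_sizes"] = write_chrom_sizes(chrom_sizes, directory / "chrom_sizes.tsv")
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(ds.truth, indent=2) + "\n")
    paths["truth_json"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# lightweight calibration helpers (counts-level, no genotype simulation)
# ---------------------------------------------------------------------------

def simulate_bin_counts(cfg: SyntheticConfig, seed: Optional[int] = None) -> BinCounts:
    """Counts-only analogue of :func:`generate`: per-bin Poisson draws for
    both populations without simulating individual variants. Used for
    repeated-calibration experiments where only the per-bin counts matter.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bins = cfg.bins()
    mult = np.ones(len(bins))
    for idx, m in cfg.planted_bins:
        mult[idx] = m
    widths = np.array([e - s for _, s, e in bins.bins], dtype=float)
    a = rng.poisson(cfg.background_rate * widths * mult)
    b = rng.poisson(cfg.background_rate * widths)
    return BinCounts(bins=bins, per_bin_a=a, total_a=int(a.sum()),
                     per_bin_b=b, total_b=int(b.sum()))


def simulate_enrichment_experiment(
    n_per_class: int = 500,
    feature_fraction: float = 0.2,
    relative_rate: float = 1.0,
    seed: int = 0,
) -> tuple[AnnotatedCallSet, FeatureSet]:
    """Minimal annotated call set + single feature block for enrichment
    calibration.

    Known variants land inside the feature region with probability equal to
    its genomic fraction; novel variants land inside at ``relative_rate``
    times the background odds. ``relative_rate = 1`` is the null.
    """
    if not 0.0 < feature_fraction < 1.0:
        raise ValueError("feature_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genome = 1_000_000
    boundary = int(feature_fraction * genome)
    fs = FeatureSet(name="block", intervals=[("chr1", 0, boundary)])
    f = feature_fraction
    p_in_novel = relative_rate * f / (relative_rate * f + (1 - f))
    variants = []
    for is_novel in (True, False):
        p_in = p_in_novel if is_novel else f
        inside = rng.random(n_per_class) < p_in
        for ins in inside:
            pos0 = int(rng.integers(0, boundary)) if ins else int(rng.integers(boundary, genome))
            base = VariantRecord(
                chrom="chr1", pos=pos0 + 1, ref="A", alt="G", qual=100.0,
                per_sample=(SampleCall(gt=(0, 1), dp=30, gq=60, ad=(15, 15)),),
                var_class=VarClass.SNP,
            )
            variants.append(AnnotatedVariant(base=base, novel=is_novel, aaf=0.5,
                                             freq_class="COMMON", n_samples_present=1))
    return AnnotatedCallSet(label="sim", n_samples=1, variants=variants), fs
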