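# Methods

## Scope and model

`varscape` analyses two multi-sample call sets sharing one genome — a
"cohort" (the study population) and a "reference" (a public panel treated
as healthy background) — together with a known-variant catalog, feature
interval sets, gene models, and a scored regulatory-potential (RP) track.
The pipeline stages are hard filtering, novelty annotation, QC, binned
density-hotspot detection, and feature enrichment. Each stage is a pure
function over explicit containers (`CallSet`, `Catalog`, `FeatureSet`,
`BinCounts`), so stages compose in any order and every CLI subcommand is a
thin wrapper over one library call.

Coordinates: VCF records are 1-based and stay 1-based in memory; all
interval arithmetic is 0-based half-open. The conversion happens exactly
once, where a variant at 1-based position `p` is placed at coordinate
`p - 1`. Indels and SVs are anchored by their leftmost affected base for
feature membership; SVs additionally carry a 1-based end used for
reciprocal-overlap matching.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_dp` / `min_gq` / `min_qual` / `min_mrr` | 20 / 20 / 30 / 0.2 | hard filters; all inclusive (`>=`) |
| bin width | 1,000,000 bp | hotspot scan resolution |
| `fold_min` / `p_max` | 1.5 / 0.05 | hotspot call thresholds, both inclusive |
| gene flank | 5,000 bp | hotspot-to-gene association distance |
| common AAF | 0.05 (strict `>`) | common vs low-frequency class boundary |
| common-SV fraction | 1/3 (ceiling) | 16-of-48 carrier rule |
| SV reciprocal overlap | 0.5 | catalog match threshold for SV novelty |
| `rp_min` | 0.5 (inclusive) | high-RP score boundary |

Filter semantics for multi-sample records: the per-sample criteria (DP,
GQ, MRR) are satisfied if **any one** sample call passes them all; site
quality applies once per record. This is the most permissive reading
consistent with producing a cohort-level variant list — a variant
confidently called in one sample belongs in the cohort's catalog even if
other samples covered it poorly. MRR applies to heterozygous calls only:
a hom-alt call legitimately has near-zero reference reads, so an MRR
criterion there would reject essentially all true homozygous calls.
Missing genotypes (`./.`) are excluded from every per-sample computation,
including the AAF denominator.

Size classes: SNP (equal length-1 alleles), indel (length difference
1–50 bp), SV (> 50 bp, or any record tagged DEL/DUP/INV). The 50 bp
boundary keeps the indel definition primary; sequence-resolved events just
past it are promoted to the SV classes (long deletion → SV_DEL, long
insertion → SV_DUP, the closest match in the DEL/DUP/INV vocabulary).

## Statistical procedures

**Fisher exact test.** One-sided ("greater"): `p = P(X >= a)` for
`X ~ Hypergeometric(N, K, n)` with the observed table's margins, computed
via `scipy.stats.hypergeom.sf`. One-sided because both uses are
directional by construction — a hotspot is defined as *excess* density
and enrichment as *over*-representation. The test suite checks agreement
with an exact integer enumeration over every 2x2 table with row margins
<= 60 (about 3.6 million tables) to 1e-12 absolute.

**Hotspots.** The fold statistic is the ratio of in-bin proportions; a
reference-empty bin with cohort variants gives fold = +inf (still
eligible), and a cohort-empty bin gives 0. Terminal partial bins are
binned and tested like full bins. No multiple-testing correction gates
hotspot status — each bin is tested marginally — but a Benjamini–Hochberg
column (`scipy.stats.false_discovery_control`) is emitted for the reader.
Gene association counts a gene whose interval touches the hotspot
expanded by the flank, including exact abutment: the flank is a distance
bound, so a gene ending exactly 5 kb away is within it.

**Enrichment.** RP score lookup takes the covering interval's score, with
the maximum across overlapping scored intervals; variants without RP
coverage are excluded from the RP threshold test rather than imputed.
Rank comparisons of per-variant metrics use `scipy.stats.mannwhitneyu`:
exact enumeration for tie-free samples up to n = 20 per group, otherwise
the tie-corrected normal approximation.

**QC.** Het/Hom divides heterozygous by homozygous-alternate calls; a
variant-site call set carries no hom-ref information, so hom-ref never
enters the denominator. Concordance between call sets is
`100 x |shared keys| / |observed set|` — deliberately asymmetric, with
the identity `conc(A,B)·|A| = conc(B,A)·|B|`. Singletons are variants
with exactly one carrier sample.

## The synthetic-data generator

The generator emulates the data *shape* the analysis consumes, not the
biology that produced it: per-bin Poisson site counts (rate =
`background_rate` x bin width x multiplier; reference always multiplier
1), uniform unique positions within each bin, Bernoulli catalog
membership, marginal genotype fields per sample, and uniform feature
intervals. Defaults are the study conditions the pipeline is meant for:

- three 10 Mb chromosomes; background 1e-3 variants/bp per population
  (~1,000 variants per 1 Mb bin per population);
- 48-sample cohort (the cohort size these analyses target) with mean
  depth 38X; the reference also gets 48 simulated samples because no
  analysis stage reads reference genotypes — only reference site
  density — so a 2,504-sample panel would add cost without information;
- transition probability 2/3, so expected Ti/Tv = 2.0; het fraction 0.6
  among carriers, so expected Het/Hom = 0.6/0.4 = 1.5;
- catalog membership probability 0.8 (expected novelty 20%, mid-range
  of the 11–27% novelty rates typical of deep-WGS call sets);
- carrier probability 0.1 per sample, putting the AAF distribution
  astride the 5% common/low boundary;
- SVs: 150 records, type mix 70/15/15 DEL/DUP/INV, log-normal lengths
  around 5 kb; catalog entries are jittered same-type copies (shift and
  rescale within 10%), so catalog membership survives the 0.5
  reciprocal-overlap rule by construction.

Feature sets may declare a `novel_multiplier`: novel cohort variants are
then re-placed inside that set at `m·f / (m·f + 1 - f)` odds (f = the
set's genomic fraction), giving a planted relative rate of exactly *m*
for the enrichment test to detect.

Determinism: one `SeedSequence` per dataset, spawned into fixed per-stage
substreams; identical config + seed give byte-identical fixture files,
and adding a generation stage cannot perturb earlier stages.

What the generator does **not** emulate — and hence what green tests do
not show about real data: linkage disequilibrium and haplotype sharing,
locus-dependent mutation and error rates, batch effects between
sequencing runs, population structure, and reference-bias artefacts. In
particular the between-batch concordance of a real replicated cohort
(~70–80%) arises from shared subjects re-sequenced, which a marginal
site simulator cannot produce; the acceptance script instead reports
concordance between two 80% subsamples of one call set, whose expected
value (80%) follows from the subsampling alone.

## Calibration experiments and problem sizes

The acceptance checks run at sizes chosen to keep the whole suite within
a desktop-scale run while leaving no ambiguity in the outcome:

- **Hotspot recovery**: full generation at the default conditions with
  three bins planted at multiplier 3. With ~1,000 background variants
  per bin, a fold threshold of 1.5 sits ~9 standard errors from the
  null, so recovery must be exact (all three planted, zero false
  positives).
- **Null calibration of the hotspot caller**: 1,000 seeded counts-only
  replicates (the per-bin Poisson draws are the only thing the caller
  sees, so genotype simulation would add runtime, not information); the
  per-bin flag rate must not exceed 0.05 + 3 binomial SE. At this depth
  the observed rate is ~0, reflecting the conjunction of the fold and
  significance criteria.
- **Enrichment calibration**: 1,000 seeded replicates at 500 variants
  per class with the feature region covering 0.2 of the genome (a
  fraction fixed once for these experiments; large enough that a 3-fold
  planted signal is unambiguous at n = 500). Null p-values must be
  super-uniform at every alpha checked — guaranteed in expectation
  because the exact test is conservative — and power at alpha = 0.001
  under the planted 3-fold signal must be >= 99%.

## Known limitations

- Multi-allelic records are rejected, not decomposed; split them
  upstream (`bcftools norm`) first.
- SV novelty matching uses simple same-type reciprocal overlap; no
  breakpoint-uncertainty model.
- The VCF writer emits the fixed GT:DP:GQ:AD layout the pipeline uses;
  arbitrary FORMAT fields are not round-tripped.
- p-values from the vectorised hypergeometric survival function are
  accurate to ~1e-15 absolute; for astronomically small tails the
  relative error grows, which matters only to the displayed magnitude,
  never to threshold decisions at p <= 0.05.
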