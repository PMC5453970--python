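"""Test novel variants for enrichment in regulatory feature sets.

Plants novel variants inside DNase hypersensitivity sites at 4x the
background odds, then tests every (variant type, feature set) pair with a
one-sided Fisher exact test, and runs the regulatory-potential score
threshold test over LD blocks.
"""

import varscape as vs

cfg = vs.SyntheticConfig(
    seed=4,
    chrom_sizes={"chr1": 4_000_000},
    background_rate=1e-3,
    feature_config={
        "dnase_sites": vs.FeatureConfig(n_intervals=300, mean_length=2_000,
                                        novel_multiplier=4.0),
        "ctcf_sites": vs.FeatureConfig(n_intervals=150, mean_length=500),
    },
)
ds = vs.generate(cfg)
ann = vs.mark_novelty(ds.cohort, ds.catalog)

report = vs.feature_enrichment_report(ann, list(ds.feature_sets.values()))
print(report.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print()

ld_blocks = vs.FeatureSet(name="ld_blocks", intervals=[("chr1", 0, 800_000)])
res = vs.rp_threshold_enrichment(ds.cohort, ds.rp_track, ld_blocks, rp_min=0.5)
print(f"RP >= 0.5 within LD blocks: fold {res.fold:.2f}, p {res.p:.3g} "
      f"(table {res.a}/{res.b}/{res.c}/{res.d})")
print()
print("Small p-values for dnase_sites reflect the planted 4x placement of "
      "novel variants; ctcf_sites has no planted signal, so its p-values "
      "stay unremarkable. The RP test asks whether variants inside LD "
      "blocks carry high regulatory-potential scores more often than "
      "variants outside; this generator assigns scores independently of "
      "position, so any apparent RP enrichment here is sampling noise "
      "rather than planted signal.")
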