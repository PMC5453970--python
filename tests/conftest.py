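import pytest

from varscape import (
    CallSet,
    SampleCall,
    SyntheticConfig,
    VariantRecord,
    classify_variant,
    generate,
)


def make_variant(chrom="chr1", pos=100, ref="A", alt="G", qual=100.0, calls=None,
                 var_class=None, sv_end=None):
    if calls is None:
        calls = [SampleCall(gt=(0, 1), dp=30, gq=60, ad=(15, 15))]
    if var_class is None:
        var_class = classify_variant(ref, alt)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                         per_sample=tuple(calls), var_class=var_class, sv_end=sv_end)


@pytest.fixture
def toy_callset():
    """Three samples, five variants with a known genotype layout."""
    def calls(*gts):
        return [SampleCall(gt=g, dp=30, gq=60, ad=(15, 15) if g == (0, 1) else (0, 30))
                for g in gts]

    variants = [
        make_variant(pos=100, ref="A", alt="G", calls=calls((0, 1), (0, 1), (1, 1))),
        make_variant(pos=200, ref="C", alt="T", calls=calls((0, 1), (0, 0), (0, 0))),
        make_variant(pos=300, ref="A", alt="C", calls=calls((1, 1), (0, 1), (0, 0))),
        make_variant(chrom="chr2", pos=150, ref="G", alt="A",
                     calls=calls((0, 1), (1, 1), (0, 1))),
        make_variant(chrom="chr2", pos=250, ref="T", alt="A",
                     calls=calls((0, 0), (0, 0), (0, 1))),
    ]
    return CallSet(label="toy", n_samples=3, variants=variants)


SMALL_CONFIG = SyntheticConfig(
    seed=11,
    chrom_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
    background_rate=3e-4,
    n_samples_cohort=6,
    n_samples_reference=6,
    n_sv=40,
    n_rp_intervals=100,
    n_genes=40,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across test modules."""
    return generate(SMALL_CONFIG)
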