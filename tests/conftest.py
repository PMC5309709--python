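import pytest

from strseq.simulate import (FragmentationModel, StutterModel,
                             build_synthetic_panel, default_allele_freqs,
                             draw_individual_genotypes, generate_read_pairs)


@pytest.fixture(scope="session")
def small_panel():
    """A 6-locus synthetic panel shared (read-only) across tests."""
    return build_synthetic_panel(6, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return draw_individual_genotypes(small_panel, default_allele_freqs(small_panel),
                                     seed=12, name="S1")


def make_reads(panel, truth, coverage=40, stutter=None, frag=None, seed=13,
               **kw):
    kw.setdefault("base_error", 0.0)
    return generate_read_pairs(
        truth, panel, coverage=coverage,
        stutter=stutter or StutterModel.off(),
        frag=frag or FragmentationModel(mode="crispr", jitter_sd=0.0,
                                        on_target_prob=1.0),
        seed=seed, **kw)


@pytest.fixture()
def clean_reads(small_panel, small_truth):
    pairs, truths = make_reads(small_panel, small_truth)
    return pairs, truths
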