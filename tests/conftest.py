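import hypothesis
import pytest

from grainpep import seq_io, synthetic

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=100,
    deadline=None,
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grain_set():
    """The shipped default synthetic scenario with planted ground truth."""
    return synthetic.generate_grain_set(
        n_grains=4, gpts_per_grain=2, n_seqs=20, sub_rate=0.1, seed=20210923)


@pytest.fixture()
def default_config(default_grain_set):
    _, truth = default_grain_set
    return seq_io.load_config(None, gpt_abundance=truth.gpt_abundance,
                              seed=20210923)
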