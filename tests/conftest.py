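import pytest

from cohesim import make_toy_genome_pair


@pytest.fixture(scope="session")
def tiny_pair():
    """Small genome pair (2 x 2 kb experimental, 1 x 1.5 kb calibration)."""
    pair = make_toy_genome_pair(
        n_chrom=2, chrom_length=2000, n_cal_chrom=1, cal_length=1500,
        read_length=20, seed=11,
    )
    pair.validate()
    return pair
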