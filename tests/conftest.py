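import numpy as np
import pytest

from repeatmap import Genome

# The 16-base worked example threaded through the whole suite.
TOY_SEQ = "atcgaaatatccatcc"


@pytest.fixture
def toy():
    return Genome.from_dict({"t": TOY_SEQ})


def random_genome(rng: np.random.Generator, length: int, alphabet: str = "ACGT",
                  n_prob: float = 0.0) -> Genome:
    """Random single-contig genome; low-complexity alphabets make repeats dense."""
    chars = rng.choice(list(alphabet), size=length)
    if n_prob > 0:
        chars[rng.random(length) < n_prob] = "N"
    return Genome.from_dict({"r": "".join(chars)})
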