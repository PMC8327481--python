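import numpy as np
import pytest

from itrscan import SimulationConfig, simulate_dataset
from itrscan.genome_scan import CORE_MOTIF, ItrHit, mismatch_profile


def random_genome(seed: int, length: int, n_frac: float = 0.0) -> str:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=length)]
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        seq[mask] = ord("N")
    return seq.tobytes().decode()


def make_hit(chrom: str, start: int, strand: str = "+", seq: str = CORE_MOTIF) -> ItrHit:
    """A well-formed ItrHit at a given locus with the given oriented sequence."""
    profile = mismatch_profile(seq, CORE_MOTIF)
    return ItrHit(chrom, start, start + len(seq), strand, len(profile), profile, seq)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(), seed=11)
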