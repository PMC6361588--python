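import numpy as np
import pytest

from chipwin import features, synthetic
from chipwin.peakcalling import TagTrack


@pytest.fixture(scope="session")
def pwm():
    return features.ctcf_like_pwm()


@pytest.fixture(scope="session")
def small_pwm():
    """Informative 8-mer, small enough for exhaustive 4^8 enumeration."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 40, size=(8, 4)).astype(float)
    counts[np.arange(8), rng.integers(0, 4, size=8)] += 120
    return features.PWM.from_counts(counts, name="test8")


@pytest.fixture(scope="session")
def planted_genome(pwm):
    cfg = synthetic.SimulationConfig(seed=7, n_sites=20)
    genome = synthetic.generate_genome(1, 300_000, 0.42, seed=7)
    genome, sites = synthetic.plant_sites(genome, pwm, cfg)
    return genome, sites, cfg


def random_track(rng, chrom_lengths, mean=2.0):
    return TagTrack({c: rng.poisson(mean, size=L).astype(np.int64)
                     for c, L in chrom_lengths.items()})
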