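import random

import pytest
from hypothesis import HealthCheck, settings

from circconsensus.harmonize import CircRNA
from circconsensus.io_formats import METHODS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_circrnas(rng: random.Random, n: int, n_samples: int = 4) -> list[CircRNA]:
    """In-memory random harmonized circRNAs with evidence from the four methods."""
    samples = [f"s{i}" for i in range(1, n_samples + 1)]
    out = []
    used = set()
    for _ in range(n):
        while True:
            key = (str(rng.randint(1, 3)), rng.randint(0, 10_000) * 10, 0)
            key = (key[0], key[1], key[1] + rng.randint(100, 5000))
            if key not in used:
                used.add(key)
                break
        n_entries = rng.randint(1, 6)
        evidence = {}
        for _ in range(n_entries):
            evidence[(rng.choice(samples), rng.choice(METHODS))] = rng.randint(1, 20)
        out.append(
            CircRNA(
                chrom=key[0],
                start=key[1],
                end=key[2],
                strand=rng.choice("+-"),
                evidence=evidence,
            )
        )
    return out


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A generated synthetic dataset shared across tests (fixed seed)."""
    from circconsensus.fixtures import FixtureSpec, generate

    out = tmp_path_factory.mktemp("fixture")
    return generate(FixtureSpec(seed=11, n_genes=60, n_circrnas=80, n_samples=4), out)
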