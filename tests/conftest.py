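import random

import pytest

from gts.config import DEFAULT_CONFIG
from gts.fixtures import FixtureSpec, generate_parts
from gts.planner import AssemblyDesign


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def registry():
    """A medium synthetic registry shared across the suite (seeded)."""
    return generate_parts(FixtureSpec(seed=42, n_fragments=14, n_barcodes=14))


@pytest.fixture()
def rng():
    return random.Random(7)


@pytest.fixture(scope="session")
def design_factory(registry):
    """Factory of seeded random valid designs (2-7 fragments, random flips)."""

    def make(rng: random.Random, name: str = "design", n_fragments: int | None = None):
        k = n_fragments or rng.randint(2, 7)
        frags = rng.sample(sorted(registry.fragments), k)
        bcs = rng.sample(sorted(registry.barcodes), k)
        parts = []
        for f, b in zip(frags, bcs):
            parts.append(("<" if rng.random() < 0.5 else "") + b)
            parts.append(("<" if rng.random() < 0.5 else "") + f)
        return AssemblyDesign.from_strings(name, parts)

    return make
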