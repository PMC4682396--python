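import numpy as np
import pytest

from methylmerge.io_calls import CytosineCall, MapperCallSet
from methylmerge.simulate import make_reference, generate_reads, preset_profiles


CONTEXTS = ("CG", "CHG", "CHH")


def random_callset(
    rng: np.random.Generator,
    mapper_id: str,
    n_positions: int = 100,
    chrom: str = "chr1",
    max_pos: int = 1000,
    max_depth: int = 30,
    coverage: float = 0.7,
) -> MapperCallSet:
    """A random call set over positions 1..max_pos (helper, not a fixture)."""
    positions = rng.choice(max_pos, size=min(n_positions, max_pos), replace=False) + 1
    cs = MapperCallSet(mapper_id=mapper_id)
    for pos in positions:
        if rng.random() > coverage:
            continue
        depth = int(rng.integers(1, max_depth + 1))
        n_meth = int(rng.integers(0, depth + 1))
        cs.add(
            CytosineCall(
                chrom=chrom,
                pos=int(pos),
                strand="+" if rng.random() < 0.5 else "-",
                context=CONTEXTS[int(rng.integers(0, 3))],
                n_meth=n_meth,
                n_unmeth=depth - n_meth,
            )
        )
    cs.lam = sum(c.depth for c in cs) / max_pos
    return cs


@pytest.fixture(scope="session")
def profiles():
    return preset_profiles()


@pytest.fixture(scope="session")
def small_simulation():
    """A 30-block, 100-bp-read simulation shared across read-only tests."""
    reference, targets = make_reference(30, 500, repeat_fraction=0.1, seed=11)
    reads, truth = generate_reads(targets, reference, 100, 50, 0.02, seed=12)
    return reference, targets, reads, truth
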