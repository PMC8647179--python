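import numpy as np
import pytest

from ihmforge import fixtures
from ihmforge.ihm_dictionary import builtin_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return builtin_dictionary()


@pytest.fixture(scope="session")
def toy():
    """One standard generated entry with ground truth, shared read-only."""
    return fixtures.generate_entry(fixtures.ToyConfig(seed=42))


def random_config(rng: np.random.Generator, seed: int) -> fixtures.ToyConfig:
    """A random but always-feasible generator configuration."""
    n_states = int(rng.integers(1, 4))
    length = int(rng.integers(40, 160))
    atomic_fraction = float(rng.choice([0.0, 0.2, 0.3, 0.5, 1.0]))
    bead = int(rng.choice([1, 5, 10]))
    # keep the cross-link plan feasible: each group uses up to 2 pairs and
    # every pair needs a fresh site on the first chain
    n_atomic = int(atomic_fraction * length)
    n_sites = n_atomic + -(-(length - n_atomic) // bead)
    max_groups = max((n_sites - 1) // 4, 1)
    n_sat = int(rng.integers(0, min(8, max_groups + 1)))
    n_vio = int(rng.integers(0, min(5, max_groups - n_sat + 1)))
    if n_sat + n_vio == 0:
        n_sat = 1
    return fixtures.ToyConfig(
        n_entities=int(rng.integers(1, 3)),
        chain_length=length,
        n_models=int(rng.integers(1, 5)),
        atomic_fraction=atomic_fraction,
        sphere_residues_per_bead=bead,
        n_states=n_states,
        ordered=bool(rng.integers(2)) and n_states >= 2,
        n_crosslinks_satisfied=n_sat,
        n_crosslinks_violated=n_vio,
        crosslink_threshold=float(rng.choice([15.0, 25.0, 35.0])),
        seed=seed,
    )
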