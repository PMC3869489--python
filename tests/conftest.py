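import numpy as np
import pytest

from cliffminer.chemistry import Molecule, standardize_compound
from cliffminer.synthetic import (
    R_GROUP_LIBRARY,
    SCAFFOLD_TEMPLATES,
    GeneratorConfig,
    generate_collection,
)

#: a few acyclic molecules to mix into random sets (chains exercise the
#: degenerate no-ring paths of fragmentation and scaffolding)
CHAINS = ("CCO", "CCCC", "CCN", "CC(C)O", "CCOC", "CCCBr", "NCCO", "CC(N)C")


def mol(smiles: str) -> Molecule:
    return standardize_compound(smiles)


def random_molecule_set(rng: np.random.Generator, n: int) -> dict[str, Molecule]:
    """Random small molecules from the valence-safe scaffold/R grammar."""
    out: dict[str, Molecule] = {}
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 20 * n:
        attempts += 1
        if rng.random() < 0.2:
            smi = CHAINS[rng.integers(len(CHAINS))]
        else:
            tpl = SCAFFOLD_TEMPLATES[rng.integers(len(SCAFFOLD_TEMPLATES))]
            smi = tpl.format(r=R_GROUP_LIBRARY[rng.integers(len(R_GROUP_LIBRARY))])
        m = standardize_compound(smi)
        if m.smiles in seen:
            continue
        seen.add(m.smiles)
        out[f"M{len(out):03d}"] = m
    return out


@pytest.fixture(scope="session")
def default_collection():
    """The generator's default study conditions (3 sets x 120 compounds)."""
    return generate_collection(GeneratorConfig(seed=20))


@pytest.fixture(scope="session")
def small_collection():
    """A reduced collection for faster end-to-end checks."""
    cfg = GeneratorConfig(n_sets=1, set_size=60, seed=5)
    return generate_collection(cfg)
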