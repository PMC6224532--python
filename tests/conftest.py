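import numpy as np
import pytest

import commstruct as cs


@pytest.fixture(scope="session")
def toy():
    """4-tip tree ((A:1,B:1):1,(C:1,D:1):1) with hand-checked tables."""
    tree, traits, meta, cm = cs.toy4()
    return {"tree": tree, "traits": traits, "meta": meta, "cm": cm}


@pytest.fixture(scope="session")
def toy_patristic(toy):
    return cs.patristic_matrix(toy["tree"])


@pytest.fixture(scope="session")
def small_world():
    """A small mixed-process world reused across pipeline-level tests."""
    sc = cs.AssemblyScenario(
        n_species=120, n_sites=30,
        biome_plan=(("TMBF", 10), ("TGSS", 9), ("MGS", 4), ("MFWS", 2),
                    ("DXS", 5)),
        assembly="mixed", richness_mean=18, seed=42)
    tree, traits, meta, cm = cs.generate_world(sc)
    return {"scenario": sc, "tree": tree, "traits": traits, "meta": meta,
            "cm": cm}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
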