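import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from pseudotrace.species_tree import SpeciesTree
from pseudotrace.synth_data import (PlantedEvent, SimulationParams,
                                    simulate_family)

THREE_LEAF = "((Hsa:6,Ptr:6)Hpa:84,Mus:90)Eth;"
FIVE_LEAF = "(((Hsa:6,Ptr:6)Hpa:19,Mmu:25)Ctr:65,(Mus:20,Rno:20)Mur:70)Eth;"


@pytest.fixture
def tree3() -> SpeciesTree:
    return SpeciesTree.from_newick(THREE_LEAF)


@pytest.fixture
def tree5() -> SpeciesTree:
    return SpeciesTree.from_newick(FIVE_LEAF)


@pytest.fixture
def study_factory(tree5):
    """Build a simulated study on the 5-species tree with chosen events."""

    def make(seed=0, rate=0.02, events=(), unannotated=frozenset(), **kw):
        params = SimulationParams(tree=tree5, subst_rate=rate,
                                  planted_events=tuple(events),
                                  unannotated_species=frozenset(unannotated),
                                  seed=seed, **kw)
        return simulate_family(params)

    return make
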