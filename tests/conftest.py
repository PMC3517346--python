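import pytest

from paofam.scoring import ScoringScheme
from paofam.synthetic_data import (DuplicationScenario, default_params,
                                   random_species_tree, simulate_family)


@pytest.fixture(scope="session")
def blosum62():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def dup_family():
    """A 10-taxon family with one duplication, an isoform block and a few
    planted constrained columns, shared across test modules."""
    species = random_species_tree(10, seed=42, min_branch=0.03,
                                  max_branch=0.12)
    clade = None
    for node in species.tree.preorder_internal_node_iter():
        leafset = species.clade_leafset(node)
        if 4 <= len(leafset) <= 6:
            clade = leafset
            break
    assert clade is not None
    iso = frozenset(sorted(clade)[:2])
    # the isoform clade must be the MRCA leafset of its members
    iso = species.clade_leafset(species.mrca(iso))
    scenario = DuplicationScenario(duplication_clade=clade,
                                   isoform_clade=iso)
    params = default_params(p_invariant=0.1, gamma_shape=1.0,
                            indel_rate=0.002,
                            constrained_columns=frozenset(range(10, 100,
                                                                15)),
                            seed=7)
    seqs, truth = simulate_family(species, scenario, params,
                                  root_length=240)
    return {"species": species, "scenario": scenario, "params": params,
            "sequences": seqs, "truth": truth, "clade": clade, "iso": iso}
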