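import numpy as np
import pytest
import dendropy

from opsinkit.config import SimulationConfig, PlantedEvent
from opsinkit.simul import (
    simulate_species_tree,
    simulate_gene_family_history,
    evolve_codon_sequences,
    emit_genomes,
)


def rooted(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    t.is_rooted = True
    return t


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-species simulated dataset with one tandem + one retro event."""
    tree = simulate_species_tree(6, birth=1.0, death=0.0, seed=11)
    cfg = SimulationConfig(
        seed=11, n_species=6,
        planted_events=[
            PlantedEvent("duplication_tandem", "n2", family="blue"),
            PlantedEvent("duplication_retro", "n2", family="LW"),
        ],
    )
    ledger = simulate_gene_family_history(tree, cfg)
    seqs = evolve_codon_sequences(ledger, tree, cfg)
    genomes = emit_genomes(ledger, seqs, cfg)
    return {"tree": tree, "cfg": cfg, "ledger": ledger, "seqs": seqs,
            "genomes": genomes}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
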