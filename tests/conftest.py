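import pytest

from genomejenga.fba_core import MetabolicModel, Reaction
from genomejenga.io_formats import (
    Annotation,
    GeneAnnotation,
    MutationRecord,
    MutationTable,
)
from genomejenga.synthetic_data import ToyModelConfig, generate_toy_model


@pytest.fixture
def chain_model():
    """EX_A (lb -10) -> A; R1: A -> B (gene g1); BIOMASS: B -> ∅.
    Hand-solvable: optimum = uptake bound x unit yield = 10."""
    return MetabolicModel(
        id="chain",
        metabolites=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr="g1"),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0),
        ],
        genes=["g1"],
        objective_reaction="BIOMASS",
    )


@pytest.fixture
def symmetric_model():
    """Two parallel 2-gene pathways, each alone sufficient for growth."""
    return generate_toy_model(
        ToyModelConfig(n_pathways=2, genes_per_pathway=2, seed=0)
    )


@pytest.fixture
def redundant_model():
    """Two parallel pathways of unequal gene counts plus two isozyme pairs."""
    return generate_toy_model(
        ToyModelConfig(
            n_pathways=2, genes_per_pathway=(2, 3), n_isozyme_pairs=2, seed=0
        )
    )


@pytest.fixture
def hand_annotation():
    return Annotation(
        [GeneAnnotation("g1", 100), GeneAnnotation("g2", 300)]
    )


@pytest.fixture
def hand_mutations():
    """Mutations at generations 100, 200, 200 in a 2-gene genome."""
    return MutationTable(
        [
            MutationRecord("Ara-1", 100.0, "g1"),
            MutationRecord("Ara-1", 200.0, "g2"),
            MutationRecord("Ara-1", 200.0, "g2"),
        ]
    )
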