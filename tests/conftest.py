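import numpy as np
import pytest

from rxnedit.model import EncoderConfig, ReactionModel
from rxnedit.reaction_io import parse_reaction
from rxnedit.synthetic_data import GeneratorConfig, generate

ESTERIFICATION = ("[CH3:1][C:2](=[O:3])[OH:4].[OH:5][CH3:6]"
                  ">>[CH3:1][C:2](=[O:3])[O:5][CH3:6]")

# fixture molecules with <= 8 heavy atoms for symmetry tests
SMALL_MOLECULES = {
    "benzene": "c1ccccc1",
    "para_xylene": "Cc1ccc(C)cc1",
    "ethanol": "CCO",
    "acetic_acid": "CC(=O)O",
    "cyclopropane": "C1CC1",
    "isobutane": "CC(C)C",
    "furan": "c1ccoc1",
    "toluene": "Cc1ccccc1",
    "propene": "C=CC",
    "glycol": "OCCO",
}


@pytest.fixture
def esterification():
    return parse_reaction(ESTERIFICATION)


@pytest.fixture(scope="session")
def generated_batch():
    """A reusable batch of synthetic reactions with exact ground truth."""
    return generate(GeneratorConfig(seed=11, n_reactions=60))


@pytest.fixture
def tiny_model():
    return ReactionModel(EncoderConfig(num_layers=2, hidden_dim=16,
                                       num_heads=2, seed=3))


@pytest.fixture
def mol_graphs():
    return {name: parse_reaction(f">>{smi}").product
            for name, smi in SMALL_MOLECULES.items()}
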