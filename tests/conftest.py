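import numpy as np
import pytest

from pepdock import synth


@pytest.fixture(scope="session")
def planted():
    """Canonical planted complex: (spec, receptor, ligand, ground_truth)."""
    spec, (receptor, ligand, gt) = synth.standard_fixture(seed=0)
    return spec, receptor, ligand, gt


@pytest.fixture()
def helix_pair():
    """Two small typed helices placed far apart (no interactions)."""
    rec = synth.make_peptide("AAEAKAA", chain_id="A")
    lig = synth.make_peptide("AKAEA", chain_id="B")
    for a in lig.atoms():
        a.position = a.position + np.array([100.0, 0.0, 0.0])
    return rec, lig
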