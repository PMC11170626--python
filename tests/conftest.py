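import numpy as np
import pytest

from epichem.panel import generic_panel
from epichem.synthetic import SyntheticSpec, generate_library, generate_with_assignments
from epichem.types import CompoundLibrary, CompoundRecord


def make_library(smiles_profiles, n_targets=4, names=None, general=None):
    """Build a small library from (smiles, profile) pairs over a generic panel."""
    panel = generic_panel(n_targets)
    records = []
    for i, (smi, profile) in enumerate(smiles_profiles):
        flags = np.asarray(general[i], dtype=np.uint8) if general else np.zeros(0, np.uint8)
        records.append(
            CompoundRecord(
                compound_id=i,
                name=names[i] if names else f"CPD-{i:03d}",
                smiles=smi,
                specific_profile=np.asarray(profile, dtype=np.uint8),
                general_flags=flags,
            )
        )
    return CompoundLibrary(records=records, panel=panel, provenance="test")


@pytest.fixture(scope="session")
def small_synthetic():
    """Mid-diversity synthetic library: 30 compounds over 10 scaffolds."""
    return generate_library(SyntheticSpec(n_compounds=30, n_scaffolds=10, seed=7))


@pytest.fixture(scope="session")
def assigned_synthetic():
    """Library with known scaffold assignments (60 compounds, 12 scaffolds)."""
    spec = SyntheticSpec(n_compounds=60, n_scaffolds=12, seed=7)
    return generate_with_assignments(spec) + (spec,)
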