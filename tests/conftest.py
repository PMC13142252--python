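"""Shared fixtures: small synthetic bundles and calibrated index models."""

import numpy as np
import pytest

from fshrdyn.activation import calibrated_model
from fshrdyn.microswitch import helix_anchor
from fshrdyn.synth import build_bundle, default_geometry, place_ligand
from fshrdyn.trajio import Structure, Trajectory

MICROSWITCH_PAIRS = [("TMD6", "TMD3"), ("TMD6", "TMD5"), ("TMD2", "TMD7")]

#: allosteric-pocket analogue residues in the default bundle numbering:
#: TMD3 upper third (T449/S453/G454 analogues), TMD6 (F591 analogue),
#: TMD7 (H615 analogue)
POCKET_RESIDUES = [449, 453, 454, 591, 615]


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def bundle(geometry):
    """Active-state Cα bundle, 8 residues per helix (smallest legal)."""
    return build_bundle(geometry, helix_length=8)


@pytest.fixture(scope="session")
def bundle25(geometry):
    """Long bundle whose numbering covers the pocket-analogue residues."""
    return build_bundle(geometry, helix_length=25)


@pytest.fixture(scope="session")
def holo_bundle(geometry, bundle25):
    return place_ligand(bundle25, POCKET_RESIDUES, contact_distance=3.4, seed=1)


@pytest.fixture(scope="session")
def index_model(geometry):
    """Activation model calibrated to 75 (active) / -25 (inactive)."""
    act = build_bundle(geometry, helix_length=8)
    ina = build_bundle(geometry, helix_length=8, state="inactive")
    anchors = [
        (helix_anchor(act, a), helix_anchor(act, b)) for a, b in MICROSWITCH_PAIRS
    ]
    return calibrated_model(act, ina, anchors)


@pytest.fixture
def tiny_structure():
    """Two residues, three atoms, plus one annotated helix."""
    return Structure(
        atom_names=["N", "CA", "CA"],
        elements=["N", "C", "C"],
        res_names=["ALA", "ALA", "GLY"],
        res_numbers=[1, 1, 2],
        chain_ids=["A", "A", "A"],
        coords=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [3.0, 4.0, 0.0]],
        helix_annotation={"TMD1": (1, 2)},
    )


def static_trajectory(structure: Structure, n_frames: int = 5, dt: float = 0.1):
    coords = np.repeat(structure.coords[None], n_frames, axis=0)
    return Trajectory(structure, coords, dt * np.arange(n_frames))
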