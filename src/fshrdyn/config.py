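"""Run configuration: schema, defaults, YAML round-trip, hashing.

A single YAML document declares everything a pipeline run needs —
simulate-or-load mode, system/replicate layout, generator dynamics,
activation model and thresholds, microswitch pairs with reference
distances, contact parameters and assay truth blocks — so a run is
reproducible from the config plus one global seed.  The SHA-256 hash
of the canonical config dump is stamped into every output.
"""

from __future__ import annotations

import copy
import hashlib

import yaml

#: Reference TMD-TMD distances (Å) used by shift-vs-reference reports.
#: These are PLACEHOLDER values computed from this package's own default
#: active-state bundle geometry, standing in for experimentally derived
#: cryo-EM distances; replace them with measured values for real data.
PLACEHOLDER_REFERENCE_DISTANCES = {
    "TMD6-TMD3": 22.4,
    "TMD6-TMD5": 10.0,
    "TMD2-TMD7": 18.0,
}

DEFAULT_CONFIG: dict = {
    "mode": "simulate",
    "seed": 1,
    "helix_length": 12,
    "n_frames": 600,
    "n_replicates": 3,
    "dynamics": {
        "tau": 5.0,
        "sigma": 1.0,
        "k_act_to_inact": 0.005,
        "k_inact_to_act": 0.005,
        "dt": 0.1,
    },
    "systems": [
        # mutants are modelled as rigidified bundles: smaller positional
        # noise and slower state switching than wild type
        {"label": "WT", "ligand_states": ["apo", "holo"]},
        {
            "label": "D408Y",
            "ligand_states": ["apo", "holo"],
            "dynamics": {"sigma": 0.6, "k_act_to_inact": 0.002,
                         "k_inact_to_act": 0.002},
        },
    ],
    # pocket residues chosen as synthetic analogues of the allosteric
    # site (TMD3 and TMD6/TMD7 upper-third residues)
    "pocket_residues": [445, 446, 573, 574, 602],
    "thresholds": {"inactive_max": 0.0, "active_min": 55.0},
    # "auto" calibrates a model on the generator's own state geometries;
    # replace with an explicit descriptor list for real receptors
    "activation_model": "auto",
    "pairs": ["TMD6-TMD3", "TMD6-TMD5", "TMD2-TMD7"],
    "reference_distances": dict(PLACEHOLDER_REFERENCE_DISTANCES),
    "contact": {
        "cutoff": 3.5,
        "window": 40.0,
        "atom_scope": "sidechain",
        "min_persistence": 0.25,
    },
    "assay": {
        "dose_response": {
            # truth blocks for the two agonist curves of the reporter assay
            "recFSH": {"bottom": 0.0, "top": 100.0, "ec50": 0.18, "hill": 1.0,
                       "dose_min": 0.001, "dose_max": 100.0, "n_doses": 8},
            "CAN1405": {"bottom": 0.0, "top": 100.0, "ec50": 11.3, "hill": 1.0,
                        "dose_min": 0.1, "dose_max": 10000.0, "n_doses": 8},
        },
        "cv": 0.05,
        "n_replicates": 3,
        "densitometry": {"variant": "WT", "fold": 1.6, "cv": 0.10,
                         "n_replicates": 3},
    },
}


def default_config() -> dict:
    """A fresh copy of the bundled demo configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    merged = default_config()
    merged.update(cfg)
    return merged


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-keys) YAML dump, hex-encoded."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
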