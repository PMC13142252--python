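"""Ligand contact-occupancy maps over the trailing analysis window.

Builds a bundle with a pocket ligand contacting analogues of the
allosteric-site residues, simulates replicates, and reports each
residue's contact occupancy over the last 40 ns plus the
presence/absence comparison across replicates.
"""

from fshrdyn.contacts import ContactConfig, compare_maps, occupancy_map
from fshrdyn.synth import (
    DynamicsParams, build_bundle, default_geometry, place_ligand, simulate,
)

geometry = default_geometry()
apo = build_bundle(geometry, helix_length=25)
pocket = [449, 453, 454, 591, 615]   # TMD3 / TMD6 / TMD7 analogues
holo = place_ligand(apo, pocket, contact_distance=3.3, seed=1)

config = ContactConfig(cutoff=3.5, window=40.0)
maps = []
for rep in range(3):
    dynamics = DynamicsParams(tau=2.0, sigma=0.5, dt=0.1, seed=100 + rep)
    traj, _ = simulate(geometry, dynamics, 500, structure=holo, helix_length=25)
    cmap = occupancy_map(traj, config, system="WT", replicate=f"R{rep + 1}")
    maps.append(cmap)
    occ = "  ".join(f"{r}:{f:.2f}" for r, f in sorted(cmap.occupancy.items()))
    print(f"R{rep + 1} ({cmap.n_frames} frames): {occ}")

table = compare_maps(maps, min_fraction=config.min_persistence)
print(f"residues whose presence differs between replicates: "
      f"{table.attrs['diff'] or 'none'}")
print("-> occupancy is the fraction of window frames with any residue atom "
      f"within {config.cutoff} Å of the ligand; pocket residues stay high, "
      "all others stay absent.")
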