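"""Rigid-body superposition and per-residue displacement vectors.

Rotates one half of a synthetic Cα chain about a pivot (emulating an
auxiliary subunit tilting against a fixed receptor core), aligns on the
unmoved anchor region, and reads the conformational change off the
displacement field.
"""
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import amparkit as ak


def ca_system(coords):
    atoms = pd.DataFrame([dict(atom_id=i, atom_name="CA", element="C",
                               residue_number=i + 1, residue_name="ALA",
                               chain_id="A", is_heavy=True, is_hetero=False)
                          for i in range(len(coords))])
    return ak.MolecularSystem(atoms=atoms, frames=np.asarray(coords)[None])


rng = np.random.default_rng(0)
reference = rng.normal(size=(20, 3)) * 6.0

# residues 11-20 tilt by 8 degrees about the z-axis through the origin
tilt = Rotation.from_euler("z", 8, degrees=True).as_matrix()
mobile = reference.copy()
mobile[10:] = mobile[10:] @ tilt.T

result = ak.kabsch_align(ca_system(mobile), ca_system(reference),
                         "name CA resid 1-10")
print(f"anchor-region RMSD after superposition: {result.rmsd:.4f} Å "
      f"over {result.n_atoms} Cα atoms")

aligned = ak.apply_alignment(ca_system(mobile), result)
field = ak.displacement_field(aligned, ca_system(reference))
print("\nresidue   |displacement| (Å)")
for row in field.table.itertuples():
    marker = "  <- tilted" if row.residue_number > 10 else ""
    print(f"  {row.residue_number:3d}     {row.magnitude:10.3f}{marker}")
print("\nanchor residues stay near zero; tilted residues move by "
      "2 sin(4°) times their distance from the pivot axis, so the vector "
      "field localises and quantifies the conformational change.")
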