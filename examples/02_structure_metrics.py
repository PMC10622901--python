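"""Structure-level metrics on ideal-geometry fixtures.

Builds an ideal alpha-helix and a two-strand antiparallel beta-sheet,
assigns 3-state secondary structure from Kabsch-Sander hydrogen bonds,
and demonstrates rigid-body superposition RMSD.
"""

import numpy as np

import idrfold as f
from idrfold.synthetic import _rotation_matrix, replace_coords

helix = f.gen_helix_structure(20)
print("ideal 20-residue helix  :", f.assign_ss3(helix))
sheet = f.gen_beta_sheet(8)
print("antiparallel sheet (2x8):", f.assign_ss3(sheet))
extended = f.gen_extended_structure(12)
print("fully extended chain    :", f.assign_ss3(extended))

# secondary-structure content per pLDDT confidence bin
plddt = np.linspace(40, 98, helix.n_residues)
table = f.ss_content_by_bin(f.assign_ss3(helix), plddt)
print("\nsecondary-structure content per pLDDT bin (helix, synthetic pLDDT):")
print(table.round(1))

# RMSD is invariant under rigid motion and reports real deformations
rng = np.random.default_rng(0)
R = _rotation_matrix(np.array([1.0, 1.0, 0.0]), 120.0)
moved = replace_coords(helix, helix.coords @ R.T + np.array([10.0, -5.0, 3.0]))
print(f"\nRMSD vs rigidly moved copy : {f.superpose_rmsd(helix, moved).rmsd:.2e} A")
noisy = replace_coords(helix, helix.coords + rng.normal(0, 0.3, helix.coords.shape))
print(f"RMSD vs 0.3 A jittered copy: {f.superpose_rmsd(helix, noisy).rmsd:.2f} A")
print("\nThe near-zero value shows superposition removes rigid motion exactly;")
print("the jittered copy reports the true coordinate deformation.")
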