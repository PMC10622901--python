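"""MSA conservation statistics and variant mutational burden.

Conditionally folded IDRs are more positionally conserved and less
tolerant to substitutions than IDRs that stay disordered.  This example
measures both signals on synthetic data with known ground truth.
"""

import numpy as np

import idrfold as f
from idrfold.burden import burden_table, residue_totals

# --- conservation: CF-like (conserved) vs non-CF-like (diverged) MSAs -------
ref = "MKQLEDKVEELLSKNYHLENEVARLKKLVGER" * 4
msa_cf = f.gen_msa(ref, 300, conservation=0.60, gap_rate=0.10, seed=1)
msa_ncf = f.gen_msa(ref, 300, conservation=0.25, gap_rate=0.25, seed=2)
cons_cf = f.positional_conservation(msa_cf)
cons_ncf = f.positional_conservation(msa_ncf)
print(f"mean positional conservation: CF-like {cons_cf.mean:.2f}, "
      f"non-CF-like {cons_ncf.mean:.2f}")
test = f.mann_whitney_u(
    cons_cf.per_column[~np.isnan(cons_cf.per_column)],
    cons_ncf.per_column[~np.isnan(cons_ncf.per_column)],
    mode="normal",
)
print(f"Mann-Whitney two-sided p = {test.p:.2e} (U = {test.u:.0f})")

# --- burden: polymorphisms concentrate in low-pLDDT IDRs --------------------
spec = f.SyntheticProteomeSpec(n_proteins=300, length_range=(800, 1200), seed=3)
tracks, truth = f.gen_proteome_tracks(spec)
variants = f.gen_variant_set(
    truth, {"disordered_non_cf": 0.008, "disordered_cf": 0.002}, seed=4,
    variant_label="population",
)
track_map = {t.protein_id: t for t in tracks}
counts, _ = f.map_variants_to_classes(variants, track_map)
table = burden_table(counts, residue_totals(track_map))
print("\nper-residue burden by region class:")
print(table.round(4).to_string(index=False))
low = table.set_index("region_class").loc["idr_very_low"]
high = table.set_index("region_class").loc[["idr_confident", "idr_very_confident"]]
b_high = high["n_mutations"].sum() / high["n_residues"].sum()
fisher = f.fisher_exact(
    int(low["n_mutations"]), int(low["n_residues"] - low["n_mutations"]),
    int(high["n_mutations"].sum()),
    int(high["n_residues"].sum() - high["n_mutations"].sum()),
)
print(f"\nburden fold-ratio (low pLDDT / confident): {low['burden'] / b_high:.1f}x,"
      f" Fisher p = {fisher.p:.2e}")
print("The ~4x excess in low-pLDDT IDRs mirrors their structural tolerance")
print("to substitutions; confident (conditionally folded) IDRs are constrained.")
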