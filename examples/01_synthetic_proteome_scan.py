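"""Scan a synthetic proteome for conditionally folded IDRs.

Generates a 100-protein proteome in which 30% of residues are disordered
and 15% of those sit in conditionally folded (CF) segments with confident
pLDDT, then runs the core pipeline: disorder segmentation, pLDDT binning,
CF classification and a residue-level ROC analysis against the known truth.
"""

import numpy as np

import idrfold as f

spec = f.SyntheticProteomeSpec(n_proteins=100, length_range=(300, 700), seed=1)
tracks, truth = f.gen_proteome_tracks(spec)
track_map = {t.protein_id: t for t in tracks}

summary = f.proteome_summary(tracks)
print(f"residues: {summary['n_residues']:,}")
print(f"disordered: {summary['pct_disordered']:.1f}% of the proteome")
print(f"of those, pLDDT >= 70: {summary['pct_disordered_plddt_ge_70']:.1f}% "
      "(candidate conditional folders)")
print(f"conditionally folded upper bound: "
      f"{summary['pct_total_cf_plddt_ge_70']:.1f}% of all residues")

segments = []
for t in tracks:
    segments.extend(f.extract_idr_segments(t))
calls = f.classify_idrs(segments, track_map)
n_cf = sum(calls.values())
print(f"\nIDR segments: {len(segments)}, called conditionally folded: {n_cf}")

# how well does pLDDT separate CF from non-CF disordered residues?
scores = np.concatenate([t.plddt[t.disordered_mask()] for t in tracks])
labels = np.concatenate([truth.cf[t.protein_id][t.disordered_mask()] for t in tracks])
roc = f.roc_curve(scores, labels)
op = f.best_operating_point(roc)
print(f"\nresidue-level ROC: AUC = {roc.auc:.3f} "
      f"({roc.n_positive:,} CF vs {roc.n_negative:,} non-CF residues)")
print(f"best operating point (max TPR/FPR): pLDDT >= {op.threshold:.1f} "
      f"(TPR {op.tpr:.2f}, FPR {op.fpr:.4f})")
print("\nAUC near 1 reflects the designed separation between CF (mean pLDDT 85)")
print("and non-CF (mean 35) residues; real proteomes are far noisier.")
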