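"""Secondary-structure propensity from Ca/Cb chemical shifts.

An IDR that helically folds only on binding shows fractional helix in its
unbound NMR shifts (SSP well below 1) even when a predicted structure of
the bound state is fully helical.  This example synthesizes shifts for a
40%-populated helix and compares the SSP track against an all-helix
structure string.
"""

import numpy as np

import idrfold as f

# unbound ensemble: 40% transient helix, realistic 0.1 ppm shift noise
shifts = f.gen_shift_table("H" * 60, population=0.4, noise_ppm=0.1, seed=3)
deltas = f.secondary_shifts(shifts)
track = f.ssp_track(deltas, window=5, min_data=3)
print(f"mean SSP over the helical region: {np.nanmean(track):+.2f} "
      "(the generating population is 0.40)")

agreement = f.ssp_vs_structure(track, "H" * 60)
print(f"mean |SSP - target| vs an all-helix structure: "
      f"{agreement.mean_residual:.2f}")

# a fully formed helix, by contrast, scores +1 by construction
full = f.gen_shift_table("H" * 60, population=1.0, noise_ppm=0.0, seed=0)
full_track = f.ssp_track(f.secondary_shifts(full))
print(f"fully formed helix SSP (interior): {np.nanmean(full_track[2:-2]):+.2f}")

print("\nSSP ~ +0.4 with residual ~ 0.6 against a fully helical model is the")
print("signature of conditional folding: the free ensemble is mostly coil,")
print("while the confidently predicted structure shows the folded form.")
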