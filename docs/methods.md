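# Methods

## The problem and the core procedure

Intrinsically disordered regions (IDRs) interconvert among many
conformations and have no single native structure, yet a subset of them —
*conditionally folded* IDRs — acquire a stable fold on binding a partner or
ligand, or after post-translational modification.  Structure predictors
trained on folded proteins assign these regions confident per-residue
scores even though the free chain is disordered: the predicted model
resembles the bound/modified form.  `idrfold` operationalizes that
observation as a classifier and provides the surrounding analyses.

The pipeline, per protein:

1. **Disorder segmentation.**  A per-residue disorder propensity track in
   [0, 1] (from any external predictor) is thresholded at 0.5, *inclusive*
   (a residue scoring exactly 0.5 is disordered).  Maximal runs of
   disordered residues are IDR segments; coordinates are 1-based and
   inclusive everywhere, including all TSV output.
2. **pLDDT binning.**  AlphaFold2 per-residue confidence (pLDDT, 0–100,
   stored in the B-factor column of AFDB files) is binned into
   [0, 50) *very low*, [50, 70) *low*, [70, 90) *confident* and [90, 100]
   *very confident* — left-closed, right-open except the last.  A value of
   exactly 70 is confident, exactly 90 very confident.
3. **Conditional-folding call.**  A segment is called conditionally folded
   (CF) when it contains at least `min_consecutive` (default 10)
   consecutive residues with pLDDT ≥ `plddt_threshold` (default 70).  The
   criterion is a *consecutive run*, not a segment mean: a long disordered
   tail must not dilute a confidently predicted core, and a single
   confident residue must not promote a segment.
4. **Classifier scoring.**  Where ground-truth CF labels exist, pooled
   per-residue pLDDT values are scored as a binary classifier
   ("pLDDT ≥ t ⇒ conditionally folded") with a full ROC curve: one point
   per distinct score, ties grouped, AUC by the trapezoid rule — exactly
   the tie-adjusted rank statistic U/(n₊ n₋).  The preferred operating
   point maximizes TPR/FPR over points with FPR > 0; a perfectly
   separating input has no interior optimum and is flagged degenerate.
5. **Extrapolation.**  With an observed fraction *f* of disordered
   residues called CF and a classifier sensitivity *s* estimated on known
   conditional folders, *f*/*s* (capped at 1) is an upper bound on the
   true CF fraction — e.g. 0.15/0.60 = 25%.

## Supporting analyses

* **Composition contrasts.**  Amino-acid percentages over the 20 standard
  residues (non-standard letters dropped with a count); percent-change
  deltas Δ(aa) = 100·(f_ref − f_other)/f_other, with zero-denominator
  entries undefined (NaN), never a crash; Δ-differences subtract
  elementwise and are antisymmetric by construction.
* **Charge–hydropathy features.**  ⟨H⟩ is mean Kyte–Doolittle hydropathy
  rescaled to [0, 1] via (KD + 4.5)/9 with *no* window smoothing; ⟨R⟩ is
  |#(K,R) − #(D,E)|/length with histidine and other titratable residues
  neutral; the boundary ⟨R⟩ = 2.785·⟨H⟩ − 1.151 separates ordered from
  disordered sequences.  All three conventions are module constants and
  can be overridden.  Whether published CH analyses smooth ⟨H⟩ over a
  short window varies; the unsmoothed convention is the package default
  and is stated here because it changes ⟨H⟩ in the second decimal.
* **Conservation.**  Positional conservation of an MSA is, per reference
  non-gap column, the fraction of non-gap entries in the other rows that
  match the reference residue ("identity to reference, ignoring gaps":
  gaps are excluded from numerator and denominator; columns with no other
  residue are excluded from the mean, with a count).  A column-majority
  variant (`mode="majority"`) is provided because the identity-to-reference
  choice is an interpretation; it is the default and is logged.
  Alignment depth is the fraction of non-gap rows per reference column.
* **Rank test.**  Mann–Whitney U with midrank ties; exact two-sided p by
  enumeration of all C(n₁+n₂, n₁) assignments for n₁+n₂ ≤ 20, otherwise a
  tie-corrected normal approximation with continuity correction.
* **Mutational burden.**  Variants are mapped to disjoint
  (order class × pLDDT bin) region classes; burden = mutations/residues
  (recurrent positions all count; a flagless deduplication is left to the
  caller's input).  Contrasts use burden fold-ratios and a two-sided
  Fisher exact test: p is the sum of hypergeometric probabilities of all
  same-margin tables with probability ≤ the observed table, computed in
  exact rational arithmetic so that the tie comparison has no
  floating-point fuzz.
* **Secondary structure (3-state).**  Hydrogen bonds use the
  Kabsch–Sander electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
  below −0.5 kcal/mol.  Amide hydrogens are absent from AFDB/X-ray files
  and are reconstructed 1.0 Å from N opposite the bisector of
  C(i−1)–N–CA; the chain's first residue and prolines donate no bond.
  Helices (two consecutive i→i+n turns, n = 3, 4, 5, collapsed to H) and
  strands (parallel/antiparallel bridge patterns with |i−j| ≥ 3, collapsed
  to E) follow the DSSP precedence α-helix > strand > short helices;
  everything else is coil.
* **Superposition.**  Least-squares rigid superposition by the Kabsch/SVD
  construction with reflection correction (det = +1 enforced); atoms pair
  by (residue id, atom name) after an optional residue-offset map because
  AFDB and PDB author numbering often differ; unmatched atoms are an
  error, never silently dropped.  "Heavy atoms" means all non-hydrogens.
* **Hydrophobic contacts.**  Apolar typing follows the Arpeggio-style
  rule: a carbon whose covalently bonded neighbors (bonds inferred by
  covalent-radius distance, tolerance 0.45 Å) are all carbon or hydrogen.
  Sulfur is excluded by default (`include_sulfur=True` admits it).  A
  contact is a focal side-chain apolar atom within 4.5 Å of an apolar
  atom of another residue in the partner range.
* **SSP.**  Secondary shifts Δδ = observed − random-coil reference per
  nucleus (missing data propagate; glycine has no Cβ).  The SSP score
  sums ΔδCα − ΔδCβ over an odd window (default 5) and normalizes by the
  same sum of residue-specific full-structure constants — helix constants
  when the windowed sum is positive, strand constants otherwise — so a
  fully formed helix scores +1 and a fully formed strand −1, with uniform
  weighting inside the window.  Windows with fewer than `min_data`
  (default 3) observed residues are undefined (NaN), and exports write an
  explicit sentinel, never 0.  The random-coil and full-structure
  constants ship as an editable TSV compiled from the random-coil /
  secondary-shift literature; any table with the same columns can be
  substituted, and neighbor-residue coil corrections are out of scope.

## The synthetic-data generator

The generator produces every input of the pipeline with known truth; its
defaults are the study conditions under which the package's claims are
tested.

* **pLDDT.**  Truncated normals on [0, 100]: ordered (92, 6), disordered
  non-CF (35, 10), disordered CF (85, 8).  The proteome-wide pLDDT
  histogram of a real eukaryotic AFDB is bimodal with modes near 100 and
  35; the three-component mixture is the simplest generative model with
  that shape plus a confident CF class.
* **Fractions.**  30% of residues disordered; 15% of disordered residues
  in CF segments.  Disordered and CF residue counts are allocated per
  protein by rounded quota, so realized fractions track the parameters to
  well under ±0.02 at a few hundred proteins.
* **Run lengths.**  Disordered residues sit in contiguous runs (a floor
  plus a geometric tail, mean 40) rather than i.i.d. per residue, so
  segmentation sees realistic IDR-sized stretches.  Non-CF runs floor at
  10 residues.  CF runs floor at 20: conditional folders are binding
  domains or motifs that fold as units (a homeodomain is ~60 residues,
  the phospho-stabilized 4E-BP2 β-fold ~37), and a truth segment barely
  at the 10-residue detection limit would be undetectable by construction
  — any segment that must contain a 10-residue confident run can only be
  recovered reliably when it is comfortably longer than 10.
* **Disorder scores.**  Uniform on [0.5, 1] for disordered residues and
  [0, 0.5) for ordered ones, so thresholding at 0.5 recovers the truth
  labels *exactly* and segmentation oracles are deterministic.
* **Variants.**  Independent Bernoulli per residue at a per-class rate;
  the default contrast (0.008 vs 0.002 per residue) encodes a 4× burden
  design.
* **MSAs.**  Non-reference rows copy the reference per column with the
  conservation probability, substitute a uniformly random different
  residue otherwise, and gap independently at the gap rate.
* **Shifts.**  Observed = random coil + population × full-structure
  constant + Gaussian noise, using the same reference table the SSP
  scorer reads, so population recovery is exact in expectation.
* **Structures.**  Backbones built from ideal internal coordinates
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; trans peptide)
  by torsion propagation: α-helix at (φ, ψ) = (−57.8°, −47.0°), extended
  chain at (180°, 180°), and a two-strand antiparallel sheet built from a
  (−139°, 135°) strand and its 180°-rotated copy, placed by a
  deterministic grid search that maximizes inter-strand Kabsch–Sander
  bonds.
* **Determinism.**  Every generator takes an explicit seed and one
  private `numpy.random.Generator`; fixed seed means bit-identical
  output.  The pipeline manifest records content hashes so reruns are
  checkable.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: compositional bias of real IDRs (sequences are
uniform over the 20 residues, so composition deltas on synthetic data
hover near zero), co-evolutionary structure in MSAs (columns are
independent), pLDDT autocorrelation along the chain within a class,
AFDB fragmenting of proteins longer than ~2,700 residues (out of scope),
and any actual structure prediction — pLDDT is sampled, never predicted.

## Problem sizes

The shipped tests and `scripts/acceptance.py` run at deliberately modest
sizes chosen to make the statistical tolerances meaningful: 200-protein
proteomes (~10⁵ residues) for fraction recovery at ±0.02; 20,000 scores
per class for the Gaussian AUC closed form at ±0.01; 125,000 residues per
rate class for the 4× burden design at ±20%; 500-row MSAs for
conservation at ±0.02; 1,000 random tracks against the segmentation
oracle; exhaustive 2×2 tables with all entries < 5 plus 300 random tables
with margins ≤ 30 against the Fisher enumeration oracle.

## Known limitations

* The 3-state assignment reproduces the H/E/C content of a DSSP-style
  analysis but not its 8-state detail, solvent accessibility, or chain
  break handling; it assumes a single contiguous chain.
* Contact counting depends on bond inference by distance; exotic
  chemistry (metal sites, modified residues) can misclassify atoms.
* Comparisons against published structures (the 4E-BP2 superposition, the
  ALX3 contact count and net charge) require reference files that are not
  redistributed here; see `data/external/README.md`.
* Burden analysis treats variants as point events on the reference
  numbering; indels and isoform mapping are the caller's responsibility.
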