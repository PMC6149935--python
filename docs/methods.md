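# Methods

## Problem and model

`mlabdna` predicts, from sequence-derived information alone, which residues
of a protein chain contact DNA.  Each residue is a sample in a binary
classification problem with heavy class imbalance (curated benchmarks have
roughly 11–19 non-binding residues per binding residue).  The pipeline has
four stages:

1. **Evolutionary profile.** Each chain carries an L×20 position-specific
   scoring matrix (PSSM), normally produced by iterative database search
   (PSI-BLAST `-out_ascii_pssm`); a construction path from residue
   frequencies and a substitution matrix (`compute_pssm`, using Dayhoff
   mutation scores via Biopython) is also provided.  The matrix is min-max
   scaled to [0, 1] per protein over all L×20 entries; a constant matrix
   maps to zeros (it carries no conservation signal, and this avoids a
   division by zero).

2. **Multi-scale local average blocks (MLAB).** For each residue, the
   w-row window of the normalized PSSM centered on it (w = 11 by default,
   zero rows padding the termini) is averaged over six row blocks at three
   scales: the whole window (A), its two halves (B, C) and its three
   thirds (D, E, F), giving 6×20 = 120 features.  Block boundaries follow
   the ceiling rule — block t of scale s covers rows
   ⌈(t−1)·w/s⌉+1 … ⌈t·w/s⌉ — so w = 11 splits 11 / 6+5 / 4+4+3.  The rule
   is a design choice (any odd w works and the split is a one-line
   change); blocks overlap *between* scales, not within a scale.

3. **Solvent accessibility.** A per-residue predicted solvent
   accessibility (PSA) value, min-max normalized per protein, is windowed
   exactly like the PSSM (w values, zero-padded), for 120 + w = 131
   features in total.  One value per window residue was chosen over a
   single target-residue value so the two feature families share a
   receptive field.

4. **Classification.** An ensemble of m = 19 weighted
   sparse-representation classifiers (WSRC), each trained on a balanced
   dictionary: all minority (binding) samples plus an equal-size
   with-replacement draw of majority samples ("random under-sampling").
   The ensemble probability P(y) is the arithmetic mean of member scores,
   thresholded at an operating point chosen by strategy (see below).

## The WSRC core

A test vector y is coded against the dictionary rows x_i by

    min Σ_i w_i |α_i|   subject to   ‖y − αX‖₂ ≤ ε ,

and classified to the class whose rows reconstruct it best:
v_c = ‖y − δ_c(α)X‖₂, label = argmin_c v_c (ties go to non-binding, the
majority class, which minimizes false positives).  Locality enters through
the Gaussian similarity λ_i = exp(−‖y − x_i‖²/(2σ²)) ∈ (0, 1]: the penalty
applied to coefficient i is the inverse similarity w_i = 1/λ_i =
exp(+‖y−x_i‖²/(2σ²)), so distant training samples are expensive and the
coding concentrates on the test point's neighborhood.  (Penalizing by λ
itself would make *distant* samples nearly free, inverting the locality
idea and breaking the nearest-neighbor-like behavior the classifier is
meant to have; the inverse-similarity orientation is the standard one for
locality-weighted sparse coding.)  Defaults σ = 1.5, ε = 0.5.

Residuals map to a probability-like score; three variants are provided:

    score1 = 2 − v_b/v_nb              (default; range (−∞, 2], neutral 1)
    score2 = 1 − v_b/(v_nb + v_b)      (range [0, 1], neutral 0.5)
    score3 = σ(v_nb − v_b)             (range (0, 1), neutral 0.5)

All three agree with the min-residual decision at their neutral
thresholds.  Degenerate conventions: score1 returns −∞ when v_nb = 0 and
v_b > 0, and the neutral value on exact ties; score2 returns 0.5 when both
residuals vanish.

### Solver

The constrained weighted-ℓ1 problem is solved by substitution
β_i = w_i α_i, which turns it into plain ℓ1 minimization over re-scaled
rows x_i/w_i, traced by a LARS-lasso homotopy (`_homotopy.py`, compiled
with numba).  Along the lasso path the residual norm decreases
monotonically while the ℓ1 objective increases, so the constrained optimum
is the path point where the residual norm first reaches ε; coefficients
are piecewise-linear between path knots, so that point is computed in
closed form inside the crossing segment.  Implementation notes:

- Correlations are maintained through a precomputed Gram matrix of the
  dictionary rows, shared by every solve against the same dictionary; the
  active-set Cholesky factor grows by rank-one updates and is rebuilt on
  the (rare) sign-change drops.
- Penalty weights are normalized by their minimum before solving (the
  argmin is invariant to a common positive factor); a ridge of 1e-10
  relative to the Gram diagonal guards the near-collinear scaled atoms
  that strong locality weighting produces.  Weights whose exponent
  overflows are treated as +∞ and simply disable the atom.
- If ε is below the attainable residual (y outside the reachable set at
  tolerance), the solver returns the path endpoint and flags the code as
  infeasible.
- The solver is validated against two independent oracles: sklearn's
  `lars_path` on medium random instances, and, on small instances, exact
  brute force (exhaustive enumeration of sign patterns with a closed-form
  KKT boundary solve).  A dense coarse-to-fine grid search localizes but
  cannot pin the optimum along the curved feasibility boundary (its error
  decays only like √step), which is why the exact enumeration serves as
  the tight reference.

Per-solve cost at ensemble scale (≈1800-row dictionaries, 131 features) is
about 1.3 ms, which puts a full ten-fold cross-validation of ~15,000
residues with m = 19 at roughly five minutes on one CPU.

## Ensemble and reproducibility

Member i of an ensemble built with master seed s draws its majority
subsample with seed s + i (i = 1..m, numpy PCG64).  "Balanced" means
exactly equal counts — all minority samples are always included — chosen
over "similar size" for determinism.  Cross-validation fold f builds its
ensemble with seed s + 100000·(f+1).  Every pipeline stage is
deterministic given (data, parameters, seed); prediction reports are
bit-identical across reruns.

## Evaluation harness

Confusion-derived metrics (ACC, SN, Spec, Pre, MCC) use the standard
formulas with a zero-denominator convention of 0.  AUC is the Mann-Whitney
rank statistic with half credit for ties (computed from midranks, which
equals the all-pairs count exactly); AUPR is step interpolation over the
precision–recall staircase.  Threshold candidates are the midpoints
between consecutive distinct scores plus ±∞ sentinels, so every achievable
confusion matrix is visited exactly once; prediction is binding iff
P(y) ≥ T (inclusive).  Strategies: `sen_eq_spec` (minimize |SN − Spec|),
`fpr_target` (pin FPR near a target, 5% by default), `max_mcc`, and
`fixed`.  Criterion ties prefer higher sensitivity, then the larger
threshold — the pure larger-T rule would let `fpr_target` pick the vacuous
T = +∞ on perfectly separable scores.

Cross-validation is stratified by class and, by default, grouped by
protein chain (all residues of a chain share a fold), which prevents
within-protein leakage between the highly overlapping windows of
neighboring residues; `split_by="residue"` is available for comparison
with residue-wise protocols.  Under-sampling happens inside each training
fold only; the operating threshold is selected on the pooled out-of-fold
probabilities and applied to both pooled and per-fold metrics.
`grid_search` re-extracts features for every window length and
cross-validates every (w, m) cell, reporting the MCC surface.  The
Wilcoxon rank-sum comparison is a thin wrapper over
`scipy.stats.ranksums`, provided for convenience.

## Synthetic corpus

Real benchmarks need database-searched PSSMs and an accessibility
predictor, so the test corpus is synthetic with a known ground truth:

- sequences uniform over the 20 amino acids; 100 proteins of length
  100–200 by default (≈15,000 residues);
- binding labels i.i.d. per residue with probability 1/15, matching the
  ≈14:1 imbalance of the curated training benchmarks (an optional
  `cluster_len` generates contiguous sites; i.i.d. is the default for
  analyzability);
- baseline PSSM scores: rounded Gaussians, mean 0, sd 4 on the integer
  score scale (typical of real log-odds profiles);
- conserved-block signal: rows within ±2 of each binding residue get a
  mean shift of `effect_size` × noise-sd (default 2 SD, i.e. +8 integer
  units) in five fixed columns.  The ±2 half-width puts the whole signal
  inside every window of length ≥ 5, which gives the window-length grid a
  known ground truth (wider windows dilute the block averages);
- PSA: uniform noise plus a +0.3 elevation at binding sites.

Everything is written in the exact dialects the pipeline reads (FASTA,
PSI-BLAST ASCII PSSM, TSV tracks) and is deterministic given the seed.
What the generator does *not* emulate: realistic amino-acid composition,
homology structure between chains, position-dependent conservation
outside binding sites, and correlated noise across PSSM columns.  Passing
tests therefore demonstrate that the pipeline recovers a local
conserved-block signal of the stated strength under realistic imbalance —
not performance on real proteins, which depends on profile quality and
the accessibility predictor.

## Numerical choices and limitations

- Residue positions are 1-based inclusive in every public interface.
- The PSSM parser keeps only the first 20 integer columns and tolerates
  20- and 40-column rows; the writer rounds to integers (the dialect is
  integer-valued) and rejects NaN.
- Feature vectors are not re-normalized per sample before coding (they
  already lie in [0, 1]); locality distances use the full fused vector.
- The homotopy path is capped at 4000 steps; at the cap the solve is
  flagged infeasible rather than silently truncated.
- Multi-class dictionaries beyond binding/non-binding are out of scope,
  as are alternative base classifiers and weighted ensemble voting.
- With score1, a member whose non-binding residual vanishes contributes
  −∞, which propagates to the ensemble mean; this is the documented
  sentinel and ranks such samples last.  In practice ε > 0 makes exact
  zero residuals rare.
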