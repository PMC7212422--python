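# Methods

## Generative model and variational fit

The biclustering engine is maximum-likelihood factor analysis
`V_i = W h_i + ε_i` with standard-normal factors and diagonal noise
covariance `diag(ψ)`. The noise covariance is restricted to a diagonal:
factor-analysis identifiability requires it, and it is what makes the
per-gene updates and the Woodbury-based likelihood cheap. The marginal
log-likelihood is evaluated through the r-dimensional space (matrix
determinant lemma + Woodbury), so cohorts with thousands of genes cost
O(m·r²) per evaluation rather than O(m³).

The fit is generalized alternating minimization. The E-step computes the
exact Gaussian posterior and then projects the posterior means onto the
constraint set {μ ≥ 0, per-unit mean square 1}. The constraint set
separates over hidden-unit rows; on each row the Euclidean projection is
clip-negatives-then-rescale, which is exact whenever the row retains a
positive entry. A row with no positive entry is left at zero: the unit is
inactive, and normalizing a zero vector is undefined. A single exact
projection is performed per E-step (it solves the projection subproblem in
closed form, so inner iterations would change nothing). The M-step uses
`W = PZ⁻¹`, `ψ = diag(C − PWᵀ − WPᵀ + WZWᵀ)` with
`Z = (1/n)Σμμᵀ + K_pp`; the full quadratic form is used for ψ (not the
`C − WPᵀ` shortcut) so the update stays a guaranteed descent step even
after L1 soft-thresholding perturbs W away from `PZ⁻¹`.

With rectification, dropout and the Laplace prior disabled, the procedure
is exactly textbook factor-analysis EM — the test suite holds it to an
independently coded reference implementation at 1e-6 per iteration and
checks that the log-likelihood never decreases. That limit is the
correctness anchor; the rectified fit is then the same machinery plus the
documented projection.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `r` | 10 | hidden units = bicluster candidates per fit; enough to hold a few real blocks plus noise units that the significance filter discards |
| `n_iters` | 100 | EM iterations; relative log-likelihood change < 1e-6 stops earlier |
| `dropout_rate` | 0.1 | fraction of hidden units masked per M-step, a sparsity device |
| `l1_weight` | 0.01 | soft-threshold on W per M-step (Laplace prior) |
| `psi_floor` | 1e-4 | keeps the noise covariance positive definite on degenerate inputs |
| `thr_w`, `thr_h` | 3.0 | membership ratio bounds: an element joins a unit when it is within 3× of the unit's peak loading/code; scale-free by construction |
| `min_genes`, `min_samples` | 2 | smallest admissible bicluster |
| `min_nonzero_ratio` | 0.5 | quality floor on bicluster density |
| `alpha` | 0.05 | family-wise level; Bonferroni-divided by the candidate count |
| `tau_up` | 0.5 | "significantly up-regulated" = normalized value ≥ 0.5, i.e. Z ≥ z_cap/2 |
| `frac` | 0.8 | G1 needs ≥ 80 % of the set's genes up-regulated |
| `reps`, `pass_frac` | 100, 0.8 | the repeated-subsampling screen: >80 % of 100 equal-size draws must reject at `alpha` |
| `train_frac` | 0.9 | 90/10 train/validation sample split |
| `samples_per_run` | 100 | training samples drawn per biclustering iteration |
| `match_jaccard` | 0.8 | cross-iteration gene-set merge threshold (1.0 = exact matching) |
| `z_cap` | 2.0 | Z-score mapped linearly onto [0,1] up to this cap; |Z| ≥ 2 is the conventional "significantly changed" cutoff |

Ratio-rule ties: membership uses `max/element ≤ thr` (inclusive), so with
`thr = 1` exactly the argmax elements qualify. Survival ties between an
event and a censoring at the same time process the event first (the
standard convention). Patients in neither G1 nor G2 are excluded from the
survival comparison rather than forced into G2, since G2 is defined by
*all* genes expressing normally. "Commonly occurred" gene sets are merged
greedily by highest Jaccard similarity (merged set = union) and need ≥ 2
occurrences; ranking is by occurrences descending, then validation p
ascending. The G1/G2 assignment during training uses the full training
set, not just the subsampled patients, which gives the survival screen its
full power.

## Significance rule

Under the no-association null every entry of the `[0,1]` matrix is nonzero
independently with probability q (estimated by the matrix density), so a
candidate's nonzero count is binomial. The operational rule is the
Chernoff form `k ≥ mnq + sqrt(3(−ln p*)mnq)`; the exact binomial survival
function is reported alongside and used by the tests to verify the rule's
soundness (whenever it fires with δ ≤ 1, the exact tail is below p*).
Decisions use the Chernoff rule, at `p* = alpha / b` for b candidates.
The default log-rank statistic is the observed-vs-expected chi-square
form; the variance-normalized Mantel–Haenszel form is available via
`variance_normalized=True` and is cross-checked against lifelines. Null
calibration of the default form (equal exponential hazards, 50 vs 50,
2 000 replicates) lands near 0.05 and is asserted within [0.03, 0.08] by
the test suite rather than assumed.

## Synthetic cohorts

`generate_dataset` emulates the screen's inputs: Gaussian background
Z-scores (sd 0.5 by default — enough to give the normalized matrix a
realistic ~0.5 nonzero density), disjoint planted gene blocks shifted by
`z_cap·mean_up` so normalization puts block entries near `mean_up`, one
mutation record per gene (so preprocessing retains all genes unless a test
withholds them), and exponential survival with proportional hazards:
carriers — members of any survival-linked block — die at
`hazard_ratio × baseline_hazard`. Exponential proportional hazards is the
simplest law under which the log-rank test is the textbook-optimal
detector, which is exactly what the screen should be able to find.
Censoring is independent (probability `censor_rate`, at a uniform fraction
of the event time). The defaults (200 samples, 0.03/month baseline ≈ 23-month
median, hazard ratio 3, 10 % censoring) are in the range of the mid-size
cohorts this screen targets.

What the generator does *not* emulate: gene–gene correlation outside
planted blocks, heavy-tailed expression, cancer-type-specific mutation
spectra, informative censoring, overlapping gene blocks. Passing tests
therefore demonstrate the machinery recovers planted multiplicative block
structure under independent Gaussian noise — not performance on any real
cohort.

## Problem sizes and what the checks show

The test suite and `scripts/acceptance.py` run the screen at desk scale:
500-gene × 100-sample cohorts (three 20×15 blocks) for detection, and a
200-gene × 200-sample cohort with 50 iterations of 50-sample fits for the
end-to-end screen — the full protocol's structure at a fraction of the
thousands of iterations a production run would use. At these conditions
bicluster detection is essentially solved (mean gene-set Jaccard ≈ 0.93,
under one false positive per run) and the null screen is clean (no
biomarkers on structure-free cohorts in ~all seeds).

## Known limitation: the validation gate at small cohort sizes

With a 200-sample cohort the 90/10 split leaves ~20 validation patients.
A single log-rank test at α = 0.05 with ~6 carriers against ~9–13 normal
expressers at hazard ratio 3 has power ≈ 0.3–0.4 (both by Schoenfeld's
approximation and by direct simulation), so even a perfectly detected,
training-validated gene set clears the final validation gate in only a
minority of seeds. This is a property of the protocol at small n, not of
the implementation: detection and the training screen find the planted set
in essentially every seed, and the end-to-end recovery rate observed
(~0.4) sits exactly at the validation gate's power ceiling. Larger cohorts
(validation splits of ≥ 60 patients) or milder validation criteria raise
it; neither is changed here, because the 90/10 single-test design is the
protocol being implemented. The acceptance suite keeps the corresponding
end-to-end recovery check at its nominal bar and reports the shortfall
rather than widening the bar.

Other limitations: hidden units can duplicate one strong block (near-
duplicate reported sets below the merge threshold appear as separate
ranks); the density null treats entries as independent, so long-range
correlation inflates significance; down-regulated structure is invisible
by design (normalization floors it), matching the up-regulation-only
reading of the screen.
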