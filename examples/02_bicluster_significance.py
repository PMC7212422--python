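"""Extract and filter significant biclusters from a synthetic cohort.

Generates a 500-gene x 100-sample cohort with three planted 20x15
up-regulated blocks, fits a 10-unit network, extracts candidates with the
max-to-element ratio rule, and keeps the ones that beat the Chernoff
density criterion at the Bonferroni-corrected level.
"""

import numpy as np

import rfnsurv as rs

spec = rs.PlantSpec(
    n_genes=500,
    n_samples=100,
    biclusters=tuple(
        rs.BlockSpec(n_genes=20, n_samples=15, mean_up=0.8, noise_sd=0.1)
        for _ in range(3)
    ),
    background_noise_sd=0.5,
    seed=0,
)
data = rs.generate_dataset(spec)

V = rs.normalize_expression(data.expression).to_numpy()
fit = rs.fit_rfn(V - V.mean(axis=1, keepdims=True), r=10, config=rs.EMConfig(seed=0))

candidates = rs.extract_biclusters(fit.model.W, fit.means)
params = rs.SignificanceParams(q=float(np.mean(V > 0)))
scored = [rs.score_bicluster(c, V, params) for c in candidates]
significant = rs.filter_significant(scored, params)

print(f"matrix density q = {params.q:.3f}")
print(f"{len(candidates)} candidates -> {len(significant)} significant biclusters")
for bc in significant:
    print(f"  {bc.shape[0]:>3} genes x {bc.shape[1]:>3} samples  "
          f"k={bc.k:>4}  density={bc.nonzero_ratio:.2f}  "
          f"C={bc.score_C:8.1f}  p_exact={bc.p_exact:.2e}")
symbols = list(data.expression.index)
sets = [frozenset(symbols[g] for g in bc.genes) for bc in significant]
jac, fp = rs.score_recovery(sets, {"blocks": [dict(b, survival_linked=True)
                                              for b in data.truth["blocks"]]})
print("gene-set Jaccard vs the three planted blocks:",
      [f"{j:.2f}" for j in jac], "| false positives:", fp)
# C >= 0 means the block is denser than the Bernoulli null allows at the
# corrected level; Jaccard near 1 means the planted gene sets come back.
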