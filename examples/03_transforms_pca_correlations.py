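"""Model-free companions: normalization, log transforms, PCA, paralog screen.

Size factors equalize sequencing depth exactly; the started-log transform
(zeros -> 0.1 before log10) feeds PCA; pairwise correlations over co-present
samples flag OTU pairs that behave like same-genome paralogs (positive r)
or like distinct competing genomes (negative r).
"""

import numpy as np

import plnotu as P

truth = P.orbicella_like_preset(seed=1)
screened, _ = P.screen_table(P.simulate_counts(truth))

f = P.size_factors(screened)
norm_totals = screened.counts.mul(f, axis=0).sum(axis=1)
print(f"normalized sample totals all equal the grand mean: "
      f"{np.allclose(norm_totals, screened.sample_totals.mean())}")

tm = P.started_log(screened)
hb = P.hybrid_log(screened)
r = np.corrcoef(tm.values.to_numpy().ravel(), hb.values.to_numpy().ravel())[0, 1]
print(f"started-log vs log-linear hybrid correlation: {r:.4f}")

tm_pca, retained = P.pca_prepare(screened, min_presence=0.10)
res = P.run_pca(tm_pca)
print(f"PCA on {len(retained)} OTUs present in >10% of samples: "
      f"PC1 {res.proportion_explained[0]:.1%}, PC2 {res.proportion_explained[1]:.1%}; "
      f"Kaiser retains {res.kaiser_n} components")

corr = P.paralog_correlations(screened)
pairs = corr.labels.where(np.triu(np.ones(corr.labels.shape, bool), 1))
print("pair labels (upper triangle):")
print(pairs.stack().value_counts().to_string())
# candidate-paralog = significant positive correlation of log abundances
# across co-present samples; distinct-genome = significant negative.
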