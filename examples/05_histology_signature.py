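"""A 15-gene L1-penalized histology signature with its Monte-Carlo null.

The classifier separates AC from SCC; the regularization strength is tuned
per training fold so exactly 15 genes stay active, and the reported AUC
pools out-of-fold scores.  Significance compares that AUC with random
15-gene signatures scored by the same cross-validated protocol.
"""

from dgsearch import (default_cohort_config, generate_cohort, l1_signature,
                      monte_carlo_signature_pvalue, single_feature_auc_test)

cohort = generate_cohort(default_cohort_config(seed=0))
two = cohort.labels[cohort.labels.isin(["AC", "SCC"])]
expr = cohort.expr[two.index]

clf = l1_signature(expr, two, signature_size=15, cv_folds=10, seed=0)
print(f"15-gene signature cross-validated AUC: {clf.cv_auc:.3f}")
planted = set(cohort.truth.histology_genes)
print(f"signature genes with a planted histology effect: "
      f"{len(set(clf.signature) & planted)}/15")

mc = monte_carlo_signature_pvalue(expr, two, signature_size=15,
                                  n_draws=200, seed=0,
                                  observed_auc=clf.cv_auc)
print(f"random-signature null: median AUC {mc.null_median:.3f}, "
      f"max {mc.null_aucs.max():.3f}")
print(f"Monte-Carlo p-value: {mc.p_value:.4f}")

drv = cohort.truth.planted_drivers[0]  # SCC-biased carriers
auc, p = single_feature_auc_test(expr, drv, two, n_draws=500, seed=0)
print(f"histology-biased driver {drv}: AUC {auc:.3f}, "
      f"random-gene p {p:.3f}")
# The signature's AUC exceeds every random draw (p = 1/(draws+1)); the
# single biased driver is predictive but far weaker than 15 genes.
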