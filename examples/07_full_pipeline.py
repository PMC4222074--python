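"""The end-to-end pipeline in one call, with a planted-truth scorecard.

Runs segmentation -> CNA calls -> recurrent regions -> driver search ->
sparse-CCA modules -> ranking -> histology prediction -> ANOVA clusters,
then compares the reported drivers with the generator's ground truth.
(Monte-Carlo draws are reduced here to keep the example quick; the
pipeline default is 1000.)
"""

import json

from dgsearch import PipelineConfig, default_cohort_config, \
    generate_cohort, run_pipeline

cohort = generate_cohort(default_cohort_config(seed=0))
config = PipelineConfig(seed=0, cbs_n_perm=300, mc_draws=100)
report = run_pipeline(config, cohort)

print("segmentation:", json.dumps(report["segmentation"]))
print("regions:", report["regions"]["n_recurrent"], "recurrent,",
      report["regions"]["n_pure_gene_rule"], "pure under the strict rule")
print("gene filter counts:", json.dumps(report["genes"]["filter_counts"]))

final = [d["feature"] for d in report["genes"]["final_drivers"]]
truth = cohort.truth.planted_drivers
print("final drivers:", final)
print("planted truth:", truth)
print("recall:", len(set(final) & set(truth)), "/", len(truth),
      "   false drivers:", len(set(final) - set(truth)))

pred = report["prediction"]
print(f"15-gene classifier AUC {pred['cv_auc']:.3f} "
      f"(Monte-Carlo p {pred['mc_p_value']:.4f}, "
      f"null median {pred['mc_null_median_auc']:.3f})")
print("driver AUCs:", json.dumps(pred["driver_aucs"]))
print("ANOVA:", json.dumps(report["anova"]))
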