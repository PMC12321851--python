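"""Random-forest screening of discriminative CAGs with Shapley attribution.

CAG-summed abundances feed a 500-tree forest (70/30 stratified split,
10-fold CV); per-CAG contributions to individual predictions are estimated
by Monte-Carlo permutation Shapley values (50 permutations per instance).
"""

from cagnet import SimConfig, simulate_cohort
from cagnet.cag import cag_abundance, cluster_cags, spearman_matrix
from cagnet.classify import (RfProtocol, ShapProtocol, fit_evaluate,
                             shap_group_summary, shapley_mc)

data = simulate_cohort(SimConfig(seed=7))
genus, meta = data["genus"], data["metadata"]
rho, _ = spearman_matrix(genus)
partition = cluster_cags(rho, k=8)
features = cag_abundance(genus, partition, summary="sum")

ev = fit_evaluate(features, meta["group"], RfProtocol(seed=7))
print(f"test AUC {ev.auc:.3f}; accuracy {ev.accuracy:.3f} "
      f"(sensitivity {ev.sensitivity:.3f}, specificity {ev.specificity:.3f})")
print(f"10-fold CV accuracy {ev.cv_accuracy_mean:.3f} +- {ev.cv_accuracy_sd:.3f}")
print("Gini importance ranking:", ev.importance.sort_values(ascending=False)
      .round(3).to_dict())

case_col = list(ev.model.classes_).index(1)
predict = lambda a: ev.model.predict_proba(a)[:, case_col]  # noqa: E731
attr = shapley_mc(predict, features.iloc[ev.test_idx],
                  features.iloc[ev.train_idx], ShapProtocol(seed=7))
print(f"Shapley efficiency gap (max over instances): "
      f"{attr.efficiency_gap().max():.2e}")
summary = shap_group_summary(attr, meta["group"])
print(summary[["feature", "class", "median"]].round(4).to_string(index=False))

# CAGs carrying the planted case effects earn top Gini importance and the
# widest class-separated Shapley distributions; the efficiency gap being ~0
# confirms the attributions sum exactly to prediction minus baseline.
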