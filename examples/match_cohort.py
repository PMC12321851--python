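"""One-to-one case/control matching on standardized covariates.

Cases are paired to the nearest controls in z-scored covariate space by
Hungarian assignment; the balance report shows per-covariate standardized
mean differences and paired t-tests after matching.
"""

from cagnet import SimConfig, simulate_cohort
from cagnet.matching import balance_report, match, pairwise_distances, standardize
from cagnet.simulate import CovariateSpec

# Plant a strong age confounder (cases 1.5 SD older) to show matching at work.
covs = (CovariateSpec("age", "normal", (46.0, 15.0), association=1.5),
        CovariateSpec("bmi", "normal", (24.5, 4.0)),
        CovariateSpec("sex", "binary", (0.45,)))
config = SimConfig(n_cases=150, n_controls=300, covariates=covs, seed=3)
data = simulate_cohort(config)
meta = data["metadata"]

std = standardize(meta[["age", "bmi", "sex"]])
grp = meta["group"].reindex(std.sample_ids)
dmat = pairwise_distances(std.values[(grp == "case").to_numpy()],
                          std.values[(grp == "control").to_numpy()])
cohort = match(dmat, algorithm="optimal")
report = balance_report(cohort, meta[["age", "bmi", "sex"]])

print(f"matched {len(cohort)} pairs, total distance {cohort.total_distance:.2f}")
print(report[["smd", "p_value"]].round(4).to_string())

# Pre-matching the age SMD is ~1.5 by construction; after one-to-one
# matching against a 2x control pool it shrinks substantially, and the
# paired t-tests show how much residual imbalance remains.
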