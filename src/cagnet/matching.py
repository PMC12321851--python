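"""One-to-one case/control matching on standardized covariates.

Cases are paired to controls by Euclidean distance in z-scored covariate
space, either greedily (repeatedly take the globally closest remaining
pair) or optimally (Hungarian assignment minimizing total distance).
Balance of the matched cohort is reported as per-covariate standardized
mean differences and paired t-tests; subtype comparability as one-way
ANOVA across subtype strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .stats import TestResult, anova_oneway, paired_t

__all__ = [
    "CovariateMatrix",
    "MatchedCohort",
    "standardize",
    "pairwise_distances",
    "match",
    "balance_report",
    "subtype_anova",
    "DEFAULT_CODEBOOK",
]

#: Default ordinal codebook for categorical matching covariates.
#: Sex is coded 1 = male, 0 = female.
DEFAULT_CODEBOOK = {
    "sex": {"female": 0, "male": 1, "0": 0, "1": 1, 0: 0, 1: 1},
}


@dataclass
class CovariateMatrix:
    """Z-scored covariates with the standardization record kept for audit."""

    values: pd.DataFrame  # samples x covariates, standardized
    means: pd.Series
    sds: pd.Series
    dropped: list = field(default_factory=list)  # constant covariates removed

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class MatchedCohort:
    """Ordered case/control pairs with their matching distances."""

    pairs: pd.DataFrame  # columns: case_id, control_id, distance
    unmatched_cases: list
    algorithm: str

    @property
    def total_distance(self) -> float:
        return float(self.pairs["distance"].sum())

    def __len__(self) -> int:
        return len(self.pairs)


def _encode(raw: pd.DataFrame, codebook: dict | None) -> pd.DataFrame:
    codebook = {**DEFAULT_CODEBOOK, **(codebook or {})}
    out = {}
    for col in raw.columns:
        s = raw[col]
        if s.dtype == object or str(s.dtype) == "category":
            book = codebook.get(col)
            if book is None:
                raise ValueError(f"covariate {col!r} is non-numeric and has no codebook")
            try:
                s = s.map(lambda v: book[v])
            except KeyError as e:
                bad = s.index[~s.isin(book)].tolist()[:3]
                raise ValueError(
                    f"covariate {col!r}: value {e.args[0]!r} has no codebook entry "
                    f"(samples {bad})") from None
        out[col] = pd.to_numeric(s)
    return pd.DataFrame(out, index=raw.index)


def standardize(raw: pd.DataFrame, codebook: dict | None = None) -> CovariateMatrix:
    """Center and scale each covariate to mean 0, variance 1 (sample sd, n-1).

    Standardization is over the pooled case+control sample. Rows with any
    missing covariate are excluded (and recorded); constant covariates are
    dropped with a warning.
    """
    enc = _encode(raw, codebook)
    complete = enc.dropna(axis=0)
    n_dropped_rows = len(enc) - len(complete)
    if n_dropped_rows:
        warnings.warn(f"excluded {n_dropped_rows} samples with missing covariates")
    means = complete.mean()
    sds = complete.std(ddof=1)
    dropped = list(sds.index[sds == 0])
    if dropped:
        warnings.warn(f"dropped constant covariates: {dropped}")
    keep = [c for c in complete.columns if c not in dropped]
    z = (complete[keep] - means[keep]) / sds[keep]
    return CovariateMatrix(values=z, means=means[keep], sds=sds[keep], dropped=dropped)


def pairwise_distances(cases: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix (cases x controls) on shared covariates."""
    if list(cases.columns) != list(controls.columns):
        controls = controls[cases.columns]  # raises KeyError on true mismatch
    d = cdist(cases.to_numpy(float), controls.to_numpy(float), metric="euclidean")
    return pd.DataFrame(d, index=cases.index, columns=controls.index)


def match(
    distances: pd.DataFrame,
    algorithm: str = "optimal",
    strata: tuple[pd.Series, pd.Series] | None = None,
) -> MatchedCohort:
    """Pair each case with a distinct control.

    ``algorithm='greedy'`` repeatedly removes the globally smallest
    remaining (case, control) distance, ties broken by lowest case index
    then lowest control index. ``'optimal'`` solves the assignment problem
    minimizing total distance. With ``strata=(case_labels, control_labels)``
    cross-stratum pairs are forbidden (distance set to infinity).
    """
    d = distances.to_numpy(float).copy()
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be finite")
    if strata is not None:
        cs = strata[0].reindex(distances.index).to_numpy()
        ks = strata[1].reindex(distances.columns).to_numpy()
        d[cs[:, None] != ks[None, :]] = np.inf

    case_ids, control_ids = distances.index, distances.columns
    rows: list[tuple] = []
    if algorithm == "greedy":
        work = d.copy()
        n_pairs = min(work.shape)
        for _ in range(n_pairs):
            i, j = np.unravel_index(np.argmin(work), work.shape)
            if not np.isfinite(work[i, j]):
                break
            rows.append((case_ids[i], control_ids[j], float(d[i, j])))
            work[i, :] = np.inf
            work[:, j] = np.inf
    elif algorithm == "optimal":
        solve = d.copy()
        if np.isinf(solve).any():  # keep the LP feasible; prune after
            big = 1e9
            solve[np.isinf(solve)] = big
        ri, ci = linear_sum_assignment(solve)
        for i, j in zip(ri, ci):
            if np.isfinite(d[i, j]):
                rows.append((case_ids[i], control_ids[j], float(d[i, j])))
        rows.sort(key=lambda t: list(case_ids).index(t[0]))
    else:
        raise ValueError(f"unknown matching algorithm {algorithm!r}")

    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    matched_cases = set(pairs["case_id"])
    unmatched = [c for c in case_ids if c not in matched_cases]
    return MatchedCohort(pairs=pairs, unmatched_cases=unmatched, algorithm=algorithm)


def _smd(case_vals: np.ndarray, control_vals: np.ndarray) -> float:
    """Standardized mean difference with pooled (n-1) sd."""
    diff = case_vals.mean() - control_vals.mean()
    pooled = np.sqrt((case_vals.var(ddof=1) + control_vals.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf
    return float(diff / pooled)


def balance_report(
    cohort: MatchedCohort,
    covariates: pd.DataFrame,
    codebook: dict | None = None,
) -> pd.DataFrame:
    """Per-covariate balance of the matched cohort.

    One row per covariate: standardized mean difference (case minus
    control over pooled sd) and the paired t-test p-value over matched
    pairs. Fewer than 3 pairs, or zero-variance differences, yield NaN p
    with the undefined flag set.
    """
    if len(cohort.pairs) == 0:
        raise ValueError("no matched pairs to report on")
    enc = _encode(covariates, codebook)
    case_m = enc.loc[cohort.pairs["case_id"]].to_numpy(float)
    ctrl_m = enc.loc[cohort.pairs["control_id"]].to_numpy(float)
    rows = []
    for k, name in enumerate(enc.columns):
        res: TestResult = paired_t(case_m[:, k] - ctrl_m[:, k])
        rows.append({
            "covariate": name,
            "smd": _smd(case_m[:, k], ctrl_m[:, k]),
            "t_statistic": res.statistic,
            "p_value": res.p_value,
            "undefined": res.undefined,
            "n_pairs": len(cohort.pairs),
        })
    return pd.DataFrame(rows).set_index("covariate")


def subtype_anova(
    covariates: pd.DataFrame,
    subtype_labels: pd.Series,
    codebook: dict | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of each covariate across subtype groups."""
    enc = _encode(covariates, codebook)
    labels = subtype_labels.reindex(enc.index)
    groups = [g for _, g in enc.groupby(labels)]
    rows = []
    for name in enc.columns:
        res = anova_oneway(*[g[name].to_numpy(float) for g in groups])
        rows.append({"covariate": name, "f_statistic": res.statistic,
                     "p_value": res.p_value, "undefined": res.undefined})
    return pd.DataFrame(rows).set_index("covariate")
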