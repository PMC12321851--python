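"""Co-abundance group (CAG) construction and differential analysis.

Genera surviving prevalence/abundance filters are correlated pairwise
(Spearman), multiplicity-corrected (Benjamini-Hochberg within cohort
group), and thresholded into a co-abundance network. The pooled
(case+control) correlation matrix, turned into the distance d = 1 - rho,
is clustered with Ward linkage and cut into k CAGs. Per-CAG mean (or
summed) relative abundance feeds the disease-vs-control Wilcoxon
contrasts and the downstream classifier.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import TestResult, bh_adjust, significance_stars, wilcoxon_ranksum

__all__ = [
    "FilterRules",
    "CorrelationNetwork",
    "CagPartition",
    "filter_low_count_features",
    "filter_genera",
    "spearman_matrix",
    "build_network",
    "cluster_cags",
    "cag_abundance",
    "cag_differential",
    "genus_venn",
]


@dataclass(frozen=True)
class FilterRules:
    """Feature-retention thresholds for count and relative-abundance tables."""

    min_sample_presence: int = 30
    min_total_reads: int = 10
    min_prevalence_fraction: float = 0.20
    min_mean_rel_abundance: float = 0.0005

    def __post_init__(self):
        if self.min_sample_presence < 0 or self.min_total_reads < 0:
            raise ValueError("count thresholds must be nonnegative")
        if not (0 <= self.min_prevalence_fraction <= 1):
            raise ValueError("prevalence fraction must lie in [0, 1]")
        if self.min_mean_rel_abundance < 0:
            raise ValueError("mean abundance threshold must be nonnegative")


@dataclass
class CorrelationNetwork:
    """Thresholded Spearman co-abundance network for one cohort group."""

    group: str
    nodes: pd.DataFrame     # index genus, column mean_abundance
    edges: pd.DataFrame     # source, target, rho, p, q, sign (i < j canonical)
    rho: pd.DataFrame       # full unthresholded correlation matrix
    threshold: float
    positive_only: bool
    excluded: list = field(default_factory=list)  # constant genera

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        for genus, row in self.nodes.iterrows():
            g.add_node(genus, mean_abundance=float(row["mean_abundance"]))
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], rho=float(e["rho"]),
                       p=float(e["p"]), q=float(e["q"]))
        return g


@dataclass
class CagPartition:
    """Genus -> CAG assignment from Ward clustering of 1 - rho distances."""

    assignment: pd.Series       # genus -> cag id (1..k)
    k: int
    linkage_method: str
    size_bounds: tuple[int, int] = (2, 10)

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def size_bound_report(self) -> pd.DataFrame:
        lo, hi = self.size_bounds
        sizes = self.sizes
        return pd.DataFrame({
            "size": sizes,
            "within_bounds": (sizes >= lo) & (sizes <= hi),
        })

    def members(self, cag: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cag])


def filter_low_count_features(
    counts: pd.DataFrame,
    rules: FilterRules = FilterRules(),
    exclusion_rule: str = "both",
) -> pd.DataFrame:
    """Drop low-count features from a samples x features read-count table.

    Default ``exclusion_rule='both'``: a feature is removed only if it is
    present in fewer than ``min_sample_presence`` samples AND its total
    reads fall below ``min_total_reads`` (so passing either threshold keeps
    it). ``'any'`` removes a feature failing either threshold.
    """
    arr = counts.to_numpy()
    if arr.size and ((arr < 0).any() or not np.allclose(arr, np.round(arr))):
        raise ValueError("expected a nonnegative integer count table")
    presence = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    ok_presence = presence >= rules.min_sample_presence
    ok_reads = totals >= rules.min_total_reads
    if exclusion_rule == "both":
        keep = ok_presence | ok_reads
    elif exclusion_rule == "any":
        keep = ok_presence & ok_reads
    else:
        raise ValueError(f"unknown exclusion_rule {exclusion_rule!r}")
    return counts.loc[:, keep]


def filter_genera(table: pd.DataFrame, rules: FilterRules = FilterRules()) -> pd.DataFrame:
    """Keep genera present in >= 20% of samples with mean abundance >= 0.05%.

    Surviving columns keep their original (pre-filter) relative abundances;
    rows are not re-closed, so row sums drop below 1 by the removed mass.
    """
    prevalence = (table > 0).mean(axis=0)
    mean_ab = table.mean(axis=0)
    keep = (prevalence >= rules.min_prevalence_fraction) & \
           (mean_ab >= rules.min_mean_rel_abundance)
    return table.loc[:, keep]


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and t-approximation p for a samples x features table.

    Constant columns get NaN rho/p against everything (flagged by caller).
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    ranks = table.rank(axis=0).to_numpy()
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - ranks.mean(axis=0)) / sd
        rho = (z.T @ z) / n
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    cols = table.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def build_network(
    table: pd.DataFrame,
    group: str = "cohort",
    threshold: float = 0.4,
    positive_only: bool = True,
    q_cutoff: float = 0.05,
) -> CorrelationNetwork:
    """Thresholded Spearman co-abundance network for one cohort group.

    All genus pairs are correlated; BH correction runs over the full set of
    pairs within this group; an edge is retained when q < ``q_cutoff`` and
    rho > ``threshold`` (``positive_only``) or |rho| > ``threshold``.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 genera")
    rho_df, p_df = spearman_matrix(table)
    genera = list(table.columns)
    constant = [g for g in genera if table[g].nunique() <= 1]
    if constant:
        warnings.warn(f"constant genera excluded from edges: {constant}")

    pairs = [(i, j) for i, j in itertools.combinations(range(len(genera)), 2)
             if genera[i] not in constant and genera[j] not in constant]
    rho_v = np.array([rho_df.iat[i, j] for i, j in pairs])
    p_v = np.array([p_df.iat[i, j] for i, j in pairs])
    q_v = bh_adjust(p_v) if len(p_v) else np.array([])

    keep = (q_v < q_cutoff)
    keep &= (rho_v > threshold) if positive_only else (np.abs(rho_v) > threshold)
    edges = pd.DataFrame(
        [(genera[i], genera[j], rho_v[k], p_v[k], q_v[k], int(np.sign(rho_v[k])))
         for k, (i, j) in enumerate(pairs) if keep[k]],
        columns=["source", "target", "rho", "p", "q", "sign"],
    )
    nodes = pd.DataFrame({"mean_abundance": table.mean(axis=0)})
    return CorrelationNetwork(group=group, nodes=nodes, edges=edges, rho=rho_df,
                              threshold=threshold, positive_only=positive_only,
                              excluded=constant)


def cluster_cags(
    rho: pd.DataFrame,
    k: int = 8,
    size_bounds: tuple[int, int] = (2, 10),
) -> CagPartition:
    """Ward-cluster the pooled correlation matrix into k CAGs.

    Distance is d = 1 - rho on the full (unthresholded) matrix, Ward.D2
    linkage, tree cut at k clusters. CAG ids are relabelled 1..k in order
    of first appearance along the genus axis, so the partition is
    deterministic and invariant to scipy's internal label order. Size-bound
    violations are reported by :meth:`CagPartition.size_bound_report`, not
    enforced.
    """
    if rho.shape[0] != rho.shape[1] or not (rho.index == rho.columns).all():
        raise ValueError("expected a square correlation matrix with matching labels")
    if k > rho.shape[0]:
        raise ValueError(f"k={k} exceeds number of genera ({rho.shape[0]})")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = 1.0 - rho.to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assignment = pd.Series([relabel[v] for v in labels], index=rho.index, name="cag")
    return CagPartition(assignment=assignment, k=k, linkage_method="ward.D2(1-rho)",
                        size_bounds=size_bounds)


def cag_abundance(
    table: pd.DataFrame,
    partition: CagPartition,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-sample CAG abundance: mean or sum of member-genus abundances."""
    missing = [g for g in table.columns if g not in partition.assignment.index]
    if missing:
        raise ValueError(f"genera absent from partition: {missing[:5]}")
    if summary not in ("mean", "sum"):
        raise ValueError("summary must be 'mean' or 'sum'")
    out = {}
    for cag in sorted(partition.assignment.unique()):
        members = [g for g in partition.members(cag) if g in table.columns]
        sub = table[members]
        out[f"CAG{cag}"] = sub.mean(axis=1) if summary == "mean" else sub.sum(axis=1)
    return pd.DataFrame(out, index=table.index)


def cag_differential(
    cag_table: pd.DataFrame,
    labels: pd.Series,
    case_label: str = "case",
) -> pd.DataFrame:
    """Wilcoxon rank-sum per CAG, disease vs control, with direction and stars."""
    lab = labels.reindex(cag_table.index)
    is_case = (lab == case_label).to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for cag in cag_table.columns:
        a = cag_table.loc[is_case, cag].to_numpy()
        b = cag_table.loc[~is_case, cag].to_numpy()
        res: TestResult = wilcoxon_ranksum(a, b, mode="approx")
        rows.append({
            "cag": cag,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "direction": "up" if a.mean() > b.mean() else "down",
            "case_mean": a.mean(),
            "control_mean": b.mean(),
            "stars": significance_stars(res.p_value),
        })
    return pd.DataFrame(rows).set_index("cag")


def genus_venn(named_sets: dict[str, set]) -> dict[str, int]:
    """Counts of every intersection region over 2 or 3 genus sets.

    Keys are '+'-joined sorted name combinations; each region is exclusive
    (members of exactly that combination of sets).
    """
    names = sorted(named_sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("venn supports 2 or 3 sets")
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            out["+".join(combo)] = len(inside - outside)
    return out
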