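"""Genus-pathway association and focal-pathway contrasts.

Each genus is Spearman-correlated with each predicted metabolic pathway
within a cohort group; pairs with |rho| above a threshold (default 0.2)
form a bipartite co-abundance network. Pathways are grouped into
hierarchical categories, and for every (CAG, category) cell the disease
and control distributions of the *unthresholded* genus x pathway rho
values are compared by Wilcoxon rank-sum — thresholding shapes the network
only, so the two groups contribute equal-length, selection-free vectors.
Focal pathway groups (e.g. acetate/propionate/butyrate biosynthesis,
LPS-associated, tryptophan-associated) are tested by paired t over the
matched cohort on group-summed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, paired_t, significance_stars, wilcoxon_ranksum
from .cag import CagPartition, spearman_matrix
from .matching import MatchedCohort

__all__ = [
    "PathwayCategoryMap",
    "BipartiteNetwork",
    "AssociationCell",
    "genus_pathway_network",
    "cell_tests",
    "focal_pathway_paired_test",
]


@dataclass
class PathwayCategoryMap:
    """Pathway -> category labels plus named focal pathway groups."""

    categories: pd.Series                     # pathway id -> category label
    focal_groups: dict[str, list[str]] | None = None

    def __post_init__(self):
        self.focal_groups = dict(self.focal_groups or {})
        known = set(self.categories.index)
        for name, members in self.focal_groups.items():
            missing = [m for m in members if m not in known]
            if missing:
                raise ValueError(f"focal group {name!r} lists unknown pathways {missing}")

    def validate_against(self, pathway_table: pd.DataFrame) -> None:
        missing = [p for p in pathway_table.columns if p not in self.categories.index]
        if missing:
            raise ValueError(f"pathways without a category: {missing[:5]}")

    def pathways_in(self, category: str) -> list[str]:
        return list(self.categories.index[self.categories == category])


@dataclass
class BipartiteNetwork:
    """Genus x pathway Spearman associations for one cohort group."""

    group: str
    rho: pd.DataFrame    # genera x pathways, unthresholded
    p: pd.DataFrame
    edges: pd.DataFrame  # genus, pathway, rho, p, sign where |rho| > threshold
    threshold: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        g.add_nodes_from(self.rho.index, bipartite="genus")
        g.add_nodes_from(self.rho.columns, bipartite="pathway")
        for _, e in self.edges.iterrows():
            g.add_edge(e["genus"], e["pathway"], rho=float(e["rho"]), p=float(e["p"]))
        return g


@dataclass
class AssociationCell:
    """One (CAG, category) cell of the disease-vs-control rho comparison."""

    cag: int
    category: str
    rho_disease: np.ndarray
    rho_control: np.ndarray
    test: TestResult | None
    empty: bool = False

    @property
    def mean_rho_disease(self) -> float:
        return float(np.nanmean(self.rho_disease)) if self.rho_disease.size else np.nan

    @property
    def mean_rho_control(self) -> float:
        return float(np.nanmean(self.rho_control)) if self.rho_control.size else np.nan

    @property
    def shift(self) -> float:
        return self.mean_rho_disease - self.mean_rho_control


def genus_pathway_network(
    genus_table: pd.DataFrame,
    pathway_table: pd.DataFrame,
    group: str = "cohort",
    threshold: float = 0.2,
) -> BipartiteNetwork:
    """Spearman-correlate every genus with every pathway; keep |rho| > threshold.

    Both positive and negative associations are retained (sign kept).
    """
    if set(genus_table.index) != set(pathway_table.index):
        only_g = sorted(set(genus_table.index) - set(pathway_table.index))[:5]
        only_p = sorted(set(pathway_table.index) - set(genus_table.index))[:5]
        raise ValueError(
            f"sample id mismatch between tables (genus-only: {only_g}, pathway-only: {only_p})")
    pathway_table = pathway_table.loc[genus_table.index]
    combined = pd.concat([genus_table, pathway_table], axis=1)
    rho_all, p_all = spearman_matrix(combined)
    g_ids, p_ids = list(genus_table.columns), list(pathway_table.columns)
    rho = rho_all.loc[g_ids, p_ids]
    p = p_all.loc[g_ids, p_ids]

    mask = rho.abs().to_numpy() > threshold
    gi, pj = np.nonzero(mask)
    edges = pd.DataFrame({
        "genus": [g_ids[i] for i in gi],
        "pathway": [p_ids[j] for j in pj],
        "rho": rho.to_numpy()[gi, pj],
        "p": p.to_numpy()[gi, pj],
        "sign": np.sign(rho.to_numpy()[gi, pj]).astype(int),
    })
    return BipartiteNetwork(group=group, rho=rho, p=p, edges=edges, threshold=threshold)


def cell_tests(
    disease: BipartiteNetwork,
    control: BipartiteNetwork,
    partition: CagPartition,
    catmap: PathwayCategoryMap,
    bh_across_cells: bool = False,
) -> pd.DataFrame:
    """Disease-vs-control Wilcoxon on rho values per (CAG, category) cell.

    Each cell collects the unthresholded rho of every member-genus x
    category-pathway pair from both groups (equal-length vectors by
    construction) and compares them by rank-sum. Cells whose CAG has no
    genus or whose category has no pathway are marked empty. Raw p-values
    are reported by default; ``bh_across_cells`` adds a q column.
    """
    if list(disease.rho.index) != list(control.rho.index) or \
       list(disease.rho.columns) != list(control.rho.columns):
        raise ValueError("disease and control networks must share the same genus/pathway universe")
    rows = []
    cells: list[AssociationCell] = []
    for cag in sorted(partition.assignment.unique()):
        genera = [g for g in partition.members(cag) if g in disease.rho.index]
        for category in sorted(catmap.categories.unique()):
            pwys = [p for p in catmap.pathways_in(category) if p in disease.rho.columns]
            if not genera or not pwys:
                cells.append(AssociationCell(cag, category, np.array([]), np.array([]),
                                             None, empty=True))
                continue
            rd = disease.rho.loc[genera, pwys].to_numpy().ravel()
            rc = control.rho.loc[genera, pwys].to_numpy().ravel()
            rd, rc = rd[~np.isnan(rd)], rc[~np.isnan(rc)]
            if rd.size < 2 or rc.size < 2:
                cells.append(AssociationCell(cag, category, rd, rc, None, empty=True))
                continue
            res = wilcoxon_ranksum(rd, rc, mode="approx")
            cells.append(AssociationCell(cag, category, rd, rc, res))
    for c in cells:
        rows.append({
            "cag": c.cag,
            "category": c.category,
            "n_pairs": int(c.rho_disease.size),
            "mean_rho_disease": c.mean_rho_disease,
            "mean_rho_control": c.mean_rho_control,
            "shift": c.shift if not c.empty else np.nan,
            "p_value": c.test.p_value if c.test is not None else np.nan,
            "empty": c.empty,
            "stars": c.test.stars if c.test is not None else "na",
        })
    out = pd.DataFrame(rows)
    if bh_across_cells:
        valid = ~out["empty"]
        q = np.full(len(out), np.nan)
        q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p_value"].to_numpy())
        out["q_value"] = q
    return out


def focal_pathway_paired_test(
    pathway_table: pd.DataFrame,
    cohort: MatchedCohort,
    focal_group: str,
    catmap: PathwayCategoryMap,
    mode: str = "sum",
) -> TestResult:
    """Paired t-test on a focal pathway group over matched case/control pairs.

    ``mode='sum'`` (default) sums the group's member pathway abundances per
    sample before differencing; ``mode='per_pathway'`` returns the test on
    the per-pathway mean instead of the sum. Pairs with a missing member
    are dropped with a warning.
    """
    members = (catmap.focal_groups or {}).get(focal_group)
    if not members:
        raise ValueError(f"unknown or empty focal group {focal_group!r}")
    cols = [m for m in members if m in pathway_table.columns]
    if not cols:
        raise ValueError(f"no pathways of focal group {focal_group!r} present in table")
    agg = pathway_table[cols].sum(axis=1) if mode == "sum" \
        else pathway_table[cols].mean(axis=1)

    pairs = cohort.pairs
    present = pairs["case_id"].isin(agg.index) & pairs["control_id"].isin(agg.index)
    if not present.all():
        import warnings
        warnings.warn(f"dropped {int((~present).sum())} pairs with missing samples")
    pairs = pairs[present]
    diffs = agg.loc[pairs["case_id"]].to_numpy() - agg.loc[pairs["control_id"]].to_numpy()
    return paired_t(diffs)
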