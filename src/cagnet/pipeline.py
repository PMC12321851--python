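"""End-to-end orchestration of the per-subtype co-abundance workflow.

`run_pipeline` chains the stages — (simulate or load) -> cohort matching ->
genus filtering -> co-abundance networks -> CAG clustering -> differential
tests -> pathway association -> classifier + Shapley — and writes every
stage's tables plus a manifest (parameters, seeds, interpretation switches,
package version) sufficient to regenerate the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as cio
from .cag import (FilterRules, build_network, cag_abundance, cag_differential,
                  cluster_cags, filter_genera, spearman_matrix)
from .classify import (RfProtocol, ShapProtocol, fit_evaluate, shap_group_summary,
                       shapley_mc)
from .matching import balance_report, match, pairwise_distances, standardize
from .pathways import PathwayCategoryMap, cell_tests, genus_pathway_network
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

#: Covariates used for matching when present in the metadata.
MATCHING_COVARIATES = (
    "age", "bmi", "height_cm", "weight_kg", "sex", "geography",
    "alcohol_frequency", "vegetable_frequency", "meat_egg_frequency",
    "whole_grain_frequency",
)


@dataclass
class RunConfig:
    """Everything one subtype run needs; either file paths or a SimConfig."""

    genus_path: str | None = None
    metadata_path: str | None = None
    pathway_path: str | None = None
    category_path: str | None = None
    simulate: SimConfig | None = None
    subtype: str = "IBS-D"
    out_dir: str | None = None
    matching_algorithm: str = "optimal"
    edge_threshold: float = 0.4
    pathway_threshold: float = 0.2
    k_cags: int = 8
    positive_only: bool = True
    filter_rules: FilterRules = field(default_factory=FilterRules)
    rf: RfProtocol = field(default_factory=RfProtocol)
    shap: ShapProtocol = field(default_factory=ShapProtocol)
    run_pathways: bool = True
    run_classifier: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.simulate is None and (self.genus_path is None or self.metadata_path is None):
            raise ValueError("provide either simulate=SimConfig or genus/metadata paths")
        if self.edge_threshold <= 0 or self.pathway_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.k_cags < 1:
            raise ValueError("k_cags must be >= 1")


@dataclass
class PipelineResult:
    """Result bundle; every element also lands on disk when out_dir is set."""

    cohort: object
    balance: pd.DataFrame
    filtered_genus: pd.DataFrame
    network_disease: object
    network_control: object
    partition: object
    size_report: pd.DataFrame
    cag_means: pd.DataFrame
    differential: pd.DataFrame
    pathway_cells: pd.DataFrame | None
    evaluation: object | None
    shap: object | None
    shap_summary: pd.DataFrame | None
    manifest: dict


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
        data = simulate_cohort(sim)
        catmap = PathwayCategoryMap(categories=data["categories"])
        return data["genus"], data["metadata"], data["pathways"], catmap, sim
    genus = cio.read_abundance(config.genus_path)
    meta = cio.read_metadata(config.metadata_path)
    pathways = catmap = None
    if config.pathway_path:
        pathways = cio.read_abundance(config.pathway_path)
        cats = cio.read_metadata(config.category_path).iloc[:, 0]
        catmap = PathwayCategoryMap(categories=cats)
    return genus, meta, pathways, catmap, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full per-subtype workflow and return the result bundle."""
    out = Path(config.out_dir) if config.out_dir else None
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "subtype": config.subtype,
        "stages": [],
        "parameters": {
            "matching_algorithm": config.matching_algorithm,
            "edge_threshold": config.edge_threshold,
            "pathway_threshold": config.pathway_threshold,
            "k_cags": config.k_cags,
            "positive_only_edges": config.positive_only,
            "filter_rules": dataclasses.asdict(config.filter_rules),
            "rf": dataclasses.asdict(config.rf),
            "shap": dataclasses.asdict(config.shap),
            "interpretation": {
                "low_count_exclusion_rule": "both-thresholds-failed",
                "clustering_input": "pooled unthresholded Spearman matrix, d=1-rho, ward.D2",
                "cell_rho": "unthresholded",
                "shap_sample_size_reading": "monte-carlo permutations per instance",
            },
        },
    }
    genus, meta, pathways, catmap, sim = _load_inputs(config)
    if sim is not None:
        manifest["parameters"]["simulate"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim).items() if k != "covariates"
        }
    manifest["stages"].append("load")

    # --- matching ------------------------------------------------------
    covs = [c for c in MATCHING_COVARIATES if c in meta.columns]
    if not covs:
        raise RuntimeError("stage 'matching': no matching covariates found in metadata")
    std = standardize(meta[covs])
    grp = meta["group"].reindex(std.sample_ids)
    dmat = pairwise_distances(std.values.loc[(grp == "case").to_numpy()],
                              std.values.loc[(grp == "control").to_numpy()])
    cohort = match(dmat, algorithm=config.matching_algorithm)
    balance = balance_report(cohort, meta[covs])
    manifest["stages"].append("matching")

    # --- genus filter + networks + CAGs --------------------------------
    filtered = filter_genera(genus, config.filter_rules)
    if filtered.shape[1] < max(2, config.k_cags):
        raise RuntimeError("stage 'cags': too few genera survive filtering")
    case_ids = cohort.pairs["case_id"]
    ctrl_ids = cohort.pairs["control_id"]
    net_d = build_network(filtered.loc[case_ids], group=config.subtype,
                          threshold=config.edge_threshold,
                          positive_only=config.positive_only)
    net_c = build_network(filtered.loc[ctrl_ids], group="non-IBS",
                          threshold=config.edge_threshold,
                          positive_only=config.positive_only)
    pooled = filtered.loc[list(case_ids) + list(ctrl_ids)]
    rho_pooled, _ = spearman_matrix(pooled)
    partition = cluster_cags(rho_pooled, k=config.k_cags)
    size_report = partition.size_bound_report()
    if not size_report["within_bounds"].all():
        warnings.warn("CAG size-bound violations: "
                      f"{size_report[~size_report['within_bounds']].index.tolist()}")
    cag_means = cag_abundance(pooled, partition, summary="mean")
    group_labels = meta["group"].reindex(pooled.index)
    differential = cag_differential(cag_means, group_labels)
    manifest["stages"].append("cags")

    # --- pathway association -------------------------------------------
    cells = None
    if config.run_pathways and pathways is not None:
        catmap.validate_against(pathways)
        bip_d = genus_pathway_network(filtered.loc[case_ids], pathways.loc[case_ids],
                                      group=config.subtype,
                                      threshold=config.pathway_threshold)
        bip_c = genus_pathway_network(filtered.loc[ctrl_ids], pathways.loc[ctrl_ids],
                                      group="non-IBS",
                                      threshold=config.pathway_threshold)
        cells = cell_tests(bip_d, bip_c, partition, catmap)
        manifest["stages"].append("pathways")
    else:
        manifest["stages"].append("pathways:skipped")

    # --- classifier + Shapley ------------------------------------------
    evaluation = attribution = summary = None
    if config.run_classifier:
        cag_sums = cag_abundance(pooled, partition, summary="sum")
        rf = dataclasses.replace(config.rf, seed=config.rf.seed or config.seed)
        evaluation = fit_evaluate(cag_sums, group_labels, rf)
        shap_proto = dataclasses.replace(config.shap, seed=config.shap.seed or config.seed)
        test_feats = cag_sums.iloc[evaluation.test_idx]
        n_explain = min(shap_proto.n_explained, len(test_feats))
        rng_sel = pd.Index(test_feats.index[:n_explain])
        case_col = list(evaluation.model.classes_).index(1)
        predict = lambda a: evaluation.model.predict_proba(a)[:, case_col]  # noqa: E731
        attribution = shapley_mc(predict, test_feats.loc[rng_sel],
                                 cag_sums.iloc[evaluation.train_idx], shap_proto)
        summary = shap_group_summary(attribution, group_labels)
        manifest["stages"].append("classifier")
    else:
        manifest["stages"].append("classifier:skipped")

    result = PipelineResult(
        cohort=cohort, balance=balance, filtered_genus=filtered,
        network_disease=net_d, network_control=net_c, partition=partition,
        size_report=size_report, cag_means=cag_means, differential=differential,
        pathway_cells=cells, evaluation=evaluation, shap=attribution,
        shap_summary=summary, manifest=manifest,
    )
    if out is not None:
        _write_bundle(result, out, config)
    return result


def _write_bundle(result: PipelineResult, out: Path, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cio.write_table(result.cohort.pairs, out / "pairs.tsv", index_label="pair")
    cio.write_table(result.balance, out / "balance.tsv", index_label="covariate")
    cio.write_edges(result.network_disease.edges, out / "edges_disease.tsv")
    cio.write_edges(result.network_control.edges, out / "edges_control.tsv")
    cio.write_graphml(result.network_disease.to_graph(), out / "network_disease.graphml")
    cio.write_graphml(result.network_control.to_graph(), out / "network_control.graphml")
    cio.write_table(result.partition.assignment.to_frame(), out / "partition.tsv",
                    index_label="genus")
    cio.write_table(result.size_report, out / "cag_sizes.tsv", index_label="cag")
    cio.write_table(result.differential, out / "cag_differential.tsv", index_label="cag")
    if result.pathway_cells is not None:
        cio.write_table(result.pathway_cells, out / "pathway_cells.tsv", index_label="cell")
    if result.evaluation is not None:
        cio.write_json(result.evaluation.metrics_dict(), out / "metrics.json")
        cio.write_table(result.evaluation.importance.to_frame(), out / "importance.tsv",
                        index_label="feature")
        cio.write_table(result.evaluation.roc_points, out / "roc_points.tsv",
                        index_label="point")
    if result.shap is not None:
        cio.write_table(result.shap.phi, out / "shap_phi.tsv")
        cio.write_table(result.shap.se, out / "shap_se.tsv")
    cio.write_json(result.manifest, out / "manifest.json")
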