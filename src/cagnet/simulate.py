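"""Synthetic gut-microbiome cohorts with planted co-abundance structure.

The generator emulates the statistical structure of a matched case/control
16S study: compositional genus abundances with block-correlated
("co-abundance group") latent structure, case-group shifts in block mean
abundance, matching covariates optionally associated with group, and a
pathway layer produced as a nonnegative linear map of the genus abundances
plus multiplicative noise (the shape of reference-genome pathway
prediction). Ground truth (block membership, planted effects, contribution
weights) is returned alongside so downstream recovery is testable.

Model: a Gaussian copula with log-normal marginals. Latent z ~ MVN(0, R)
where R has ``within_block_rho`` inside each planted block and
``between_block_rho`` across blocks; background genera (block 0) are
independent in the latent layer. Abundances are exp(mu_g + sigma_g z),
case-group members of an effect block are multiplied by exp(log-fold-change)
before per-sample closure to sum 1. Realized Spearman correlation is
slightly below the latent Pearson value (rank transform of the copula);
closure induces a small negative spillover on non-effect genera. Both are
properties of the model, not bugs, and are asserted loosely in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_genus_table",
    "simulate_metadata",
    "simulate_pathway_table",
    "simulate_cohort",
    "DEFAULT_CATEGORIES",
]

#: Metabolic-pathway categories used for round-robin assignment.
DEFAULT_CATEGORIES = (
    "energy metabolism",
    "carbohydrate metabolism",
    "amino acid metabolism",
    "lipid metabolism",
    "nucleic acid metabolism",
    "vitamin and cofactor metabolism",
)

# Named substreams derived from the one global seed, so each layer can be
# regenerated independently without disturbing the others.
_STREAMS = {"table": 1, "metadata": 2, "pathways": 3, "baseline": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class CovariateSpec:
    """One matching covariate: its marginal law and group association.

    kind 'normal'  -> params (mean, sd); association shifts the case mean by
                      ``association * sd``.
    kind 'binary'  -> params (p,); association adds to the case probability.
    kind 'ordinal' -> params (n_levels,); latent-normal thresholded into
                      equiprobable levels 0..n_levels-1; association shifts
                      the case latent mean (in SD units).
    """

    name: str
    kind: str = "normal"
    params: tuple = (0.0, 1.0)
    association: float = 0.0

    def __post_init__(self):
        if self.kind not in ("normal", "binary", "ordinal"):
            raise ValueError(f"unknown covariate family {self.kind!r} for {self.name!r}")


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # Marginals loosely calibrated to an adult self-selected cohort.
    return (
        CovariateSpec("age", "normal", (46.0, 15.0)),
        CovariateSpec("bmi", "normal", (24.5, 4.0)),
        CovariateSpec("height_cm", "normal", (169.0, 9.5)),
        CovariateSpec("weight_kg", "normal", (71.0, 14.0)),
        CovariateSpec("sex", "binary", (0.45,)),
        CovariateSpec("geography", "ordinal", (3,)),
        CovariateSpec("alcohol_frequency", "ordinal", (5,)),
        CovariateSpec("vegetable_frequency", "ordinal", (5,)),
        CovariateSpec("meat_egg_frequency", "ordinal", (5,)),
        CovariateSpec("whole_grain_frequency", "ordinal", (5,)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated matched cohort.

    Defaults mirror the largest study arm this package targets: 365 cases
    and 365 controls, 44 genera partitioned into 8 co-abundance blocks of
    sizes 9..2, strong within-block latent correlation (0.8), and planted
    case effects on three blocks (one up, two down).
    """

    n_cases: int = 365
    n_controls: int = 365
    n_genera: int = 44
    n_blocks: int = 8
    block_sizes: tuple[int, ...] = (9, 8, 7, 6, 5, 4, 3, 2)
    within_block_rho: float = 0.8
    between_block_rho: float = 0.0
    effect_blocks: dict = field(default_factory=lambda: {3: 0.5, 1: -0.4, 2: -0.4})
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    subtype: str = "IBS-D"
    n_pathways: int = 60
    contrib_density: float = 0.10
    pathway_noise_sd: float = 0.3
    log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, 0) < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.n_genera <= 0 or self.n_pathways <= 0:
            raise ValueError("feature counts must be positive")
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        if sum(self.block_sizes) > self.n_genera:
            raise ValueError("sum(block_sizes) exceeds n_genera")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must lie in [0, 1)")
        if self.within_block_rho <= self.between_block_rho:
            raise ValueError("within_block_rho must exceed between_block_rho")
        bad = [b for b in self.effect_blocks if not (1 <= b <= self.n_blocks)]
        if bad:
            raise ValueError(f"effect_blocks refer to unknown blocks {bad}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class GroundTruth:
    """Planted structure: what the pipeline should recover."""

    block_assignment: pd.Series  # genus id -> block id, 0 = background
    effect_blocks: dict
    contribution_matrix: pd.DataFrame | None = None  # genera x pathways, >= 0

    def block_members(self, block: int) -> list[str]:
        return list(self.block_assignment.index[self.block_assignment == block])


def _block_correlation(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Latent correlation matrix and genus->block assignment vector."""
    g = config.n_genera
    assign = np.zeros(g, dtype=int)
    pos = 0
    for b, size in enumerate(config.block_sizes, start=1):
        assign[pos:pos + size] = b
        pos += size
    r = np.eye(g)
    structured = assign > 0
    between = config.between_block_rho
    if between != 0.0:
        r[np.ix_(structured, structured)] = between
    for b in range(1, config.n_blocks + 1):
        idx = np.where(assign == b)[0]
        r[np.ix_(idx, idx)] = config.within_block_rho
    np.fill_diagonal(r, 1.0)
    try:
        np.linalg.cholesky(r + 1e-12 * np.eye(g))
    except np.linalg.LinAlgError:
        raise ValueError(
            "requested latent correlation is not positive definite "
            f"(within_block_rho={config.within_block_rho}, "
            f"between_block_rho={config.between_block_rho})"
        ) from None
    return r, assign


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"case_{i:04d}" for i in range(1, config.n_cases + 1)] + \
           [f"ctrl_{i:04d}" for i in range(1, config.n_controls + 1)]


def simulate_genus_table(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a samples x genera relative-abundance table with planted blocks.

    Returns the closed (rows sum to 1) table and the ground truth. The first
    ``n_cases`` rows are the case group. Deterministic under ``config.seed``.
    """
    corr, assign = _block_correlation(config)
    genera = [f"g{j:03d}" for j in range(1, config.n_genera + 1)]
    samples = _sample_ids(config)

    base_rng = _rng(config.seed, "baseline")
    # Heterogeneous genus baselines give the uneven composition real genus
    # tables have (a few dominant taxa, a long tail).
    mu = base_rng.normal(0.0, 1.5, size=config.n_genera)

    rng = _rng(config.seed, "table")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(config.n_genera))
    z = rng.standard_normal((config.n_samples, config.n_genera)) @ chol.T
    raw = np.exp(mu + config.log_sd * z)

    # Case-group multiplicative shifts, applied before closure.
    if config.n_cases and config.effect_blocks:
        lfc = np.zeros(config.n_genera)
        for block, eff in config.effect_blocks.items():
            lfc[assign == block] = eff
        raw[: config.n_cases] *= np.exp(lfc)

    closed = raw / raw.sum(axis=1, keepdims=True)
    table = pd.DataFrame(closed, index=pd.Index(samples, name="sample_id"),
                         columns=genera)
    truth = GroundTruth(
        block_assignment=pd.Series(assign, index=genera, name="block"),
        effect_blocks=dict(config.effect_blocks),
    )
    return table, truth


def simulate_metadata(config: SimConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample metadata: group, subtype, and matching covariates."""
    rng = _rng(config.seed, "metadata")
    n = len(table.index)
    if n != config.n_samples:
        raise ValueError("table rows do not match SimConfig cohort sizes")
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    meta = pd.DataFrame(index=table.index.copy())
    meta["group"] = np.where(is_case, "case", "control")
    meta["subtype"] = np.where(is_case, config.subtype, "non-IBS")
    for spec in config.covariates:
        if spec.kind == "normal":
            mean, sd = spec.params
            vals = rng.normal(mean, sd, size=n) + spec.association * sd * is_case
        elif spec.kind == "binary":
            (p,) = spec.params
            pv = np.clip(p + spec.association * is_case, 0.0, 1.0)
            vals = (rng.random(n) < pv).astype(int)
        else:  # ordinal via thresholded latent normal, equiprobable levels
            (levels,) = spec.params
            z = rng.standard_normal(n) + spec.association * is_case
            cuts = norm.ppf(np.linspace(0, 1, levels + 1)[1:-1])
            vals = np.searchsorted(cuts, z)
        meta[spec.name] = vals
    return meta


def simulate_pathway_table(
    table: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pathway abundances as a noisy nonnegative linear map of genera.

    pathway = genus_abundances @ contribution_matrix, then multiplied by
    log-normal noise exp(sd * eps). Returns (samples x pathways table,
    pathway -> category map). The contribution matrix is stored on ``truth``.
    """
    rng = _rng(config.seed, "pathways")
    genera = list(table.columns)
    pathways = [f"pwy{j:03d}" for j in range(1, config.n_pathways + 1)]

    if truth.contribution_matrix is None:
        mask = rng.random((len(genera), config.n_pathways)) < config.contrib_density
        # every pathway needs at least one contributing genus
        empty = ~mask.any(axis=0)
        mask[rng.integers(0, len(genera), size=int(empty.sum())), np.where(empty)[0]] = True
        weights = rng.uniform(0.5, 1.5, size=mask.shape) * mask
        truth.contribution_matrix = pd.DataFrame(weights, index=genera, columns=pathways)
    contrib = truth.contribution_matrix
    if list(contrib.index) != genera:
        raise ValueError("contribution matrix rows do not match genus table columns")
    if (contrib.to_numpy() < 0).any():
        raise ValueError("contribution matrix must be nonnegative")

    clean = table.to_numpy() @ contrib.to_numpy()
    if config.pathway_noise_sd > 0:
        clean = clean * np.exp(config.pathway_noise_sd * rng.standard_normal(clean.shape))
    pw = pd.DataFrame(clean, index=table.index.copy(), columns=contrib.columns.copy())
    catmap = pd.Series(
        [categories[j % len(categories)] for j in range(len(pw.columns))],
        index=pw.columns, name="category",
    )
    return pw, catmap


def simulate_cohort(config: SimConfig) -> dict:
    """Convenience: genus table, metadata, pathway table and ground truth."""
    table, truth = simulate_genus_table(config)
    meta = simulate_metadata(config, table)
    pathways, catmap = simulate_pathway_table(table, truth, config)
    return {"genus": table, "metadata": meta, "pathways": pathways,
            "categories": catmap, "truth": truth}
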