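"""Synthetic multi-study data with known ground truth.

Generates everything the prioritization pipeline consumes — paired
tumor/normal expression studies, an interaction network, gene-set
collections, and a clinical cohort — from one seed, with the planted truth
(DEGs, correlation modules, marker gene, hazard ratio) returned alongside
so every stage can be scored offline.

The expression model: per-gene baselines mu_g ~ N(7, 2^2) on the log2
scale; gene precisions 1/sigma_g^2 ~ Gamma(a, b), matching the shrinkage
prior the moderated t-test assumes; planted DEGs shifted by +/- delta in
tumor samples; genes of a planted module share a per-sample latent factor,
gene = lambda * f + sqrt(1 - lambda^2) * eps with lambda = sqrt(rho), so
the expected pairwise correlation is rho. Per-study batch effects are an
additive gene-wise shift ~ N(0, batch_shift_sd^2) plus a multiplicative
LogNormal(0, batch_scale_sd^2) factor on the noise term — the structure the
location/scale batch adjustment removes.

The marker module (the module containing the marker gene) is built at
``module_corr``; the other modules sit ``module_corr_gap`` lower, emulating
a study design where one module clearly carries the top average
correlation. A single root seed spawns independent substreams per study, so
adding a study never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .deg import ExpressionStudy
from .enrich import GeneSetCollection

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_studies",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_clinical",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults emulate a five-cohort paired design
    with a 90-patient validation cohort."""

    n_studies: int = 5
    genes: int = 2000
    pairs_per_study: int = 20
    deg_fraction: float = 0.05
    effect_log2fc: float = 2.0
    variance_prior: tuple[float, float] = (2.0, 1.0)  # (shape a, scale b)
    n_modules: int = 3
    module_size: int = 10
    module_corr: float = 0.95
    module_corr_gap: float = 0.25  # non-marker modules sit this much lower
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    network_background_density: float = 0.002
    module_edge_retention: float = 0.9
    n_patients: int = 90
    true_hr: float = 2.0
    censor_rate: float = 0.25
    covariate_assoc: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_studies", "genes", "pairs_per_study", "n_modules",
                     "module_size", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("deg_fraction", "network_background_density",
                     "module_edge_retention", "censor_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.module_corr < 1:
            raise ValueError("module_corr must lie in [0, 1)")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        a, b = self.variance_prior
        if a <= 0 or b <= 0:
            raise ValueError("variance prior (a, b) must be positive")
        if self.module_size * self.n_modules > self.genes:
            raise ValueError("planted modules cannot exceed the gene universe")


@dataclass
class SimTruth:
    """Planted ground truth: signed DEG effects, module memberships, the
    prognostic marker gene, and its hazard ratio."""

    planted_degs: dict[str, float]  # gene -> signed log2FC effect
    planted_modules: list[tuple[str, ...]]
    marker_gene: str
    true_hr: float
    gene_ids: tuple[str, ...]
    baseline: dict[str, float] = field(default_factory=dict, repr=False)
    sigma: dict[str, float] = field(default_factory=dict, repr=False)


def _streams(config: SimConfig):
    base = np.random.SeedSequence(config.seed)
    truth_ss, studies_ss, network_ss, clinical_ss, sets_ss = base.spawn(5)
    return truth_ss, studies_ss, network_ss, clinical_ss, sets_ss


def _build_truth(config: SimConfig) -> SimTruth:
    truth_ss, *_ = _streams(config)
    rng = np.random.default_rng(truth_ss)
    G = config.genes
    width = max(4, len(str(G)))
    gene_ids = tuple(f"G{i:0{width}d}" for i in range(G))

    a, b = config.variance_prior
    sigma2 = 1.0 / rng.gamma(shape=a, scale=b, size=G)
    baseline = rng.normal(7.0, 2.0, size=G)

    n_deg = int(round(G * config.deg_fraction))
    deg_idx = rng.choice(G, size=n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    planted_degs = {
        gene_ids[i]: float(s * config.effect_log2fc) for i, s in zip(deg_idx, signs)
    }

    # module genes drawn from the planted DEGs first so modules appear in
    # the DEG-induced subnetwork; remaining slots from non-DEG genes
    need = config.n_modules * config.module_size
    pool = list(deg_idx)
    if len(pool) < need:
        others = np.setdiff1d(np.arange(G), deg_idx)
        extra = rng.choice(others, size=need - len(pool), replace=False)
        pool = pool + list(extra)
    chosen = pool[:need]
    modules = [
        tuple(sorted(gene_ids[i] for i in chosen[m * config.module_size:(m + 1) * config.module_size]))
        for m in range(config.n_modules)
    ]
    deg_set = set(planted_degs)
    in_deg = [g for g in modules[0] if g in deg_set]
    marker = in_deg[0] if in_deg else modules[0][0]
    return SimTruth(
        planted_degs=planted_degs,
        planted_modules=modules,
        marker_gene=marker,
        true_hr=config.true_hr,
        gene_ids=gene_ids,
        baseline=dict(zip(gene_ids, baseline)),
        sigma=dict(zip(gene_ids, np.sqrt(sigma2))),
    )


def simulate_studies(config: SimConfig) -> tuple[list[ExpressionStudy], SimTruth]:
    """Generate the paired tumor/normal expression studies plus the truth."""
    truth = _build_truth(config)
    _, studies_ss, *_ = _streams(config)
    study_seeds = studies_ss.spawn(config.n_studies)

    G = config.genes
    gene_ids = list(truth.gene_ids)
    mu = np.array([truth.baseline[g] for g in gene_ids])
    sig = np.array([truth.sigma[g] for g in gene_ids])
    delta = np.array([truth.planted_degs.get(g, 0.0) for g in gene_ids])

    lam = np.zeros(G)
    module_of = np.full(G, -1)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for m, members in enumerate(truth.planted_modules):
        rho = config.module_corr
        if truth.marker_gene not in members:
            rho = max(rho - config.module_corr_gap, 0.0)
        for g in members:
            lam[gene_pos[g]] = np.sqrt(rho)
            module_of[gene_pos[g]] = m

    studies = []
    for s, seed in enumerate(study_seeds):
        rng = np.random.default_rng(seed)
        study_id = f"STUDY{s + 1}"
        n = config.pairs_per_study
        n_samples = 2 * n  # tumor, normal per subject

        shift = rng.normal(0.0, config.batch_shift_sd, size=G)
        scale = rng.lognormal(0.0, config.batch_scale_sd, size=G)

        factors = rng.normal(size=(config.n_modules, n_samples))
        eps = rng.normal(size=(G, n_samples))
        z = np.where(
            (module_of >= 0)[:, None],
            lam[:, None] * factors[np.clip(module_of, 0, None)]
            + np.sqrt(1.0 - lam[:, None] ** 2) * eps,
            eps,
        )
        base = mu[:, None] + shift[:, None] + scale[:, None] * sig[:, None] * z
        # columns: subject j tumor at 2j, normal at 2j+1
        tumor_cols = np.arange(0, n_samples, 2)
        base[:, tumor_cols] += delta[:, None]

        sample_ids, meta_rows = [], []
        for j in range(n):
            subj = f"{study_id}_P{j + 1:02d}"
            for cond, col in (("tumor", 2 * j), ("normal", 2 * j + 1)):
                sid = f"{subj}_{'T' if cond == 'tumor' else 'N'}"
                sample_ids.append((sid, col))
                meta_rows.append((sid, subj, cond, study_id))
        order = [col for _, col in sample_ids]
        values = pd.DataFrame(
            base[:, order], index=gene_ids, columns=[sid for sid, _ in sample_ids]
        )
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "subject_id", "condition", "batch"]
        ).set_index("sample_id")
        studies.append(ExpressionStudy(study_id=study_id, values=values, sample_meta=meta))
    return studies, truth


def simulate_network(config: SimConfig, truth: SimTruth) -> nx.Graph:
    """Interaction network: Erdos-Renyi background over all genes plus
    dense planted-module subgraphs (each internal edge kept with
    probability ``module_edge_retention``)."""
    *_, network_ss, _, _ = _streams(config)
    rng = np.random.default_rng(network_ss)
    gene_ids = list(truth.gene_ids)
    G = len(gene_ids)
    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)

    p = config.network_background_density
    if p > 0:
        iu, ju = np.triu_indices(G, k=1)
        keep = rng.random(iu.size) < p
        graph.add_edges_from(
            (gene_ids[i], gene_ids[j]) for i, j in zip(iu[keep], ju[keep])
        )
    for members in truth.planted_modules:
        members = list(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < config.module_edge_retention:
                    graph.add_edge(members[i], members[j])
    return graph


def simulate_gene_sets(
    config: SimConfig, truth: SimTruth, n_decoys: int = 20, decoy_size: int = 25
) -> GeneSetCollection:
    """GMT-style collection: each planted module as a named set plus random
    decoy sets drawn from the gene universe."""
    *_, sets_ss = _streams(config)
    rng = np.random.default_rng(sets_ss)
    sets = {
        f"PLANTED_MODULE_{m}": frozenset(members)
        for m, members in enumerate(truth.planted_modules)
    }
    genes = list(truth.gene_ids)
    for d in range(n_decoys):
        pick = rng.choice(len(genes), size=min(decoy_size, len(genes)), replace=False)
        sets[f"DECOY_{d:02d}"] = frozenset(genes[i] for i in pick)
    return GeneSetCollection(name="synthetic", sets=sets, universe=frozenset(genes))


def _censor_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound of the U(0, u) censoring law giving the target censoring
    fraction on average across subjects."""

    def frac(u: float) -> float:
        hu = rates * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu))

    lo, hi = 1e-9, 1.0
    while frac(hi) > target and hi < 1e9:
        hi *= 2.0
    return float(optimize.brentq(lambda u: frac(u) - target, lo, hi))


def simulate_clinical(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Clinical cohort whose hazard depends on the planted marker.

    The marker score is a noisy draw from the marker gene's tumor
    expression law; survival is exponential with hazard
    ``h0 * true_hr ** I(marker > median)`` (baseline median 20 months),
    censoring uniform and calibrated to ``censor_rate``. Stage-like and
    grade-like ordinal covariates are tilted toward high-marker patients
    with strength ``covariate_assoc``; gender is independent.
    """
    *_, clinical_ss, _ = _streams(config)
    rng = np.random.default_rng(clinical_ss)
    n = config.n_patients

    mu = truth.baseline[truth.marker_gene] + truth.planted_degs.get(truth.marker_gene, 0.0)
    sd = truth.sigma[truth.marker_gene]
    z = rng.normal(size=n)
    marker = mu + sd * z + rng.normal(0.0, 0.5 * sd, size=n)

    high = marker > np.median(marker)
    h0 = np.log(2.0) / 20.0
    rates = h0 * np.where(high, config.true_hr, 1.0)
    latent_t = rng.exponential(1.0 / rates)

    if config.censor_rate == 0:
        time, event = latent_t, np.ones(n, dtype=int)
    else:
        u = _censor_horizon(rates, config.censor_rate)
        c = rng.uniform(0.0, u, size=n)
        event = (latent_t <= c).astype(int)
        time = np.minimum(latent_t, c)
    time = np.maximum(time, 1e-6)

    assoc = config.covariate_assoc
    stage_latent = assoc * z + rng.normal(size=n)
    grade_latent = assoc * z + rng.normal(size=n)
    lat_sd = np.sqrt(1.0 + assoc**2)
    # marginal stage probs ~ (10%, 50%, 30%, 10%); grade ~ (20%, 50%, 30%)
    stage_cuts = stats.norm.ppf([0.10, 0.60, 0.90]) * lat_sd
    grade_cuts = stats.norm.ppf([0.20, 0.70]) * lat_sd
    stage = np.digitize(stage_latent, stage_cuts) + 1
    grade = np.digitize(grade_latent, grade_cuts) + 1
    gender = rng.integers(0, 2, size=n)
    age_group = (rng.random(n) < 0.4).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:03d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "marker": marker,
            "tnm_stage": stage,
            "differentiation": grade,
            "gender": gender,
            "age_group": age_group,
        }
    ).set_index("patient_id")
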