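"""End-to-end orchestration of the prioritization pipeline.

Stage order: probe filtering and batch adjustment -> per-study moderated-t
screening and cross-study intersection -> DEG-induced subnetwork, topology
metrics and hub filter -> correlation weighting, Markov clustering and
module filters -> optional gene-set enrichment -> hub-by-module candidate
prioritization -> optional clinical validation of the top candidate.
Every stage's headline counts land in a JSON-serializable run report; the
same inputs and config reproduce the same report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io as nio
from .clinical import cox_fit, dichotomize, km_fit, logrank_test
from .deg import ExpressionStudy, adjust_batch, filter_probes, intersect_studies, screen_study
from .enrich import GeneSetCollection, enrich_modules
from .mcl import (
    MCLParams,
    correlation_weights,
    filter_modules,
    mcl_cluster,
    module_avg_correlation,
    prioritize_candidates,
)
from .network import build_subnetwork, filter_hubs, node_metrics

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold the pipeline applies, with the study's defaults."""

    fc_min: float = 1.0          # |log2FC| must exceed this (strict)
    q_max: float = 0.05          # BH-FDR cutoff (strict)
    min_studies: int | None = None  # None = all studies
    nc_min: float = 20.0         # hub neighborhood connectivity (inclusive)
    aspl_min: float = 3.5        # hub avg shortest path length (inclusive)
    inflation: float = 5.0       # MCL inflation coefficient
    module_min_size: int = 3
    module_min_avg_corr: float = 0.25
    enrich_min_size: int = 7
    enrich_fdr: float = 0.05
    corr_study: str | None = None   # study whose tumor samples weight edges
    corr_condition: str = "tumor"
    ties: str = "breslow"
    cutoff: str | float = "median"
    marker_col: str = "marker"
    covariate_cols: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariate_cols" in d:
            d = {**d, "covariate_cols": tuple(d["covariate_cols"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @classmethod
    def sim_scale(cls, sim_config=None, **overrides) -> "PipelineConfig":
        """Thresholds sized for the synthetic benchmark.

        The headline defaults (NC >= 20, path length >= 3.5, all-study
        intersection) were chosen for a genome-scale interaction network
        with hundreds of DEGs; the synthetic subnetwork is two orders of
        magnitude smaller, so hubs are defined as nodes whose neighborhood
        connectivity reflects membership in a planted near-clique
        (half the expected in-module degree), the path-length floor drops
        to 1 hop, and a gene may miss the DEG cutoff in one study.
        """
        kwargs: dict = {"aspl_min": 1.0, "nc_min": 5.0}
        if sim_config is not None:
            kwargs["min_studies"] = max(2, sim_config.n_studies - 1)
            kwargs["nc_min"] = max(
                2.0,
                0.5 * (sim_config.module_size - 1) * sim_config.module_edge_retention,
            )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    report: dict
    deg_tables: dict[str, pd.DataFrame]
    intersection: object = None
    metrics: pd.DataFrame | None = None
    hubs: set[str] = field(default_factory=set)
    modules: list = field(default_factory=list)
    enrichment: pd.DataFrame | None = None
    candidates: tuple[str, ...] = ()
    clinical: dict | None = None


def run_pipeline(
    studies: list[ExpressionStudy],
    edge_graph: nx.Graph,
    config: PipelineConfig | None = None,
    collection: GeneSetCollection | None = None,
    clinical: pd.DataFrame | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full prioritization flow on in-memory inputs.

    When ``out_dir`` is given every intermediate table plus the run report
    is written there as TSV/JSON.
    """
    config = config or PipelineConfig()
    report: dict = {"parameters": _params_dict(config), "stages": {}}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- screening -------------------------------------------------------
    filtered = [filter_probes(s) for s in studies]
    adjusted = adjust_batch(filtered) if len(filtered) > 1 else filtered
    deg_tables = {
        s.study_id: screen_study(s, fc_min=config.fc_min, q_max=config.q_max)
        for s in adjusted
    }
    report["stages"]["screen"] = {
        s: int(tab["passes"].sum()) for s, tab in deg_tables.items()
    }
    result = PipelineResult(report=report, deg_tables=deg_tables)

    if len(deg_tables) > 1:
        inter = intersect_studies(deg_tables, min_studies=config.min_studies)
        common = inter.genes
        result.intersection = inter
        report["stages"]["intersection"] = {
            "n_common": len(common), "n_up": inter.n_up, "n_down": inter.n_down,
        }
    else:
        only = next(iter(deg_tables.values()))
        common = set(only.index[only["passes"]])
        report["stages"]["intersection"] = {"n_common": len(common)}

    if out is not None:
        for sid, tab in deg_tables.items():
            tab.to_csv(out / f"deg_{sid}.tsv", sep="\t", index_label="gene")

    if not common:
        report["stages"]["status"] = "no common DEGs; stopped before the network stage"
        _finish(result, out)
        return result

    # --- network topology ------------------------------------------------
    subnet = build_subnetwork(edge_graph, common)
    metrics = node_metrics(subnet.graph)
    hubs = filter_hubs(metrics, nc_min=config.nc_min, aspl_min=config.aspl_min)
    result.metrics, result.hubs = metrics, hubs
    report["stages"]["network"] = {
        "n_nodes": subnet.graph.number_of_nodes(),
        "n_edges": subnet.graph.number_of_edges(),
        "n_unmapped": len(subnet.unmapped),
        "mean_degree": metrics.attrs["mean_degree"],
        "n_hubs": len(hubs),
    }
    if out is not None:
        metrics.to_csv(out / "node_metrics.tsv", sep="\t")
        nio.write_edge_list(subnet.graph, out / "subnetwork.tsv")

    # --- modules ---------------------------------------------------------
    corr_study = adjusted[0]
    if config.corr_study is not None:
        by_id = {s.study_id: s for s in adjusted}
        corr_study = by_id[config.corr_study]
    weighted = correlation_weights(subnet.graph, corr_study, condition=config.corr_condition)
    raw_modules = mcl_cluster(weighted, MCLParams(inflation=config.inflation))
    raw_modules = [module_avg_correlation(m, weighted) for m in raw_modules]
    modules = filter_modules(
        raw_modules,
        min_size=config.module_min_size,
        min_avg_corr=config.module_min_avg_corr,
    )
    result.modules = modules
    report["stages"]["modules"] = {
        "n_raw_clusters": len(raw_modules),
        "n_modules": len(modules),
        "sizes": [m.size for m in modules],
        "avg_corrs": [round(m.avg_corr, 4) for m in modules],
    }
    if out is not None:
        nio.write_modules(modules, out / "modules.tsv")

    # --- enrichment ------------------------------------------------------
    if collection is not None and modules:
        measured = set(corr_study.values.index)
        enr = enrich_modules(
            modules,
            collection,
            measured=measured,
            min_module_size=config.enrich_min_size,
            fdr_max=config.enrich_fdr,
        )
        result.enrichment = enr
        report["stages"]["enrichment"] = {
            "n_records": len(enr),
            "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
        }
        if out is not None:
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- prioritization --------------------------------------------------
    if modules and hubs:
        prio = prioritize_candidates(hubs, modules)
        result.candidates = prio.candidates
        report["stages"]["candidates"] = {
            "selected_module": prio.selected_module.module_id,
            "selected_module_avg_corr": round(prio.selected_module.avg_corr, 4),
            "genes": list(prio.candidates),
        }
        if out is not None:
            prio.per_module.to_csv(out / "hub_module_overlap.tsv", sep="\t", index=False)
    else:
        report["stages"]["candidates"] = {"genes": []}

    # --- clinical validation --------------------------------------------
    if clinical is not None:
        result.clinical = _clinical_stage(clinical, config)
        report["stages"]["clinical"] = result.clinical["summary"]
        if out is not None:
            result.clinical["cox"].summary.to_csv(out / "cox.tsv", sep="\t")

    _finish(result, out)
    return result


def _clinical_stage(clinical: pd.DataFrame, config: PipelineConfig) -> dict:
    labels = dichotomize(clinical[config.marker_col].to_numpy(), cutoff=config.cutoff)
    times = clinical["time_months"].to_numpy()
    events = clinical["event"].to_numpy()
    chi2, df, p = logrank_test(labels, times, events)
    km = {lab: km_fit(times[labels == lab], events[labels == lab]) for lab in ("Low", "High")}
    design = pd.DataFrame({"marker_high": (labels == "High").astype(float)},
                          index=clinical.index)
    for col in config.covariate_cols:
        design[col] = pd.to_numeric(clinical[col]).astype(float)
    cox = cox_fit(design, times, events, ties=config.ties)
    return {
        "labels": labels,
        "km": km,
        "cox": cox,
        "summary": {
            "n_high": int((labels == "High").sum()),
            "n_low": int((labels == "Low").sum()),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "marker_hr": float(cox.hr["marker_high"]),
            "marker_hr_ci": [
                float(cox.summary.loc["marker_high", "ci_low"]),
                float(cox.summary.loc["marker_high", "ci_high"]),
            ],
            "median_survival": {k: v.median for k, v in km.items()},
        },
    }


def _params_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["covariate_cols"] = list(d["covariate_cols"])
    return d


def _finish(result: PipelineResult, out: Path | None) -> None:
    if out is not None:
        nio.write_json(result.report, out / "run_report.json")
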