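"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are TSV (first column gene symbol, header = sample
ids); sample metadata is CSV (sample_id, subject_id, condition, study_id);
interaction networks are 2/3-column TSV edge lists or SIF; gene sets are
GMT; clinical tables are CSV. Gene symbols are whitespace-stripped and
treated case-sensitively.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .deg import ExpressionStudy
from .enrich import GeneSetCollection
from .mcl import Module

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_meta",
    "write_sample_meta",
    "read_studies",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "write_modules",
    "read_modules",
    "write_json",
]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression columns {non_numeric}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"sample_id", "subject_id", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return meta.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def read_studies(expr_path, meta_path) -> list[ExpressionStudy]:
    """Load one expression TSV + metadata CSV, split into per-study objects
    by the metadata's ``study_id`` (or ``batch``) column."""
    values = read_expression(expr_path)
    meta = read_sample_meta(meta_path)
    study_col = "study_id" if "study_id" in meta.columns else "batch"
    if study_col not in meta.columns:
        raise ValueError(f"{meta_path}: need a study_id or batch column")
    studies = []
    for study_id, sub in meta.groupby(study_col, sort=True):
        cols = [c for c in values.columns if c in sub.index]
        studies.append(
            ExpressionStudy(
                study_id=str(study_id),
                values=values[cols],
                sample_meta=sub.rename(columns={study_col: "batch"}),
            )
        )
    return studies


def read_edge_list(path) -> nx.Graph:
    """Edge list as TSV (geneA geneB [weight]) or SIF (geneA relation geneB)."""
    path = Path(path)
    graph = nx.Graph()
    is_sif = path.suffix.lower() == ".sif"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if is_sif:
                    a, _, b = parts[0], parts[1], parts[2]
                    w = 1.0
                else:
                    a, b = parts[0], parts[1]
                    w = float(parts[2]) if len(parts) > 2 else 1.0
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}") from err
            a, b = a.strip(), b.strip()
            if a != b:
                graph.add_edge(a, b, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path, sif: bool = False) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            if sif:
                fh.write(f"{u}\tFI\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, desc, genes")
            set_name = parts[0].strip()
            if set_name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {set_name!r}")
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            sets[set_name] = genes
    return GeneSetCollection(name=name or Path(path).stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[set_name]))
            fh.write(f"{set_name}\t{collection.name}\t{genes}\n")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient ids")
    return df.set_index("patient_id")


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="patient_id")


def write_modules(modules: list[Module], path) -> None:
    rows = [
        {
            "module_id": m.module_id,
            "size": m.size,
            "avg_corr": m.avg_corr,
            "genes": ",".join(m.genes),
        }
        for m in modules
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_modules(path) -> list[Module]:
    df = pd.read_csv(path, sep="\t")
    return [
        Module(
            module_id=int(r.module_id),
            genes=tuple(sorted(str(r.genes).split(","))),
            avg_corr=float(r.avg_corr),
            avg_corr_defined=bool(pd.notna(r.avg_corr)),
        )
        for r in df.itertuples()
    ]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if hasattr(x, "tolist"):
        return x.tolist()
    if isinstance(x, (set, frozenset, tuple)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
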