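"""Multi-study differential-expression screening.

Each study is a paired tumor/normal log2 expression matrix. Per gene we test
the paired log2 differences with a random-variance-model (RVM) moderated
t-test: the per-gene variance is shrunk toward an inverse-Gamma prior fitted
across all genes, which buys degrees of freedom when the number of pairs is
small. Genes passing |log2FC| and FDR cutoffs in every study (with one
consistent sign) form the common DEG set fed to the network stages.

The RVM model: gene-level precisions 1/sigma^2 are Gamma(a, b) distributed,
so the observed sample variance satisfies s^2 * a * b ~ F(n-1, 2a). The
moderated variance is the precision-weighted compromise

    s~^2 = ((n-1) s^2 + 2/b) / ((n-1) + 2a)

and the moderated t has n - 1 + 2a degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionStudy",
    "RVMPrior",
    "DEGIntersection",
    "filter_probes",
    "adjust_batch",
    "estimate_rvm_prior",
    "rvm_paired_t",
    "bh_adjust",
    "screen_study",
    "intersect_studies",
]


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus per-sample metadata.

    Parameters
    ----------
    study_id : str
        Label for the study (e.g. a repository accession).
    values : pandas.DataFrame
        Genes x samples log2 intensities; index = gene symbols,
        columns = sample ids.
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``subject_id`` and ``condition``
        (``"tumor"`` or ``"normal"``); an optional ``batch`` column defaults
        to the study id.
    """

    study_id: str
    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta
        if not set(self.values.columns) <= set(meta.index):
            missing = sorted(set(self.values.columns) - set(meta.index))
            raise ValueError(f"samples without metadata: {missing}")
        bad = set(meta["condition"].unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if "batch" not in meta.columns:
            self.sample_meta = meta.assign(batch=self.study_id)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        return list(meta.index[meta["condition"] == condition])

    def paired_diffs(self) -> pd.DataFrame:
        """Tumor minus normal log2 differences, one column per subject.

        Raises ``ValueError`` naming unmatched subjects if the pairing is
        incomplete.
        """
        meta = self.sample_meta.loc[list(self.values.columns)]
        tumor = meta[meta["condition"] == "tumor"]
        normal = meta[meta["condition"] == "normal"]
        t_by_subj = dict(zip(tumor["subject_id"], tumor.index))
        n_by_subj = dict(zip(normal["subject_id"], normal.index))
        unmatched = sorted(set(t_by_subj) ^ set(n_by_subj))
        if unmatched:
            raise ValueError(
                f"study {self.study_id}: unpaired subjects {unmatched}"
            )
        subjects = sorted(t_by_subj)
        diffs = (
            self.values[[t_by_subj[s] for s in subjects]].to_numpy()
            - self.values[[n_by_subj[s] for s in subjects]].to_numpy()
        )
        return pd.DataFrame(diffs, index=self.values.index, columns=subjects)


@dataclass(frozen=True)
class RVMPrior:
    """Gamma(a, b) prior on gene-level inverse variances (b is the scale)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"RVM prior requires a, b > 0; got {self}")


def filter_probes(study: ExpressionStudy) -> ExpressionStudy:
    """Drop probes with missing values and collapse duplicate symbols.

    Rows containing any missing value are removed; when several rows share a
    gene symbol the row with the largest variance across samples is kept.
    """
    values = study.values.dropna(axis=0, how="any")
    if values.index.has_duplicates:
        row_var = values.var(axis=1, ddof=1).fillna(0.0)
        order = np.argsort(-row_var.to_numpy(), kind="stable")
        values = values.iloc[order]
        values = values[~values.index.duplicated(keep="first")]
        values = values.sort_index()
    if values.shape[0] == 0:
        raise ValueError(f"study {study.study_id}: no probes left after filtering")
    return replace(study, values=values)


def adjust_batch(studies: list[ExpressionStudy]) -> list[ExpressionStudy]:
    """Location/scale batch adjustment across studies.

    Restricts every study to the shared gene universe, then maps each
    study's per-gene distribution onto the pooled cross-study mean and SD:
    ``x' = (x - m_sg) / sd_sg * SD_g + M_g``. This exactly removes additive
    per-study shifts and rescales multiplicative ones.
    """
    if not studies:
        raise ValueError("no studies given")
    shared_set = set(studies[0].values.index)
    for st in studies[1:]:
        shared_set &= set(st.values.index)
    if not shared_set:
        raise ValueError("empty gene intersection across studies")
    shared = studies[0].values.index[studies[0].values.index.isin(shared_set)]

    mats = [st.values.loc[shared] for st in studies]
    pooled = np.concatenate([m.to_numpy() for m in mats], axis=1)
    pooled_mean = pooled.mean(axis=1)
    pooled_sd = pooled.std(axis=1, ddof=1)

    out = []
    for st, m in zip(studies, mats):
        x = m.to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd_safe = np.where(sd > 0, sd, 1.0)
        z = (x - mu) / sd_safe
        adj = z * pooled_sd[:, None] + pooled_mean[:, None]
        out.append(replace(st, values=pd.DataFrame(adj, index=shared, columns=m.columns)))
    return out


def _rvm_mom(variances: np.ndarray, n: int) -> RVMPrior:
    # Moment estimator: E[s^2] = 1/(b(a-1)), E[s^4] = (n+1)/(n-1) / (b^2 (a-1)(a-2))
    m1 = float(np.mean(variances))
    m2 = float(np.mean(variances**2))
    c = m2 * (n - 1) / ((n + 1) * m1 * m1) if m1 > 0 else np.inf
    if np.isfinite(c) and c > 1.0:
        a = (2.0 * c - 1.0) / (c - 1.0)
    else:
        a = 3.0
    a = float(np.clip(a, 1.05, 500.0))
    b = 1.0 / (m1 * (a - 1.0)) if m1 > 0 else 1.0
    return RVMPrior(a=a, b=float(b))


def estimate_rvm_prior(variances, n: int) -> RVMPrior:
    """Fit the Gamma(a, b) inverse-variance prior by maximum likelihood.

    Under the model, ``s^2 * a * b ~ F(n-1, 2a)``; the likelihood over all
    gene-level sample variances is maximized over (a, b) by Nelder-Mead from
    a method-of-moments start. Zero variances are excluded; on optimizer
    failure the moment estimate is returned with a warning.

    Parameters
    ----------
    variances : array-like
        Per-gene sample variances of the paired differences (>= 50 values).
    n : int
        Number of pairs each variance was computed from (n >= 2).
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 50:
        raise ValueError(f"need >= 50 positive variances, got {v.size}")
    if n < 2:
        raise ValueError("need n >= 2 pairs")

    mom = _rvm_mom(v, n)
    if np.var(v) == 0:
        warnings.warn("degenerate (constant) variances; returning moment estimate")
        return mom

    d1 = n - 1

    def nll(theta: np.ndarray) -> float:
        a, b = np.exp(theta)
        x = v * a * b
        ll = stats.f.logpdf(x, d1, 2.0 * a).sum() + v.size * np.log(a * b)
        return -ll if np.isfinite(ll) else np.inf

    try:
        res = optimize.minimize(
            nll,
            x0=np.log([mom.a, mom.b]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.success and np.all(np.isfinite(res.x)):
            a, b = np.exp(res.x)
            return RVMPrior(a=float(a), b=float(b))
    except Exception:  # pragma: no cover - defensive
        pass
    warnings.warn("RVM likelihood optimization failed; falling back to moments")
    return mom


def rvm_paired_t(diffs, prior: RVMPrior | None):
    """Moderated paired t-test on one gene's per-subject log2 differences.

    With ``prior=None`` this is the classical paired t-test (no shrinkage).
    Returns ``(log2fc, t, df, p)``.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    log2fc = float(d.mean())
    s2 = float(d.var(ddof=1))
    if prior is None:
        s2_mod, df = s2, float(n - 1)
    else:
        s2_mod = ((n - 1) * s2 + 2.0 / prior.b) / ((n - 1) + 2.0 * prior.a)
        df = float(n - 1 + 2.0 * prior.a)
    if s2_mod == 0.0:
        t = 0.0 if log2fc == 0.0 else np.sign(log2fc) * np.inf
    else:
        t = log2fc * np.sqrt(n) / np.sqrt(s2_mod)
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return log2fc, float(t), df, min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_study(
    study: ExpressionStudy,
    fc_min: float = 1.0,
    q_max: float = 0.05,
    prior: RVMPrior | None = None,
) -> pd.DataFrame:
    """Screen one paired study for DEGs with the RVM moderated t-test.

    The shrinkage prior is fitted from the study's own per-gene difference
    variances unless supplied; studies with fewer than 50 genes fall back to
    the classical paired t-test. A gene "passes" when |log2fc| > ``fc_min``
    and q < ``q_max`` (both strict, matching the screening convention).

    Returns a DataFrame indexed by gene with columns
    ``log2fc, t, df, p, q, direction, passes``.
    """
    diffs = study.paired_diffs()
    n = diffs.shape[1]
    if prior is None:
        variances = diffs.var(axis=1, ddof=1).to_numpy()
        if diffs.shape[0] >= 50 and np.sum(variances > 0) >= 50:
            prior = estimate_rvm_prior(variances, n)
        else:
            warnings.warn(
                f"study {study.study_id}: too few genes to fit the RVM prior; "
                "using the classical paired t-test"
            )
    rows = [rvm_paired_t(diffs.iloc[i].to_numpy(), prior) for i in range(diffs.shape[0])]
    res = pd.DataFrame(rows, index=diffs.index, columns=["log2fc", "t", "df", "p"])
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["log2fc"] >= 0, "up", "down")
    res["passes"] = (res["log2fc"].abs() > fc_min) & (res["q"] < q_max)
    return res


@dataclass
class DEGIntersection:
    """Cross-study common DEGs with per-gene support counts."""

    genes: set[str]
    table: pd.DataFrame  # gene-indexed: n_passing, consistent, direction
    min_studies: int
    n_up: int
    n_down: int


def intersect_studies(
    deg_tables: dict[str, pd.DataFrame],
    min_studies: int | None = None,
    require_direction: bool = True,
) -> DEGIntersection:
    """Intersect per-study DEG calls into the common DEG set.

    ``deg_tables`` maps study id to a :func:`screen_study` result. A gene is
    common when it passes in at least ``min_studies`` studies (default: all)
    with one consistent sign when ``require_direction``.
    """
    if len(deg_tables) < 2:
        raise ValueError("need at least 2 studies to intersect")
    if min_studies is None:
        min_studies = len(deg_tables)

    support: dict[str, list[str]] = {}
    for tab in deg_tables.values():
        passing = tab[tab["passes"]]
        for gene, direction in passing["direction"].items():
            support.setdefault(gene, []).append(direction)

    columns = ["gene", "n_passing", "consistent", "direction", "common"]
    records = []
    for gene, dirs in support.items():
        consistent = len(set(dirs)) == 1
        keep = len(dirs) >= min_studies and (consistent or not require_direction)
        records.append((gene, len(dirs), consistent, dirs[0] if consistent else "mixed", keep))
    table = pd.DataFrame(records, columns=columns).set_index("gene").sort_index()
    table = table.astype({"n_passing": int, "consistent": bool, "common": bool})

    common = table[table["common"]]
    genes = set(common.index)
    return DEGIntersection(
        genes=genes,
        table=table,
        min_studies=min_studies,
        n_up=int((common["direction"] == "up").sum()),
        n_down=int((common["direction"] == "down").sum()),
    )
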