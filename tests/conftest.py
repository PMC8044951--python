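import numpy as np
import pandas as pd
import pytest

from netprio import ExpressionStudy
from netprio.sim import SimConfig, simulate_network, simulate_studies


def make_study(values: np.ndarray, genes, n_pairs: int, study_id="S1") -> ExpressionStudy:
    """Wrap a genes x (2*n_pairs) matrix as a paired study.

    Columns alternate tumor, normal per subject.
    """
    cols, meta = [], []
    for j in range(n_pairs):
        for cond, tag in (("tumor", "T"), ("normal", "N")):
            sid = f"{study_id}_P{j}_{tag}"
            cols.append(sid)
            meta.append((sid, f"{study_id}_P{j}", cond, study_id))
    values = pd.DataFrame(values, index=genes, columns=cols)
    meta = pd.DataFrame(meta, columns=["sample_id", "subject_id", "condition", "batch"])
    return ExpressionStudy(study_id, values, meta.set_index("sample_id"))


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic dataset shared by the fast integration tests."""
    cfg = SimConfig(seed=11, genes=400, n_studies=3, pairs_per_study=15,
                    deg_fraction=0.1, n_modules=2, module_size=8)
    studies, truth = simulate_studies(cfg)
    graph = simulate_network(cfg, truth)
    return cfg, studies, truth, graph
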