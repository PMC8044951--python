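"""DEG screening: probe filtering, batch adjustment, the moderated t-test,
BH-FDR, and cross-study intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from netprio import (
    RVMPrior,
    adjust_batch,
    bh_adjust,
    estimate_rvm_prior,
    filter_probes,
    intersect_studies,
    rvm_paired_t,
    screen_study,
)
from netprio.sim import SimConfig, simulate_studies

from conftest import make_study


class TestFilterProbes:
    def test_clean_study_unchanged(self):
        study = make_study(np.arange(12.0).reshape(3, 4), ["A", "B", "C"], 2)
        out = filter_probes(study)
        pd.testing.assert_frame_equal(out.values, study.values)

    def test_row_with_missing_value_dropped(self):
        vals = np.arange(12.0).reshape(3, 4)
        vals[1, 2] = np.nan
        out = filter_probes(make_study(vals, ["A", "B", "C"], 2))
        assert list(out.values.index) == ["A", "C"]

    def test_duplicate_symbol_keeps_highest_variance_row(self):
        low = np.array([5.0, 5.5, 5.0, 5.5])        # var 0.083
        high = np.array([3.0, 6.0, 3.0, 6.0])       # var 3
        study = make_study(np.vstack([low, high]), ["TP53", "TP53"], 2)
        out = filter_probes(study)
        assert out.values.shape[0] == 1
        np.testing.assert_allclose(out.values.loc["TP53"].to_numpy(), high)

    def test_all_rows_removed_errors(self):
        vals = np.full((2, 4), np.nan)
        with pytest.raises(ValueError, match="no probes"):
            filter_probes(make_study(vals, ["A", "B"], 2))


class TestAdjustBatch:
    def test_single_study_numerically_unchanged(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(7, 1, (20, 8)), [f"G{i}" for i in range(20)], 4)
        out = adjust_batch([study])[0]
        np.testing.assert_allclose(out.values.to_numpy(), study.values.to_numpy(), atol=1e-9)

    def test_constant_shift_between_studies_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(7, 1, (15, 10))
        s1 = make_study(base, [f"G{i}" for i in range(15)], 5, "S1")
        s2 = make_study(base + 3.0, [f"G{i}" for i in range(15)], 5, "S2")
        a1, a2 = adjust_batch([s1, s2])
        gap = a1.values.mean(axis=1) - a2.values.mean(axis=1)
        np.testing.assert_allclose(gap.to_numpy(), 0.0, atol=1e-9)

    def test_simulated_batch_variance_mostly_removed(self):
        cfg = SimConfig(seed=5, genes=300, n_studies=4, pairs_per_study=10,
                        batch_shift_sd=1.0, deg_fraction=0.0,
                        n_modules=1, module_size=3)
        studies, _ = simulate_studies(cfg)

        def between_var(sts):
            means = np.stack([s.values.mean(axis=1).to_numpy() for s in sts])
            return means.var(axis=0, ddof=1)

        before = between_var(studies)
        after = between_var(adjust_batch(studies))
        assert after.mean() <= 0.1 * before.mean()


class TestRVMPrior:
    def test_recovers_simulated_shape_and_scale(self):
        rng = np.random.default_rng(42)
        n, n_genes = 10, 5000
        sigma2 = 1.0 / rng.gamma(2.0, 1.0, size=n_genes)
        s2 = sigma2 * rng.chisquare(n - 1, size=n_genes) / (n - 1)
        prior = estimate_rvm_prior(s2, n)
        assert 1.8 <= prior.a <= 2.2
        assert 0.9 <= prior.b <= 1.1

    def test_degenerate_constant_variances_fall_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            prior = estimate_rvm_prior(np.ones(100), 5)
        assert np.isfinite(prior.a) and np.isfinite(prior.b)

    def test_too_few_variances_rejected(self):
        with pytest.raises(ValueError, match="50"):
            estimate_rvm_prior(np.ones(49) + np.arange(49) * 0.01, 5)


class TestModeratedT:
    def test_zero_differences_give_t0_p1(self):
        fc, t, df, p = rvm_paired_t(np.zeros(5), RVMPrior(2.0, 1.0))
        assert (fc, t, p) == (0.0, 0.0, 1.0)

    def test_no_shrinkage_mode_matches_hand_paired_t(self):
        fc, t, df, p = rvm_paired_t([1.0, 2.0, 3.0], None)
        assert fc == 2.0
        assert t == pytest.approx(3.4641016, abs=1e-6)
        assert df == 2

    def test_shrinkage_plugin_formula(self):
        # n=4, mean 1, sample variance 1, prior (a=1, b=1):
        # s~^2 = (3*1 + 2)/(3 + 2) = 1, t = 1*sqrt(4)/1 = 2, df = 5
        half = np.sqrt(3.0) / 2.0
        diffs = np.array([1 - half, 1 - half, 1 + half, 1 + half])
        fc, t, df, p = rvm_paired_t(diffs, RVMPrior(1.0, 1.0))
        assert fc == pytest.approx(1.0)
        assert t == pytest.approx(2.0, abs=1e-12)
        assert df == 5.0

    def test_single_difference_rejected(self):
        with pytest.raises(ValueError):
            rvm_paired_t([1.0], None)

    @settings(deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=12), st.integers(0, 100))
    def test_no_shrinkage_limit_equals_classical(self, diffs, jitter):
        diffs = np.asarray(diffs) + jitter * 1e-3
        if np.var(diffs, ddof=1) < 1e-6:
            # near-degenerate spread: the vestigial prior mass 2/b, however
            # tiny, is no longer negligible relative to s^2
            return
        # a -> 0 and 1/b -> 0 removes the prior's pull entirely
        fc, t, df, p = rvm_paired_t(diffs, RVMPrior(1e-15, 1e15))
        t_ref = stats.ttest_1samp(diffs, 0.0)
        assert t == pytest.approx(t_ref.statistic, rel=1e-9, abs=1e-9)

    @settings(deadline=None)
    @given(
        st.lists(st.floats(-3, 3), min_size=3, max_size=10),
        st.floats(0.1, 5), st.floats(0.1, 5),
    )
    def test_moderated_variance_between_sample_and_prior(self, diffs, a, b):
        d = np.asarray(diffs)
        s2 = d.var(ddof=1)
        n = d.size
        s2_mod = ((n - 1) * s2 + 2.0 / b) / ((n - 1) + 2.0 * a)
        lo, hi = sorted([s2, 1.0 / (a * b)])
        assert lo - 1e-12 <= s2_mod <= hi + 1e-12


def brute_force_bh(pvals):
    """q_i = min over tail ranks of p_(j) * m / j, the textbook step-up."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(tail))
    return q


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_worked_values(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    @settings(deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8), st.randoms())
    def test_permutation_invariant(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = bh_adjust(pvals)
        q_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)


class TestScreenStudy:
    def test_identical_tumor_normal_yields_no_degs(self):
        rng = np.random.default_rng(3)
        half = rng.normal(7, 1, (60, 5))
        vals = np.repeat(half, 2, axis=1)  # tumor == normal per subject
        study = make_study(vals, [f"G{i}" for i in range(60)], 5)
        tab = screen_study(study)
        assert tab["passes"].sum() == 0

    def test_boundary_fold_change_is_excluded(self):
        # a gene sitting exactly at |log2fc| = 1 must not pass (strict >)
        rng = np.random.default_rng(4)
        vals = rng.normal(7, 0.1, (60, 20))
        genes = [f"G{i}" for i in range(60)]
        study = make_study(vals, genes, 10)
        tumor_cols = [c for c in study.values.columns if c.endswith("T")]
        study.values.loc["G0", tumor_cols] = study.values.loc[
            "G0", [c.replace("T", "N") for c in tumor_cols]
        ].to_numpy() + 1.0
        tab = screen_study(study, fc_min=1.0)
        assert tab.loc["G0", "log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert tab.loc["G0", "q"] < 0.05
        assert not tab.loc["G0", "passes"]

    def test_unpaired_subjects_named_in_error(self):
        study = make_study(np.arange(8.0).reshape(2, 4), ["A", "B"], 2)
        broken = study.sample_meta.copy()
        broken.loc[broken.index[1], "subject_id"] = "ORPHAN"
        study.sample_meta = broken
        with pytest.raises(ValueError, match="ORPHAN"):
            study.paired_diffs()


class TestIntersectStudies:
    @staticmethod
    def _table(gene_dirs):
        genes = list(gene_dirs)
        return pd.DataFrame(
            {
                "log2fc": [2.0 if d == "up" else -2.0 for d in gene_dirs.values()],
                "direction": list(gene_dirs.values()),
                "passes": True,
            },
            index=genes,
        )

    def test_unanimous_single_gene(self):
        tabs = {f"S{i}": self._table({"A": "up"}) for i in range(3)}
        inter = intersect_studies(tabs)
        assert inter.genes == {"A"}
        assert inter.n_up == 1 and inter.n_down == 0

    def test_sign_conflict_excluded(self):
        tabs = {"S1": self._table({"A": "up"}), "S2": self._table({"A": "down"})}
        inter = intersect_studies(tabs, min_studies=2, require_direction=True)
        assert inter.genes == set()

    def test_membership_counting(self):
        tabs = {
            "S1": self._table({"A": "up", "B": "up"}),
            "S2": self._table({"B": "up", "C": "down"}),
            "S3": self._table({"B": "up"}),
        }
        inter = intersect_studies(tabs, min_studies=2)
        assert inter.genes == {"B"}
        assert inter.table.loc["A", "n_passing"] == 1
        assert inter.table.loc["C", "n_passing"] == 1

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(ValueError):
            intersect_studies({"S1": self._table({"A": "up"})})


class TestGlobalNull:
    def test_fdr_controlled_under_global_null(self):
        """With no planted effects, the q < 0.05 discovery fraction stays at
        or below the nominal level (plus Monte-Carlo slack)."""
        fracs = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, genes=400, n_studies=1, pairs_per_study=10,
                            deg_fraction=0.0, n_modules=1, module_size=3)
            studies, _ = simulate_studies(cfg)
            tab = screen_study(studies[0], fc_min=0.0)
            fracs.append((tab["q"] < 0.05).mean())
        mc_err = np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 2 * mc_err
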