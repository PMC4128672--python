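"""Transcriptome selection: BEC, moderated test, BH-FDR, conflict rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tfcrosstalk.transcriptome import (
    ExpressionStudy,
    SelectionParams,
    benjamini_hochberg,
    compute_bec,
    moderated_group_test,
    resolve_conflicts,
    select_transcriptome,
)


def make_study(values, n_target=3, n_ref=3, genes=None, target_cell="GC", ref_cell="SC"):
    values = np.asarray(values, dtype=float)
    cols = [f"t{i}" for i in range(n_target)] + [f"r{i}" for i in range(n_ref)]
    idx = [f"ps{i}" for i in range(values.shape[0])]
    cells = {f"t{i}": target_cell for i in range(n_target)}
    cells.update({f"r{i}": ref_cell for i in range(n_ref)})
    ps_map = genes if genes is not None else {p: f"g_{p}" for p in idx}
    return ExpressionStudy(
        matrix=pd.DataFrame(values, index=idx, columns=cols),
        sample_cells=cells,
        probeset_to_gene=ps_map,
    )


class TestBec:
    def test_even_count_uses_mean_of_middle(self):
        # entries {1..6} pooled across probe sets and samples -> median 3.5
        study = make_study([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        assert compute_bec(study) == 3.5
        # four entries -> mean of the two central values
        small = make_study([[1.0, 2.0, 3.0, 4.0]], n_target=2, n_ref=2)
        assert compute_bec(small) == 2.5

    def test_constant_matrix_returns_constant(self):
        study = make_study(np.full((4, 6), 7.25))
        assert compute_bec(study) == 7.25

    def test_matches_sorting_oracle_on_seeded_fixture(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(8, 2, (200, 6))
        study = make_study(vals)
        flat = sorted(vals.ravel())
        oracle = (flat[599] + flat[600]) / 2
        assert compute_bec(study) == pytest.approx(oracle, abs=0)

    def test_empty_matrix_is_hard_error(self):
        study = make_study(np.full((3, 6), 1.0))
        study.matrix = study.matrix.iloc[:0]
        with pytest.raises(ValueError):
            compute_bec(study)


class TestModeratedTest:
    def test_identical_groups_give_zero_statistic_unit_p(self):
        row = [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]
        study = make_study([row, row])
        res = moderated_group_test(study, ["GC"], ["SC"], prior_df=1.0)
        assert np.allclose(res["statistic"], 0.0)
        assert np.allclose(res["raw_p"], 1.0)

    def test_prior_df_zero_equals_classical_pooled_t(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 1, (10, 9))
        vals[:5, :4] += 2.0
        study = make_study(vals, n_target=4, n_ref=5)
        res = moderated_group_test(study, ["GC"], ["SC"], prior_df=0.0)
        t, p = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=True)
        assert np.allclose(res["raw_p"], p, atol=1e-10)
        assert np.allclose(res["statistic"], t**2, rtol=1e-10)

    def test_infinite_prior_uses_common_variance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (20, 6))
        study = make_study(vals)
        res = moderated_group_test(study, ["GC"], ["SC"], prior_df=math.inf)
        s0 = res.attrs["prior_var"]
        m1 = vals[:, :3].mean(axis=1)
        m2 = vals[:, 3:].mean(axis=1)
        expected_f = (m1 - m2) ** 2 / (s0 * (1 / 3 + 1 / 3))
        assert np.allclose(res["statistic"], expected_f)
        assert np.allclose(res["raw_p"], stats.chi2.sf(expected_f, 1))

    def test_estimated_prior_interpolates_between_extremes(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (50, 9))
        study = make_study(vals, n_target=4, n_ref=5)
        mod = moderated_group_test(study, ["GC"], ["SC"])
        assert 0 < mod.attrs["prior_df"]
        classical = moderated_group_test(study, ["GC"], ["SC"], prior_df=0.0)
        # moderation shrinks extreme statistics toward the bulk
        assert mod["statistic"].max() <= classical["statistic"].max() * 1.5

    def test_all_zero_variance_with_prior_zero_instructs_moderation(self):
        study = make_study([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]] * 3)
        with pytest.raises(ValueError, match="prior_df"):
            moderated_group_test(study, ["GC"], ["SC"], prior_df=0.0)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert benjamini_hochberg([0.4]) == pytest.approx([0.4])

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(17)
        p = rng.random(100)
        adj = benjamini_hochberg(p)
        # brute force: adj_i = min over j with p_j >= p_i of p_j * m / rank_j
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for pos_i in range(m):
            cand = [p[order[j]] * m / (j + 1) for j in range(pos_i, m)]
            brute[order[pos_i]] = min(1.0, min(cand))
        assert np.allclose(adj, brute, atol=1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(23)
        p = rng.random(64)
        assert np.allclose(benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_is_hard_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_never_decreases_and_preserves_smallest(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.argmin(adj) == np.argmin(p) or adj[np.argmin(p)] == adj.min()


class TestSelectTranscriptome:
    def _planted_study(self, seed=19, n=300, n_true=30, effect=2.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(6.0, 1.0, (n, 9))
        bec_est = 6.0
        base[:n_true] = rng.normal(2 * bec_est + effect, 0.25, (n_true, 9))
        base[:n_true, 6:] -= effect  # reference group lower by the effect
        return make_study(base, n_target=6, n_ref=3), n_true

    def test_intensity_boundary_excludes_below_threshold(self):
        # one probe set just under 2xBEC in targets, strong effect otherwise
        vals = np.full((99, 9), 6.0) + np.linspace(-0.1, 0.1, 99 * 9).reshape(99, 9)
        study_probe = np.full((1, 9), 6.0)
        study = make_study(np.vstack([vals, study_probe]), n_target=6, n_ref=3)
        bec = compute_bec(study)
        m = study.matrix.to_numpy().copy()
        m[-1, :6] = 2 * bec - 1e-6
        m[-1, 6:] = 2.0
        study.matrix.iloc[:, :] = m
        res = select_transcriptome(study, ["GC"], ["SC"], SelectionParams(prior_df=1.0))
        assert not res.per_probeset_stats.iloc[-1]["selected"]

    def test_planted_fixture_matches_rule_by_rule_oracle(self):
        study, n_true = self._planted_study()
        params = SelectionParams()
        res = select_transcriptome(study, ["GC"], ["SC"], params)

        # independent reimplementation of the three rules
        vals = study.matrix.to_numpy()
        bec = float(np.median(vals))
        tcols, rcols = slice(0, 6), slice(6, 9)
        max_t = vals[:, tcols].max(axis=1)
        fc = 2 ** (vals[:, tcols].mean(axis=1) - vals[:, rcols].mean(axis=1))
        raw = moderated_group_test(study, ["GC"], ["SC"])["raw_p"].to_numpy()
        adj = benjamini_hochberg(raw)
        oracle = (max_t >= 2 * bec) & (fc >= 2.0) & (adj <= 0.01)
        assert np.array_equal(res.per_probeset_stats["selected"].to_numpy(), oracle)
        # planted truth recovered up to FDR-consistent errors
        sel_idx = np.flatnonzero(oracle)
        assert set(sel_idx) <= set(range(n_true)) | set(sel_idx[:2])
        assert len(set(range(n_true)) & set(sel_idx)) >= int(0.8 * n_true)

    def test_all_background_world_selects_nothing(self):
        rng = np.random.default_rng(29)
        study = make_study(rng.normal(4.0, 0.5, (100, 9)), n_target=6, n_ref=3)
        res = select_transcriptome(study, ["GC"], ["SC"])
        assert res.genes == set()

    def test_unmapped_probesets_kept_in_stats_but_yield_no_genes(self):
        vals = np.full((3, 6), 6.0)
        vals[0, :3] = 20.0
        vals[0, 3:] = 10.0
        study = make_study(vals, genes={})  # nothing maps to a gene
        res = select_transcriptome(study, ["GC"], ["SC"], SelectionParams(prior_df=5.0))
        assert len(res.per_probeset_stats) == 3
        assert res.genes == set()

    def test_selection_monotone_in_thresholds(self):
        study, _ = self._planted_study(seed=31)
        loose = select_transcriptome(study, ["GC"], ["SC"], SelectionParams(adj_p_max=0.05, fold_change_min=1.5))
        tight = select_transcriptome(study, ["GC"], ["SC"], SelectionParams(adj_p_max=0.01, fold_change_min=2.5))
        assert tight.genes <= loose.genes


class TestResolveConflicts:
    def _res(self, cell, genes):
        from tfcrosstalk.transcriptome import TranscriptomeResult

        return TranscriptomeResult(cell_type=cell, genes=set(genes), per_probeset_stats=pd.DataFrame(), bec=6.0)

    def test_shared_genes_discarded_from_both(self):
        a, b, d = resolve_conflicts(self._res("GC", {"g1", "g2"}), self._res("SC", {"g2", "g3"}))
        assert a.genes == {"g1"} and b.genes == {"g3"} and d == {"g2"}
        assert a.genes.isdisjoint(b.genes)

    def test_disjoint_inputs_unchanged(self):
        a, b, d = resolve_conflicts(self._res("GC", {"g1"}), self._res("SC", {"g2"}))
        assert a.genes == {"g1"} and b.genes == {"g2"} and d == set()

    def test_seeded_planted_conflicts_exactly_recovered(self):
        rng = np.random.default_rng(37)
        shared = {f"c{i}" for i in range(12)}
        a_only = {f"a{i}" for i in range(50)}
        b_only = {f"b{i}" for i in range(40)}
        a, b, d = resolve_conflicts(
            self._res("GC", a_only | shared), self._res("SC", b_only | shared)
        )
        assert d == shared and a.genes == a_only and b.genes == b_only

    def test_same_cell_type_is_hard_error(self):
        with pytest.raises(ValueError):
            resolve_conflicts(self._res("GC", {"g"}), self._res("GC", {"g"}))


class TestStudyValidation:
    def test_missing_values_rejected(self):
        vals = np.full((2, 6), 1.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            make_study(vals)

    def test_single_sample_cell_type_rejected(self):
        with pytest.raises(ValueError, match="<2 samples"):
            make_study(np.ones((2, 3)), n_target=2, n_ref=1)
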