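"""NB GLM fitting, dispersion recovery, the fold-change threshold test and
BH adjustment against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy.stats import norm

from fluxseq.diffexpr import (
    adjust_bh,
    estimate_dispersions,
    fit_nb_glm,
    run_contrast,
)
from fluxseq.diffexpr import test_de_threshold as de_threshold  # pytest must not collect it
from fluxseq.errors import ValidationError
from fluxseq.simulate import TruthConfig, generate_counts, generate_design, generate_genes
from fluxseq.types import CountMatrix, SampleDescriptor


def _two_group_matrix(rows: dict, n_per_group: int = 3, libsize: int = 10**6) -> CountMatrix:
    samples = []
    for i in range(n_per_group):
        samples.append(SampleDescriptor(f"c{i}", "A", "control", 15.0, i + 1))
    for i in range(n_per_group):
        samples.append(SampleDescriptor(f"t{i}", "A", "starvation", 15.0, i + 1))
    df = pd.DataFrame(rows, index=[s.sample_id for s in samples]).T
    df.columns = [s.sample_id for s in samples]
    return CountMatrix(df, samples, pd.Series(libsize, index=df.columns))


class TestDispersions:
    def test_recovery_at_ten_replicates(self):
        """All genes at phi = 0.1 with 10 replicates per group: the median
        estimate lands within +/-25% of the truth."""
        design = generate_design(["A"], ["control", "starvation"], [0], replicates=10)
        genes = generate_genes(300, seed=31)
        cfg = TruthConfig(frac_de=0.0, dispersion_range=(0.1, 0.1), bias_strength=0.0)
        cm, _ = generate_counts(design, genes, cfg, seed=32)
        disp = estimate_dispersions(cm)
        assert 0.075 <= disp.dispersion.median() <= 0.125

    def test_poisson_data_yields_near_zero_dispersion(self):
        design = generate_design(["A"], ["control"], [0], replicates=10)
        genes = generate_genes(300, seed=33)
        cfg = TruthConfig(frac_de=0.0, dispersion_range=(0.0, 0.0), bias_strength=0.0)
        cm, _ = generate_counts(design, genes, cfg, seed=34)
        disp = estimate_dispersions(cm)
        assert (disp.dispersion_raw <= 0.01).mean() >= 0.9

    def test_constant_gene_hits_floor_without_crashing(self):
        cm = _two_group_matrix({"g0": [7] * 6, "g1": [0, 3, 9, 2, 8, 4]})
        disp = estimate_dispersions(cm)
        assert disp.loc["g0", "dispersion_raw"] <= 1e-6

    def test_single_replicate_group_is_error_naming_group(self):
        samples = [
            SampleDescriptor("a", "A", "control", 0.0, 1),
            SampleDescriptor("b", "A", "control", 0.0, 2),
            SampleDescriptor("c", "A", "starvation", 15.0, 1),
        ]
        df = pd.DataFrame([[5, 6, 7]], index=["g"], columns=["a", "b", "c"])
        cm = CountMatrix(df, samples)
        with pytest.raises(ValidationError, match="starvation"):
            estimate_dispersions(cm)


class TestNbGlm:
    def test_exact_log2fc_for_equal_libsizes(self):
        y = np.array([10, 10, 10, 20, 20, 20], dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(y, X, phi=0.1)
        assert fit["coef"][1] / np.log(2) == pytest.approx(1.0, abs=1e-8)
        assert fit["converged"]

    def test_identical_groups_give_zero_fc(self):
        y = np.array([15, 15, 15, 15, 15, 15], dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(y, X, phi=0.1)
        assert abs(fit["coef"][1]) < 1e-10
        p = de_threshold(fit["coef"][1], fit["se"][1], tau_log2=0.0)
        assert p[0] > 0.9

    def test_phi_to_zero_matches_poisson_oracle(self):
        """With phi = 1e-8 the NB IRLS coincides with an independent Poisson
        GLM (statsmodels) to 1e-6 on random data."""
        rng = np.random.default_rng(35)
        X = np.column_stack([np.ones(12), rng.integers(0, 2, 12), rng.normal(0, 1, 12)])
        offset = rng.normal(8, 0.2, 12)
        y = rng.poisson(np.exp(X @ np.array([0.5, 0.8, -0.3]) + offset))
        fit = fit_nb_glm(y.astype(float), X, offset=offset, phi=1e-8)
        oracle = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        np.testing.assert_allclose(fit["coef"], oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit["se"], oracle.bse, rtol=1e-4)

    def test_rank_deficient_design_is_error(self):
        y = np.array([1.0, 2.0, 3.0])
        X = np.column_stack([np.ones(3), np.ones(3)])
        with pytest.raises(ValidationError, match="full rank"):
            fit_nb_glm(y, X)


class TestThresholdTest:
    def test_tau_zero_reduces_to_two_sided_wald(self):
        p = de_threshold(np.array([1.96]), np.array([1.0]), tau_log2=0.0)
        assert p[0] == pytest.approx(0.05, abs=5e-4)

    def test_estimate_at_threshold_gives_p_above_half(self):
        tau = np.log2(1.2)
        se = 0.3
        p = de_threshold(np.array([tau]), np.array([se]), tau_log2=tau)
        expected = 0.5 + norm.sf(2 * tau / se)
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert p[0] >= 0.5

    def test_huge_effect_tiny_se_gives_tiny_p(self):
        p = de_threshold(np.array([5.0]), np.array([0.01]), tau_log2=np.log2(1.2))
        assert p[0] < 1e-12

    def test_invalid_se_is_error(self):
        with pytest.raises(ValidationError):
            de_threshold(np.array([1.0]), np.array([0.0]))


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05, 0.01], [0.05, 0.02]),
            ([0.07], [0.07]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(adjust_bh(np.array(p)), expected, atol=1e-12)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValidationError):
            adjust_bh(np.array([0.5, 1.5]))

    def test_against_brute_force_step_up_oracle(self):
        """1000 random vectors against a literal step-up implementation."""
        rng = np.random.default_rng(36)

        def oracle(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_values_in_unit_interval_and_rank_monotone(self, p):
        p = np.array(p)
        adj = adjust_bh(p)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRunContrast:
    def test_contrast_table_contract(self, small_study):
        cm, _ = small_study
        table = cm.sample_table()
        sub = cm.subset_samples(list(table.index[table.cell_line == "HeLa"]))
        disp = estimate_dispersions(sub)
        res = run_contrast(cm, "HeLa", "starvation", 15.0, disp)
        assert list(res.table.columns) == ["log2FC", "se", "p", "p_fdr", "dispersion", "converged"]
        assert res.table.p.between(0, 1).all()
        assert res.table.p_fdr.between(0, 1).all()
        assert (res.table.loc[~res.table.converged, "p"] == 1.0).all()

    def test_missing_samples_is_error(self, small_study):
        cm, _ = small_study
        disp = pd.Series(0.1, index=cm.genes)
        with pytest.raises(ValidationError, match="no samples"):
            run_contrast(cm, "U2OS", "starvation", 15.0, disp)
        with pytest.raises(ValidationError, match="replicates per group"):
            run_contrast(cm, "HeLa", "mtor_inhibition", 15.0, disp)
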