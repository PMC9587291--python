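"""Influence-matrix construction, propagation solve vs fixed-point oracle,
permutation null behaviour and cross-experiment consistency filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fluxseq.concordance import ConcordantDE
from fluxseq.errors import NumericalError, ValidationError
from fluxseq.perturbation import (
    accumulate_perturbation,
    consistency_filter,
    influence_vector,
    normalize_topology,
    permutation_null,
    perturbation_significance,
    run_perturbation_collection,
    score_pathway,
)
from fluxseq.types import PathwayTopology


def _random_dag(rng, n=None, p=0.15):
    n = n or int(rng.integers(4, 30))
    nodes = tuple(f"n{i}" for i in range(n))
    edges = [
        (nodes[i], nodes[j], int(rng.choice([1, -1])))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PathwayTopology("dag", nodes, edges)


def _conc(evidence: dict, line="A", trt="starvation"):
    df = pd.DataFrame(
        {
            "mean_log2FC": list(evidence.values()),
            "max_p_fdr": 0.01,
            "direction": ["up" if v > 0 else "down" for v in evidence.values()],
        },
        index=list(evidence),
    )
    df.index.name = "gene_id"
    return ConcordantDE(line, trt, df)


class TestNormalize:
    def test_single_activating_edge(self):
        pw = PathwayTopology("p", ("A", "B"), [("A", "B", 1)])
        B, nodes = normalize_topology(pw)
        assert nodes == ["A", "B"]
        assert B[1, 0] == 1.0 and B.sum() == 1.0

    def test_outdegree_splits_influence(self):
        pw = PathwayTopology("p", ("A", "B", "C"), [("A", "B", 1), ("A", "C", 1)])
        B, _ = normalize_topology(pw)
        assert B[1, 0] == 0.5 and B[2, 0] == 0.5

    def test_empty_edges_give_zero_matrix(self):
        pw = PathwayTopology("p", ("A", "B"), [])
        B, _ = normalize_topology(pw)
        assert not B.any()

    def test_absolute_columns_sum_to_one_for_sources(self, rng):
        pw = _random_dag(rng, n=20, p=0.3)
        B, nodes = normalize_topology(pw)
        outdeg = pw.outdegree
        for j, n in enumerate(nodes):
            expected = 1.0 if outdeg[n] > 0 else 0.0
            assert np.abs(B[:, j]).sum() == pytest.approx(expected)


class TestAccumulate:
    def test_activating_chain_hand_example(self):
        pw = PathwayTopology("p", ("A", "B", "C"), [("A", "B", 1), ("B", "C", 1)])
        B, _ = normalize_topology(pw)
        pf, acc, tA = accumulate_perturbation(B, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(pf, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(acc, [0.0, 1.0, 1.0])
        assert tA == pytest.approx(2.0)

    def test_inhibitory_edge_hand_example(self):
        pw = PathwayTopology("p", ("A", "B"), [("A", "B", -1)])
        B, _ = normalize_topology(pw)
        pf, acc, tA = accumulate_perturbation(B, np.array([1.0, 0.0]))
        np.testing.assert_allclose(pf, [1.0, -1.0])
        assert tA == pytest.approx(-1.0)

    def test_zero_evidence_gives_zero_score(self, rng):
        B, _ = normalize_topology(_random_dag(rng))
        pf, acc, tA = accumulate_perturbation(B, np.zeros(B.shape[0]))
        assert not pf.any() and not acc.any() and tA == 0.0

    def test_pure_two_cycle_is_unresolvable_unless_damped(self):
        pw = PathwayTopology("p", ("A", "B"), [("A", "B", 1), ("B", "A", 1)])
        B, _ = normalize_topology(pw)
        with pytest.raises(NumericalError, match="feedback"):
            accumulate_perturbation(B, np.array([1.0, 0.0]))
        pf, acc, tA = accumulate_perturbation(B, np.array([1.0, 0.0]), damping=0.9)
        assert np.isfinite(tA)

    def test_solve_matches_fixed_point_oracle(self, rng):
        """Linear solve equals iterating PF <- dE + B PF to convergence."""
        for _ in range(30):
            pw = _random_dag(rng)
            B, _ = normalize_topology(pw)
            n = B.shape[0]
            dE = np.where(rng.random(n) < 0.4, rng.normal(0, 1.5, n), 0.0)
            pf, _, _ = accumulate_perturbation(B, dE)
            x = dE.copy()
            for _ in range(5000):
                x_new = dE + B @ x
                if np.max(np.abs(x_new - x)) < 1e-13:
                    break
                x = x_new
            np.testing.assert_allclose(pf, x_new, atol=1e-10)

    def test_influence_vector_reproduces_total(self, rng):
        for _ in range(20):
            pw = _random_dag(rng)
            B, _ = normalize_topology(pw)
            n = B.shape[0]
            dE = np.where(rng.random(n) < 0.4, rng.normal(0, 1, n), 0.0)
            _, _, tA = accumulate_perturbation(B, dE)
            assert influence_vector(B) @ dE == pytest.approx(tA, abs=1e-10)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_total_is_linear_in_evidence(self, a, b):
        pw = PathwayTopology(
            "p", ("A", "B", "C", "D"),
            [("A", "B", 1), ("B", "C", -1), ("A", "D", 1), ("D", "C", 1)],
        )
        B, _ = normalize_topology(pw)
        e1 = np.array([1.0, 0.0, 0.0, 0.5])
        e2 = np.array([0.0, -2.0, 1.0, 0.0])
        _, _, t1 = accumulate_perturbation(B, e1)
        _, _, t2 = accumulate_perturbation(B, e2)
        _, _, t12 = accumulate_perturbation(B, a * e1 + b * e2)
        assert t12 == pytest.approx(a * t1 + b * t2, abs=1e-9)


class TestPermutationNull:
    def test_same_seed_identical_null(self, rng):
        pw = _random_dag(rng, n=15)
        dE = np.zeros(15)
        dE[[1, 3, 5]] = [1.0, -0.5, 2.0]
        a = permutation_null(pw, dE, n_perm=300, seed=7)
        b = permutation_null(pw, dE, n_perm=300, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, permutation_null(pw, dE, n_perm=300, seed=8))

    def test_full_occupancy_varies_only_by_value_shuffling(self, rng):
        """When every node carries evidence, the null permutes values over
        the whole node set; with all values equal it is degenerate."""
        pw = _random_dag(rng, n=8, p=0.4)
        dE = np.full(8, 1.5)
        null = permutation_null(pw, dE, n_perm=200, seed=1)
        assert np.allclose(null, null[0])

    def test_no_evidence_is_error(self, rng):
        pw = _random_dag(rng, n=6)
        with pytest.raises(ValidationError, match="skip"):
            permutation_null(pw, np.zeros(6), n_perm=200, seed=1)

    def test_symmetric_evidence_gives_centred_null(self, rng):
        pw = _random_dag(rng, n=20, p=0.2)
        dE = np.zeros(20)
        dE[[0, 1, 2, 3]] = [2.0, -2.0, 1.0, -1.0]
        null = permutation_null(pw, dE, n_perm=4000, seed=2)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se + 1e-12

    def test_too_few_permutations_is_error(self, rng):
        pw = _random_dag(rng, n=6)
        dE = np.zeros(6)
        dE[0] = 1.0
        with pytest.raises(ValidationError, match="n_perm"):
            permutation_null(pw, dE, n_perm=50, seed=1)


class TestSignificance:
    def test_pseudocount_p_value(self):
        null = np.linspace(0.01, 0.5, 99)  # all |null| < |obs|
        z, p = perturbation_significance(2.0, null)
        assert p == pytest.approx(1 / 100)

    def test_z_is_standardised_score(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 1, 100_000)
        z, _ = perturbation_significance(2.0, null)
        assert z == pytest.approx((2.0 - null.mean()) / null.std(ddof=1))
        assert z == pytest.approx(2.0, abs=0.05)

    def test_obs_equal_to_null_gives_p_one(self):
        null = np.full(500, 1.3)
        z, p = perturbation_significance(1.3, null)
        assert p == 1.0
        assert np.isnan(z)  # degenerate null flagged


class TestCollection:
    def test_single_pathway_fdr_equals_p(self, rng):
        pw = _random_dag(rng, n=10, p=0.3)
        conc = _conc({pw.nodes[0]: 2.0, pw.nodes[1]: -1.0})
        out = run_perturbation_collection([pw], conc, n_perm=200, seed=5)
        assert out.p_fdr.iloc[0] == out.p_perm.iloc[0]
        assert out.p_perm.iloc[0] >= 1 / 201

    def test_duplicated_pathway_gets_identical_scores(self, rng):
        pw = _random_dag(rng, n=10, p=0.3)
        dup = PathwayTopology("copy", pw.nodes, list(pw.edges))
        conc = _conc({pw.nodes[0]: 2.0})
        out = run_perturbation_collection([pw, dup], conc, n_perm=200, seed=5)
        assert out.tA.iloc[0] == out.tA.iloc[1]

    def test_pathway_without_evidence_is_skipped(self, rng):
        pw = _random_dag(rng, n=8)
        conc = _conc({"absent_gene": 2.0})
        out = run_perturbation_collection([pw], conc, n_perm=200, seed=5)
        assert len(out) == 0

    def test_deterministic_given_seed(self, rng):
        pws = [
            PathwayTopology(f"pw{i}", dag.nodes, dag.edges)
            for i, dag in enumerate(_random_dag(rng, n=12, p=0.25) for _ in range(3))
        ]
        conc = _conc({pws[0].nodes[0]: 1.5, pws[1].nodes[2]: -2.0, pws[2].nodes[1]: 1.0})
        a = run_perturbation_collection(pws, conc, n_perm=300, seed=9)
        b = run_perturbation_collection(pws, conc, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestConsistencyFilter:
    def _results(self, zs_sig):
        """Build one single-pathway result table per experiment."""
        out = {}
        for i, (z, sig) in enumerate(zs_sig):
            out[("L" + str(i), "t")] = pd.DataFrame(
                {"pathway": ["P"], "z": [z], "p_perm": [0.01 if sig else 0.5],
                 "p_fdr": [0.01 if sig else 0.5]}
            )
        return out

    def test_three_concordant_significant_signals_retained(self):
        res = self._results([(2, True), (3, True), (4, True), (1, False), (-1, False), (0.5, False)])
        out = consistency_filter(res)
        assert list(out.pathway) == ["P"]
        assert out.direction.iloc[0] == "up"

    def test_discordant_significant_signals_dropped(self):
        res = self._results([(2, True), (3, True), (-4, True)])
        assert len(consistency_filter(res)) == 0

    def test_two_significant_signals_not_enough(self):
        res = self._results([(2, True), (3, True), (4, False)])
        assert len(consistency_filter(res)) == 0
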