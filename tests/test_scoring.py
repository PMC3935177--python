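"""Marginal-likelihood scoring against independent oracles.

Oracles used here are deliberately independent of the engine's closed
forms: the sequential-predictive (chain rule) construction for discrete
models, and direct 2-D numerical integration over (mean, variance) for the
normal-inverse-gamma models.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import dirichlet_chain_rule, nig_numeric_log_marginal

from npars.dag import Dag, phenotype, snp, transcript
from npars.scoring import (
    DEFAULT_PRIOR,
    PriorSpec,
    ScoreError,
    ScoringEngine,
    local_log_marginal_continuous,
    local_log_marginal_discrete,
    network_score,
)


class TestDiscreteLocal:
    def test_two_observation_worked_example(self):
        node = snp("A", levels=2)
        data = pd.DataFrame({"A": [0, 1]})
        val = local_log_marginal_discrete(node, [], data)
        assert val == pytest.approx(math.log(0.5 * (1 / 3)), abs=1e-12)

    def test_zero_observations_scores_zero(self):
        node = snp("A", levels=3)
        data = pd.DataFrame({"A": pd.Series([], dtype=int)})
        assert local_log_marginal_discrete(node, [], data) == 0.0

    @pytest.mark.parametrize("seq", [(0, 1, 1, 2, 0), (2, 2, 0, 1, 1)])
    def test_matches_chain_rule_oracle(self, seq):
        node = snp("A", levels=3)
        data = pd.DataFrame({"A": list(seq)})
        expected = dirichlet_chain_rule(seq, 3, 1.0)
        assert local_log_marginal_discrete(node, [], data) == pytest.approx(
            expected, abs=1e-10
        )

    def test_order_invariance(self, rng):
        node = snp("A", levels=3)
        seq = rng.integers(0, 3, 40)
        v1 = local_log_marginal_discrete(node, [], pd.DataFrame({"A": seq}))
        v2 = local_log_marginal_discrete(
            node, [], pd.DataFrame({"A": rng.permutation(seq)})
        )
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_parent_configurations_decompose(self, rng):
        child = snp("A", levels=2)
        parent = snp("B", levels=2)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        df = pd.DataFrame({"A": a, "B": b})
        whole = local_log_marginal_discrete(child, [parent], df)
        split = sum(
            local_log_marginal_discrete(child, [], df[df.B == j][["A"]])
            for j in (0, 1)
        )
        assert whole == pytest.approx(split, abs=1e-10)

    @pytest.mark.parametrize("n", [2, 3])
    def test_predictive_normalization(self, n):
        """Sum of P(sequence) over all binary sequences of length n is 1."""
        node = snp("A", levels=2)
        total = 0.0
        for seq in itertools.product((0, 1), repeat=n):
            df = pd.DataFrame({"A": list(seq)})
            total += math.exp(local_log_marginal_discrete(node, [], df))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_continuous_parent_is_model_error(self):
        node = snp("A", levels=2)
        data = pd.DataFrame({"A": [0, 1], "Y": [0.1, 0.2]})
        eng = ScoringEngine(data, [node, transcript("Y")], DEFAULT_PRIOR)
        with pytest.raises(ScoreError, match="continuous"):
            eng.local_score("A", ["Y"])


class TestContinuousLocal:
    def test_single_observation_student_t(self):
        # one y = 0, default prior: Student-t, df rho, scale^2 phi(1+1/tau)/rho
        val = local_log_marginal_continuous(
            transcript("Y"), [], [], pd.DataFrame({"Y": [0.0]}), DEFAULT_PRIOR
        )
        expected = stats.t.logpdf(0.0, df=1.0, loc=0.0, scale=math.sqrt(2.0))
        assert val == pytest.approx(expected, abs=1e-10)
        assert val == pytest.approx(-1.491, abs=5e-4)

    def test_zero_observations_scores_zero(self):
        val = local_log_marginal_continuous(
            transcript("Y"), [], [],
            pd.DataFrame({"Y": pd.Series([], dtype=float)}), DEFAULT_PRIOR,
        )
        assert val == 0.0

    def test_matches_numeric_integration_intercept_only(self, rng):
        for _ in range(3):
            y = rng.normal(0.5, 1.2, size=3)
            df = pd.DataFrame({"Y": y})
            closed = local_log_marginal_continuous(
                transcript("Y"), [], [], df, DEFAULT_PRIOR
            )
            oracle = nig_numeric_log_marginal(y, np.ones((len(y), 1)),
                                              DEFAULT_PRIOR)
            assert closed == pytest.approx(oracle, abs=1e-4)

    def test_matches_numeric_integration_with_slope(self, rng):
        prior = PriorSpec(nig_mu=0.3, nig_tau=2.0, nig_rho=3.0, nig_phi=1.5)
        for _ in range(3):
            n = int(rng.integers(2, 5))
            x = rng.normal(0, 1, n)
            y = 0.4 * x + rng.normal(0, 1, n)
            df = pd.DataFrame({"Y": y, "X": x})
            closed = local_log_marginal_continuous(
                transcript("Y"), [transcript("X")], [], df, prior
            )
            oracle = nig_numeric_log_marginal(
                y, np.column_stack([np.ones(n), x]), prior
            )
            assert closed == pytest.approx(oracle, abs=1e-4)

    def test_matches_numeric_integration_with_discrete_parent(self, rng):
        l = np.array([0, 1, 1, 0])
        y = rng.normal(0, 1, 4)
        df = pd.DataFrame({"Y": y, "L": l})
        closed = local_log_marginal_continuous(
            transcript("Y"), [], [snp("L", levels=2)], df, DEFAULT_PRIOR
        )
        oracle = sum(
            nig_numeric_log_marginal(y[l == j], np.ones((2, 1)), DEFAULT_PRIOR)
            for j in (0, 1)
        )
        assert closed == pytest.approx(oracle, abs=1e-4)

    def test_discrete_parent_configurations_decompose(self, rng):
        l = rng.integers(0, 2, 24)
        y = rng.normal(5, 2, 24)
        df = pd.DataFrame({"Y": y, "L": l})
        whole = local_log_marginal_continuous(
            transcript("Y"), [], [snp("L", levels=2)], df, DEFAULT_PRIOR
        )
        parts = sum(
            local_log_marginal_continuous(
                transcript("Y"), [], [],
                df[df.L == j][["Y"]], DEFAULT_PRIOR,
            )
            for j in (0, 1)
        )
        assert whole == pytest.approx(parts, abs=1e-10)

    def test_missing_data_refused(self):
        df = pd.DataFrame({"Y": [1.0, np.nan]})
        with pytest.raises(ScoreError, match="missing"):
            local_log_marginal_continuous(transcript("Y"), [], [], df)


class TestNetworkScore:
    def test_empty_dag_is_sum_of_parentless_locals(self, rng):
        nodes = [snp("L"), transcript("E"), phenotype("D")]
        df = pd.DataFrame({
            "L": rng.integers(0, 3, 20),
            "E": rng.normal(10, 3, 20),
            "D": rng.normal(0, 1, 20),
        })
        dag = Dag(nodes, [])
        expected = (
            local_log_marginal_discrete(nodes[0], [], df[["L"]])
            + local_log_marginal_continuous(nodes[1], [], [], df[["E"]])
            + local_log_marginal_continuous(nodes[2], [], [], df[["D"]])
        )
        assert network_score(dag, df) == pytest.approx(expected, abs=1e-10)

    def test_two_binary_nodes_chain_rule_oracle(self):
        """S({A->B}) equals the log joint marginal computed by sequential
        prediction over (A, B) pairs."""
        a = [0, 1, 0, 1]
        b = [0, 0, 1, 1]
        from npars.dag import AdmissibilityRules

        nodes = [snp("A", levels=2), snp("B", levels=2)]
        df = pd.DataFrame({"A": a, "B": b})
        dag = Dag(nodes, [("A", "B")],
                  rules=AdmissibilityRules(allow_l_parents=True))
        # oracle: P(a-sequence) * prod_j P(b-subsequence within config j)
        expected = dirichlet_chain_rule(a, 2, 1.0)
        for j in (0, 1):
            sub = [bv for av, bv in zip(a, b) if av == j]
            expected += dirichlet_chain_rule(sub, 2, 1.0)
        assert network_score(dag, df, DEFAULT_PRIOR) == pytest.approx(
            expected, abs=1e-10
        )

    def test_determinism(self, scenario1_small):
        eng = ScoringEngine(scenario1_small.data, scenario1_small.nodes)
        dag = Dag(scenario1_small.nodes,
                  [("L1", "E1"), ("E1", "D"), ("E2", "D")], validate=False)
        assert eng.network_score(dag) == eng.network_score(dag)

    def test_decomposability_bit_identical(self, scenario1_small):
        """Changing one node's parents leaves other local terms unchanged."""
        eng = ScoringEngine(scenario1_small.data, scenario1_small.nodes)
        names = [n.name for n in scenario1_small.nodes]
        locals_before = {
            n: eng.local_score(n, ["E1"] if n == "D" else []) for n in names
        }
        # alter D's parent set only
        locals_after = {
            n: eng.local_score(n, ["E1", "E2"] if n == "D" else [])
            for n in names
        }
        for n in names:
            if n != "D":
                assert locals_before[n] == locals_after[n]

    def test_true_edge_beats_empty_with_high_frequency(self):
        """With a strong effect and large n the single-edge model should
        out-score independence in (nearly) every replicate."""
        from npars.simulate import ScenarioSpec, simulate_scenario

        wins = 0
        for rep in range(10):
            sim = simulate_scenario(ScenarioSpec(1, 1.5, 400, seed=rep))
            eng = ScoringEngine(sim.data, sim.nodes)
            with_edge = eng.local_score("D", ["E1"])
            without = eng.local_score("D", [])
            wins += with_edge > without
        assert wins >= 9

    def test_fixed_prior_reproducible_across_datasets(self, rng):
        """A fixed PriorSpec gives the same local score for identical
        columns regardless of the rest of the dataset (empirical mode does
        not, by design)."""
        y = rng.normal(0, 1, 15)
        df1 = pd.DataFrame({"Y": y, "Z": rng.normal(5, 2, 15)})
        df2 = pd.DataFrame({"Y": y, "Z": rng.normal(-3, 7, 15)})
        n = [transcript("Y"), transcript("Z")]
        e1 = ScoringEngine(df1, n, DEFAULT_PRIOR)
        e2 = ScoringEngine(df2, n, DEFAULT_PRIOR)
        assert e1.local_score("Y", []) == e2.local_score("Y", [])


class TestEmpiricalPrior:
    def test_centres_on_column_moments(self, rng):
        y = rng.normal(50, 4, 200)
        df = pd.DataFrame({"Y": y})
        emp = ScoringEngine(df, [transcript("Y")], None)
        fixed = ScoringEngine(
            df, [transcript("Y")],
            PriorSpec(nig_mu=float(y.mean()), nig_phi=float(y.var(ddof=1))),
        )
        assert emp.local_score("Y", []) == fixed.local_score("Y", [])

    def test_mislocated_fixed_prior_scores_lower(self, rng):
        """The empirical prior should dominate a zero-centred unit-scale
        prior on far-from-zero data."""
        y = rng.normal(50, 4, 100)
        df = pd.DataFrame({"Y": y})
        emp = ScoringEngine(df, [transcript("Y")], None)
        fixed = ScoringEngine(df, [transcript("Y")], DEFAULT_PRIOR)
        assert emp.local_score("Y", []) > fixed.local_score("Y", [])
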