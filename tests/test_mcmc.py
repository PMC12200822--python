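import numpy as np
import pytest
from scipy.special import logsumexp

from cairs.bge import BgeScorer
from cairs.decision import effective_sample_size
from cairs.graphs import Dag, Partition, compatible_dags, temporal_allowed_masks
from cairs.mcmc import (
    DagSampleSet,
    PartitionMCMC,
    consensus_graph,
    convergence_report,
    edge_probabilities,
    enumerate_posterior,
    partition_score,
    path_probabilities,
    path_probability,
    run_partition_mcmc,
)


def _sample_set(dag_parent_tuples, n_nodes, n_chains=1, chain_ids=None):
    k = len(dag_parent_tuples)
    return DagSampleSet(
        n_nodes=n_nodes,
        node_names=tuple(f"x{i}" for i in range(n_nodes)),
        dags=list(dag_parent_tuples),
        chain_ids=np.asarray(
            chain_ids if chain_ids is not None else [0] * k, dtype=np.int64
        ),
        n_chains=n_chains,
        seeds=[0] * n_chains,
        acceptance_rates=[0.0] * n_chains,
    )


class TestPartitionScore:
    def test_agrees_with_explicit_enumeration(self, chain_data):
        rng = np.random.default_rng(9)
        X = np.hstack([chain_data, rng.normal(size=(len(chain_data), 1))])
        part = Partition.from_lists(4, [[1], [0, 2], [3]])
        sc = BgeScorer(X)
        brute = logsumexp([sc.dag_score(d) for d in compatible_dags(part)])
        assert partition_score(part, X) == pytest.approx(brute, abs=1e-8)

    def test_single_block_equals_empty_graph_score(self, chain_data):
        part = Partition.single_block(3)
        sc = BgeScorer(chain_data)
        assert partition_score(part, chain_data) == pytest.approx(
            sc.dag_score(Dag(3, (0, 0, 0))), abs=1e-10
        )

    def test_finite_for_valid_partitions(self, chain_data):
        for blocks in ([[0], [1], [2]], [[2], [0, 1]], [[0, 1, 2]]):
            val = partition_score(
                Partition.from_lists(3, blocks), chain_data
            )
            assert np.isfinite(val)

    def test_respects_max_parents(self, chain_data):
        rng = np.random.default_rng(9)
        X = np.hstack([chain_data, rng.normal(size=(len(chain_data), 1))])
        part = Partition.from_lists(4, [[0, 1, 2], [3]])
        sc = BgeScorer(X)
        brute = logsumexp(
            [sc.dag_score(d) for d in compatible_dags(part, max_parents=1)]
        )
        assert partition_score(part, X, max_parents=1) == pytest.approx(
            brute, abs=1e-8
        )


class TestEnumeratePosterior:
    def test_two_node_orientation_split(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        y = 0.9 * x + 0.3 * rng.normal(size=400)
        probs = enumerate_posterior(np.column_stack([x, y]))
        # strong dependence: an edge in one of the two directions is near
        # certain and, being Markov equivalent, split evenly
        assert probs[0, 1] + probs[1, 0] > 0.99
        assert probs[0, 1] == pytest.approx(probs[1, 0], abs=1e-9)

    def test_temporal_constraint_zeroes_backward_edges(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = 0.8 * x + 0.5 * rng.normal(size=300)
        probs = enumerate_posterior(
            np.column_stack([x, y]), allowed=temporal_allowed_masks(1)
        )
        assert probs[1, 0] == 0.0
        assert probs[0, 1] > 0.9

    def test_node_guard(self):
        with pytest.raises(ValueError, match="5 nodes"):
            enumerate_posterior(np.zeros((10, 6)))


class TestSamplerCorrectness:
    def test_matches_exact_posterior_on_three_nodes(self, chain_data):
        """Sampled edge probabilities agree with the 25-DAG enumeration."""
        exact = enumerate_posterior(chain_data)
        samples = run_partition_mcmc(
            chain_data,
            chains=4,
            iterations=8000,
            burn_in=2000,
            thin=10,
            temporal=False,
            max_parents=None,
            seed=11,
        )
        est = edge_probabilities(samples)
        masks = samples.edge_matrix()
        for u in range(3):
            for v in range(3):
                if u == v:
                    continue
                per_chain_ess = []
                for c in range(samples.n_chains):
                    series = (
                        (masks[samples.chain_ids == c, v] >> u) & 1
                    ).astype(float)
                    per_chain_ess.append(effective_sample_size(series))
                n_eff = sum(per_chain_ess)
                p = est[u, v]
                p_shrunk = (p * n_eff + 2) / (n_eff + 4)
                se = np.sqrt(p_shrunk * (1 - p_shrunk) / n_eff)
                assert abs(p - exact[u, v]) <= 3 * se

    def test_determinism_under_master_seed(self, chain_data):
        kw = dict(
            chains=2, iterations=600, burn_in=200, thin=20, seed=42, temporal=False
        )
        s1 = run_partition_mcmc(chain_data, **kw)
        s2 = run_partition_mcmc(chain_data, **kw)
        assert s1.dags == s2.dags
        assert s1.seeds == s2.seeds
        assert s1.acceptance_rates == s2.acceptance_rates

    def test_all_draws_respect_temporal_constraint(self, panel3):
        from cairs.bge import ordinal_encode

        X = ordinal_encode(panel3)
        samples = run_partition_mcmc(
            X, chains=2, iterations=1500, burn_in=500, thin=10, seed=3
        )
        allowed = temporal_allowed_masks(3)
        for dag in samples.iter_dags():
            assert dag.respects(allowed)  # acyclic by construction of Dag

    def test_visits_partitions_of_many_sizes(self):
        # near-independent data: the posterior supports coarse and fine
        # partitions, and the chain should visit a range of DAG densities
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        samples = run_partition_mcmc(
            X, chains=1, iterations=4000, burn_in=1000, thin=5,
            temporal=False, seed=5,
        )
        edge_counts = {sum(bin(m).count("1") for m in d) for d in samples.dags}
        assert len(edge_counts) >= 2 and 0 in edge_counts

    def test_invalid_config_rejected(self, chain_data):
        with pytest.raises(ValueError, match="burn_in"):
            PartitionMCMC(n_iterations=10, burn_in=20).fit(chain_data)
        with pytest.raises(ValueError, match="even column count"):
            PartitionMCMC(
                n_iterations=10, burn_in=5, temporal=True
            ).fit(chain_data)


class TestSummaries:
    def test_identical_draws_give_binary_probabilities(self):
        parents = (0, 1, 0)  # edge 0 -> 1
        s = _sample_set([parents] * 5, 3)
        probs = edge_probabilities(s)
        assert set(np.unique(probs)) <= {0.0, 1.0}
        assert probs[0, 1] == 1.0

    def test_edge_probabilities_mutually_exclusive(self, chain_data):
        samples = run_partition_mcmc(
            chain_data, chains=1, iterations=1000, burn_in=200, thin=10,
            temporal=False, seed=1,
        )
        probs = edge_probabilities(samples)
        for u in range(3):
            for v in range(u + 1, 3):
                assert probs[u, v] + probs[v, u] <= 1.0 + 1e-12

    def test_path_probability_bounds_and_chain(self):
        chain = Dag.from_edges(3, [(0, 1), (1, 2)])
        s = _sample_set([chain.parents] * 4, 3)
        assert path_probability(s, 0, 2) == 1.0
        assert edge_probabilities(s)[0, 2] == 0.0
        with pytest.raises(ValueError):
            path_probability(s, 1, 1)

    def test_p_path_at_least_p_parent_on_random_draws(self, panel3):
        from cairs.bge import ordinal_encode

        samples = run_partition_mcmc(
            ordinal_encode(panel3), chains=2, iterations=1200, burn_in=400,
            thin=20, seed=9,
        )
        assert np.all(
            path_probabilities(samples) >= edge_probabilities(samples) - 1e-12
        )

    def test_path_probability_matches_reachability_count(self):
        rng = np.random.default_rng(4)
        draws = []
        for _ in range(100):
            order = rng.permutation(5)
            edges = [
                (int(order[i]), int(order[j]))
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.3
            ]
            draws.append(Dag.from_edges(5, edges).parents)
        s = _sample_set(draws, 5)
        got = path_probabilities(s)
        import networkx as nx

        brute = np.zeros((5, 5))
        for parents in draws:
            g = Dag(5, parents).to_networkx()
            for u in range(5):
                for v in nx.descendants(g, str(u)):
                    brute[u, int(v)] += 1
        np.testing.assert_allclose(got, brute / len(draws), atol=1e-12)

    def test_consensus_thresholds(self):
        always = Dag.from_edges(3, [(0, 1)]).parents
        sometimes = Dag.from_edges(3, [(0, 1), (1, 2)]).parents
        s = _sample_set([always, always, always, sometimes], 3)
        keep_all = consensus_graph(s, threshold=0.0)
        assert {(e["parent"], e["child"]) for e in keep_all.edges()} == {
            ("x0", "x1"),
            ("x1", "x2"),
        }
        only_certain = consensus_graph(s, threshold=1.0)
        assert only_certain.edges() == []
        default = consensus_graph(s)
        assert default.threshold == 0.10

    def test_consensus_edge_kind_labels(self):
        # 2 domains, 4 nodes: AR edge 0->2, lagged 0->3, within-followup 2->3
        dag = Dag.from_edges(4, [(0, 2), (0, 3), (2, 3)])
        s = _sample_set([dag.parents] * 3, 4)
        kinds = {
            (e["parent"], e["child"]): e["kind"]
            for e in consensus_graph(s, 0.05, n_baseline=2).edges()
        }
        assert kinds[("x0", "x2")] == "autoregressive"
        assert kinds[("x0", "x3")] == "lagged"
        assert kinds[("x2", "x3")] == "within_followup"


class TestConvergence:
    def test_identical_chains_pass(self):
        dag = Dag.from_edges(3, [(0, 1)]).parents
        s = _sample_set([dag] * 6, 3, n_chains=2, chain_ids=[0, 0, 0, 1, 1, 1])
        rep = convergence_report(s)
        assert rep.max_spread == 0.0 and rep.passed

    def test_disagreeing_chains_fail(self):
        empty = (0, 0, 0)
        full_chain = Dag.from_edges(3, [(0, 1), (1, 2), (0, 2)]).parents
        s = _sample_set(
            [empty] * 3 + [full_chain] * 3, 3, n_chains=2,
            chain_ids=[0, 0, 0, 1, 1, 1],
        )
        rep = convergence_report(s)
        assert rep.max_spread == 1.0 and not rep.passed

    def test_single_chain_refused(self):
        s = _sample_set([(0, 0, 0)] * 3, 3)
        with pytest.raises(ValueError, match="2 chains"):
            convergence_report(s)

    def test_well_mixed_small_problem_converges(self, chain_data):
        samples = run_partition_mcmc(
            chain_data, chains=4, iterations=80_000, burn_in=10_000, thin=10,
            temporal=False, max_parents=None, seed=11,
        )
        assert convergence_report(samples).max_spread < 0.05


def test_sample_set_json_round_trip(chain_data):
    s = run_partition_mcmc(
        chain_data, chains=2, iterations=400, burn_in=100, thin=20,
        temporal=False, seed=8,
    )
    again = DagSampleSet.from_dict(s.to_dict())
    assert again.dags == s.dags
    assert again.node_names == s.node_names
    np.testing.assert_array_equal(again.chain_ids, s.chain_ids)
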