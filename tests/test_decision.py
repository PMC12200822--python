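import numpy as np
import pytest

from cairs.bayesnet import CategoricalBn, Cpt, fit_cpts
from cairs.decision import (
    NOTHING,
    Action,
    UtilitySpec,
    ate,
    baseline_weights_from_panel,
    expected_utility,
    p_opt_summary,
    posterior_eu,
    rank_targets,
    sensitivity_table,
    utility,
)
from cairs.domains import DomainRegistry, ProfileState
from cairs.graphs import Dag

UNIFORM = np.full(3, 1 / 3)


def build_bn(registry, edges, followup_tables):
    """BN with uniform baseline CPTs and given follow-up CPTs."""
    k = len(registry)
    dag = Dag.from_edges(2 * k, edges)
    cpts = []
    for j in range(2 * k):
        parents = tuple(sorted(p for p, c in edges if c == j))
        if j < k:
            cpts.append(Cpt(j, parents, UNIFORM))
        else:
            cpts.append(Cpt(j, parents, np.asarray(followup_tables[j - k])))
    return CategoricalBn(registry, dag, tuple(cpts))


def point(level):
    out = np.zeros(3)
    out[level] = 1.0
    return out


class TestUtility:
    def test_bounds_default_spec(self, reg7):
        assert utility(ProfileState(reg7, (2,) * 7)) == pytest.approx(7.0)
        assert utility(ProfileState(reg7, (0,) * 7)) == pytest.approx(0.0)

    def test_all_fair(self, reg7):
        assert utility(ProfileState(reg7, (1,) * 7)) == pytest.approx(5.25)

    def test_single_transition_worth_one(self, reg7):
        state = ProfileState(reg7, (0, 1, 2, 0, 1, 2, 0))
        for d in reg7:
            lifted = state.replace(d, 2).replace(d, 2)
            base = state.replace(d, 0)
            assert utility(base.replace(d, 2)) - utility(base) == pytest.approx(1.0)

    def test_weights_applied(self, reg3):
        spec = UtilitySpec(weights={"a": 2.0, "b": 1.0, "c": 0.0})
        assert utility(ProfileState(reg3, (2, 2, 2)), spec) == pytest.approx(3.0)

    def test_non_monotone_subutility_rejected(self):
        with pytest.raises(ValueError):
            UtilitySpec(subutility=(0.0, 1.0, 0.5))


class TestExpectedUtility:
    def test_deterministic_all_healthy_bn(self, reg3):
        bn = build_bn(reg3, [], [point(2)] * 3)
        base = ProfileState(reg3, (0, 0, 0))
        for action in [NOTHING, Action("a"), Action("b")]:
            assert expected_utility(bn, base, action) == pytest.approx(3.0)

    def test_childless_do_identity(self, truth3, panel3):
        # do(d) on a childless follow-up node: EU gain is exactly
        # w_d * (1 - E[u(d)] under nothing)
        dag = Dag.from_edges(6, [(0, 3), (1, 4), (2, 5), (3, 5)])
        bn = fit_cpts(dag, panel3)
        base = ProfileState(bn.registry, (0, 1, 2))
        spec = UtilitySpec()
        eu_nothing = expected_utility(bn, base, NOTHING, spec)
        from cairs.bayesnet import followup_distribution

        marg_b = followup_distribution(bn, base).marginal("b")
        eu_do = expected_utility(bn, base, Action("b"), spec)
        assert eu_do == pytest.approx(
            eu_nothing + 1.0 * (1.0 - marg_b @ spec.u()), abs=1e-12
        )

    def test_matches_monte_carlo(self, truth3, panel3):
        bn = fit_cpts(truth3.dag, panel3)
        base = ProfileState(bn.registry, (1, 0, 2))
        spec = UtilitySpec()
        exact = expected_utility(bn, base, Action("a"), spec)
        from cairs.bayesnet import mutilate

        mut = mutilate(bn, "a")
        rng = np.random.default_rng(55)
        n = 100_000
        codes = np.zeros((n, 6), dtype=np.int64)
        codes[:, :3] = np.array(base.levels)
        for j in [v for v in mut.dag.topological_order() if v >= 3]:
            cpt = mut.cpts[j]
            rows = (
                cpt.table[tuple(codes[:, q] for q in cpt.parents)]
                if cpt.parents
                else np.broadcast_to(cpt.table, (n, 3))
            )
            u = rng.random(n)
            codes[:, j] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        utils = spec.u()[codes[:, 3:]].sum(axis=1)
        mc = utils.mean()
        se = utils.std(ddof=1) / np.sqrt(n)
        assert abs(mc - exact) < 3 * se


class TestPosteriorEu:
    def test_identical_samples_zero_se(self, truth3, panel3):
        bn = fit_cpts(truth3.dag, panel3)
        base = ProfileState(bn.registry, (0, 0, 0))
        mean, se = posterior_eu([bn] * 5, base)
        assert se == 0.0
        assert mean == pytest.approx(expected_utility(bn, base))

    def test_mean_invariant_to_order(self, truth3, panel3):
        dags = [
            Dag.from_edges(6, [(0, 3), (1, 4), (2, 5)]),
            Dag.from_edges(6, [(0, 3), (1, 4), (2, 5), (3, 4)]),
            truth3.dag,
        ]
        bns = [fit_cpts(d, panel3) for d in dags]
        base = ProfileState(panel3.registry, (1, 1, 1))
        m1, _ = posterior_eu(bns, base)
        m2, _ = posterior_eu(bns[::-1], base)
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_single_sample_refused(self, truth3, panel3):
        bn = fit_cpts(truth3.dag, panel3)
        with pytest.raises(ValueError, match="2 posterior samples"):
            posterior_eu([bn], ProfileState(bn.registry, (0, 0, 0)))


class TestAte:
    def test_deterministic_healthy_childless_target_zero(self, reg3):
        tables = [point(2), UNIFORM.copy(), UNIFORM.copy()]
        bn = build_bn(reg3, [], tables)
        base = ProfileState(reg3, (2, 2, 2))
        assert ate([bn, bn], base, "a") == pytest.approx(0.0, abs=1e-12)

    def test_childless_target_nonnegative(self, truth3, panel3):
        dag = Dag.from_edges(6, [(0, 3), (1, 4), (2, 5), (3, 5)])
        bn = fit_cpts(dag, panel3)
        for codes in [(0, 0, 0), (2, 1, 0), (1, 1, 1)]:
            base = ProfileState(bn.registry, codes)
            for spec in [UtilitySpec.preset(n) for n in ("default", "risk_neutral")]:
                assert ate([bn, bn], base, "b", spec) >= -1e-12

    def test_cross_domain_effects_exceed_single_domain_bound(self):
        # hub domain whose intervention lifts three descendants: ATE > 1,
        # unreachable by any single-domain transition alone
        reg = DomainRegistry(("hub", "x", "y", "z"))
        k = 4
        edges = [(k + 0, k + 1), (k + 0, k + 2), (k + 0, k + 3)]
        stay_poor = point(0)
        child = np.stack([point(0), point(0), point(2)])  # healthy iff hub healthy
        bn = build_bn(reg, edges, [stay_poor, child, child, child])
        base = ProfileState(reg, (0, 0, 0, 0))
        assert expected_utility(bn, base, NOTHING) == pytest.approx(0.0)
        got = ate([bn, bn], base, "hub")
        assert got == pytest.approx(4.0)
        assert got > 1.0

    def test_paired_ate_equals_difference_of_means(self, truth3, panel3):
        dags = [truth3.dag, Dag.from_edges(6, [(0, 3), (1, 4), (2, 5)])]
        bns = [fit_cpts(d, panel3) for d in dags]
        base = ProfileState(panel3.registry, (0, 2, 1))
        m_do, _ = posterior_eu(bns, base, Action("a"))
        m_no, _ = posterior_eu(bns, base, NOTHING)
        assert ate(bns, base, "a") == pytest.approx(m_do - m_no, abs=1e-12)


class TestRankTargets:
    def test_unhealthiest_domain_ranks_first_on_edge_free_bn(self, reg3):
        # AR-only persistence: the one poor domain is the clear target
        persist = np.stack([point(0), point(1), point(2)])
        bn = build_bn(
            reg3, [(0, 3), (1, 4), (2, 5)], [persist, persist, persist]
        )
        base = ProfileState(reg3, (2, 0, 2))
        result = rank_targets([bn, bn], base)
        assert result.ranking[0] == "do(b)"
        assert result.ate["do(b)"] == pytest.approx(1.0)

    def test_regression_to_mean_domain_ranks_first(self, reg3):
        # all-healthy baseline; domain a tends to revert to unhealthy states
        revert = np.stack([UNIFORM, UNIFORM, np.array([0.4, 0.3, 0.3])])
        persist = np.stack([point(0), point(1), np.array([0.02, 0.03, 0.95])])
        bn = build_bn(
            reg3, [(0, 3), (1, 4), (2, 5)], [revert, persist, persist]
        )
        base = ProfileState(reg3, (2, 2, 2))
        result = rank_targets([bn, bn], base)
        assert result.ranking[0] == "do(a)"
        assert result.ate["nothing"] == 0.0

    def test_ranking_invariant_under_affine_utility(self, truth3, panel3):
        bns = [
            fit_cpts(truth3.dag, panel3),
            fit_cpts(Dag.from_edges(6, [(0, 3), (1, 4), (2, 5)]), panel3),
        ]
        base = ProfileState(panel3.registry, (0, 1, 0))
        spec = UtilitySpec()
        a_scale, b_shift = 2.5, 0.3
        transformed = UtilitySpec(
            subutility=tuple(a_scale * u + b_shift for u in spec.subutility),
            name="affine",
        )
        r1 = rank_targets(bns, base, spec)
        r2 = rank_targets(bns, base, transformed)
        assert r1.ranking == r2.ranking

    def test_eu_bounds(self, truth3, panel3):
        bns = [fit_cpts(truth3.dag, panel3)] * 2
        for codes in [(0, 0, 0), (2, 2, 2), (1, 0, 2)]:
            result = rank_targets(bns, ProfileState(panel3.registry, codes))
            for a in result.actions:
                assert -1e-12 <= result.eu[a] <= 3.0 + 1e-12


class TestPOptSummary:
    def test_indicator_when_everything_fixed(self, reg3):
        persist = np.stack([point(0), point(1), point(2)])
        bn = build_bn(reg3, [(0, 3), (1, 4), (2, 5)], [persist] * 3)
        base = ProfileState(reg3, (2, 0, 2))
        summary = p_opt_summary([bn, bn], [(base, 1.0)])
        assert summary.p_opt == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_conservation(self, truth3, panel3):
        bns = [
            fit_cpts(truth3.dag, panel3),
            fit_cpts(Dag.from_edges(6, [(0, 3), (1, 4), (2, 5)]), panel3),
        ]
        weights = baseline_weights_from_panel(panel3)
        summary = p_opt_summary(bns, weights, top_n=2)
        assert sum(summary.p_opt.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(summary.p_rec.values()) == pytest.approx(2.0, abs=1e-9)

    def test_p_rec_one_equals_p_opt(self, truth3, panel3):
        bns = [fit_cpts(truth3.dag, panel3)] * 2
        weights = baseline_weights_from_panel(panel3)
        s1 = p_opt_summary(bns, weights, top_n=1)
        assert s1.p_rec == s1.p_opt

    def test_bad_weights_rejected(self, truth3, panel3):
        bn = fit_cpts(truth3.dag, panel3)
        base = ProfileState(panel3.registry, (0, 0, 0))
        with pytest.raises(ValueError, match="sum to 1"):
            p_opt_summary([bn, bn], [(base, 0.5)])


class TestSensitivity:
    def test_identical_specs_identical_rows(self, truth3, panel3):
        bns = [fit_cpts(truth3.dag, panel3)] * 2
        weights = baseline_weights_from_panel(panel3)
        specs = [
            UtilitySpec.preset("default"),
            UtilitySpec((0.0, 0.75, 1.0), name="copy"),
        ]
        table = sensitivity_table(bns, weights, specs)
        np.testing.assert_allclose(table.loc["default"], table.loc["copy"])

    def test_risk_averse_ignores_fair_to_healthy_gain(self, reg3):
        # domain a is stuck at fair and childless: under the risk-averse
        # subutility (fair == healthy) intervening on it gains nothing
        stuck_fair = np.stack([point(1), point(1), point(1)])
        persist = np.stack([point(0), point(1), point(2)])
        bn = build_bn(reg3, [(0, 3), (1, 4), (2, 5)], [stuck_fair, persist, persist])
        base = ProfileState(reg3, (1, 0, 2))
        averse = UtilitySpec.preset("risk_averse")
        assert ate([bn, bn], base, "a", averse) == pytest.approx(0.0, abs=1e-12)
        assert ate([bn, bn], base, "a", UtilitySpec()) == pytest.approx(0.25)

    def test_weights_can_reorder_targets(self):
        # closed form: gains are 0.8*w_a (do a) vs 0.4*w_b (do b); the
        # preference flips exactly when w_b / w_a crosses 2
        reg = DomainRegistry(("a", "b"))
        t_a = np.array([0.8, 0.0, 0.2])
        t_b = np.array([0.4, 0.0, 0.6])
        bn = build_bn(reg, [], [t_a, t_b])
        base = ProfileState(reg, (0, 0))
        equal = rank_targets([bn, bn], base, UtilitySpec(name="equal"))
        assert equal.ranking[0] == "do(a)"
        tilted = rank_targets(
            [bn, bn], base,
            UtilitySpec(weights={"a": 1.0, "b": 3.0}, name="tilted"),
        )
        assert tilted.ranking[0] == "do(b)"
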