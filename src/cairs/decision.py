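"""Bayesian decision layer: utilities, expected utility, ATE and rankings.

A follow-up profile is valued by an additive utility: each domain's ordinal
level is mapped to a subutility in [0, 1] and the per-domain subutilities
are combined as a weighted sum.  With the default subutility
(poor=0, fair=0.75, healthy=1 — moderately risk averse) and unit weights
over seven domains the utility runs from 0 (all poor) to 7 (all healthy).

Actions are "nothing" (simulate follow-up with no intervention) or
``do(domain)`` (the do-operation clamping the domain's follow-up node to
healthy).  An action's expected utility (EU) under one Bayesian network is
exact — utilities are additive, so EU follows from per-domain follow-up
marginals.  Uncertainty in the causal structure is handled by averaging EU
over the posterior sample of networks; the reported SE is a Monte-Carlo
standard error using an autocorrelation-based effective sample size (the
posterior standard deviation is reported alongside).  The ATE of a target
is the paired per-sample difference EU(do(target)) - EU(nothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayesnet import CategoricalBn, followup_marginals, mutilate
from .domains import DomainRegistry, ProfileState

__all__ = [
    "UtilitySpec",
    "Action",
    "DecisionResult",
    "RecommendationSummary",
    "utility",
    "expected_utility",
    "posterior_eu",
    "ate",
    "rank_targets",
    "p_opt_summary",
    "sensitivity_table",
    "baseline_weights_from_panel",
]

#: Named subutility presets: (poor, fair, healthy).
SUBUTILITY_PRESETS: Mapping[str, tuple[float, float, float]] = {
    "default": (0.0, 0.75, 1.0),
    "risk_neutral": (0.0, 0.5, 1.0),
    "risk_averse": (0.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class UtilitySpec:
    """Subutility values per level plus nonnegative per-domain weights."""

    subutility: tuple[float, float, float] = SUBUTILITY_PRESETS["default"]
    weights: Mapping[str, float] | None = None
    name: str = "default"

    def __post_init__(self) -> None:
        u = self.subutility
        if not (u[0] <= u[1] <= u[2]):
            raise ValueError(
                f"subutility must be nondecreasing in poor<fair<healthy, got {u}"
            )
        if self.weights is not None:
            for d, w in self.weights.items():
                if not np.isfinite(w) or w < 0:
                    raise ValueError(f"weight for {d!r} must be finite nonnegative")

    @classmethod
    def preset(
        cls, name: str, weights: Mapping[str, float] | None = None
    ) -> "UtilitySpec":
        if name not in SUBUTILITY_PRESETS:
            raise KeyError(
                f"unknown preset {name!r}; choose from {sorted(SUBUTILITY_PRESETS)}"
            )
        return cls(SUBUTILITY_PRESETS[name], weights, name=name)

    def u(self) -> np.ndarray:
        return np.asarray(self.subutility, dtype=float)

    def weight_vector(self, registry: DomainRegistry) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(registry))
        missing = [d for d in registry if d not in self.weights]
        if missing:
            raise KeyError(f"weights missing for domains {missing}")
        return np.array([float(self.weights[d]) for d in registry])


@dataclass(frozen=True)
class Action:
    """Either do(target) — an idealized intervention — or nothing (None)."""

    target: str | None = None

    @property
    def is_nothing(self) -> bool:
        return self.target is None

    @property
    def name(self) -> str:
        return "nothing" if self.target is None else f"do({self.target})"


NOTHING = Action(None)


def utility(state: ProfileState, spec: UtilitySpec | None = None) -> float:
    """Weighted sum of per-domain subutilities of a profile."""
    spec = spec or UtilitySpec()
    u = spec.u()
    w = spec.weight_vector(state.registry)
    codes = np.asarray(state.levels)
    return float(np.dot(w, u[codes]))


def _action_bn(bn: CategoricalBn, action: Action) -> CategoricalBn:
    return bn if action.is_nothing else mutilate(bn, action.target)


def expected_utility(
    bn: CategoricalBn,
    baseline: ProfileState,
    action: Action = NOTHING,
    spec: UtilitySpec | None = None,
) -> float:
    """Exact EU of an action under one network given a baseline profile.

    ``nothing`` evaluates the unmutilated network; ``do(d)`` the mutilated
    one.  No sampling is involved: the additive utility reduces the sum
    over the 3^k follow-up joint to per-domain marginals.
    """
    spec = spec or UtilitySpec()
    marg = followup_marginals(_action_bn(bn, action), [baseline])[0]  # (k, 3)
    u = spec.u()
    w = spec.weight_vector(bn.registry)
    return float(np.dot(w, marg @ u))


def _eu_series(
    bns: Sequence[CategoricalBn],
    baseline: ProfileState,
    action: Action,
    spec: UtilitySpec,
) -> np.ndarray:
    return np.array([expected_utility(bn, baseline, action, spec) for bn in bns])


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size (initial positive
    sequence estimator); returns len(x) for uncorrelated or constant series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return float(n)
    var = x.var()
    if var == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (var * n)
    s = 0.0
    lag = 1
    while lag + 1 < n:
        pair = acf[lag] + acf[lag + 1]
        if pair <= 0:
            break
        s += pair
        lag += 2
    ess = n / (1.0 + 2.0 * s)
    return float(np.clip(ess, 1.0, n))


def posterior_eu(
    bns: Sequence[CategoricalBn],
    baseline: ProfileState,
    action: Action = NOTHING,
    spec: UtilitySpec | None = None,
) -> tuple[float, float]:
    """(posterior-mean EU, Monte-Carlo SE) over a sample of networks."""
    if len(bns) < 2:
        raise ValueError("posterior_eu needs at least 2 posterior samples")
    spec = spec or UtilitySpec()
    series = _eu_series(bns, baseline, action, spec)
    ess = effective_sample_size(series)
    se = float(series.std(ddof=1) / np.sqrt(ess)) if len(series) > 1 else 0.0
    return float(series.mean()), se


def ate(
    bns: Sequence[CategoricalBn],
    baseline: ProfileState,
    target: str,
    spec: UtilitySpec | None = None,
) -> float:
    """Average treatment effect: paired EU(do(target)) - EU(nothing)."""
    spec = spec or UtilitySpec()
    do_series = _eu_series(bns, baseline, Action(target), spec)
    no_series = _eu_series(bns, baseline, NOTHING, spec)
    return float((do_series - no_series).mean())


@dataclass(frozen=True)
class DecisionResult:
    """Per-action summary of the decision analysis for one baseline state."""

    baseline: ProfileState
    actions: tuple[str, ...]
    eu: Mapping[str, float]
    se: Mapping[str, float]
    sd: Mapping[str, float]
    ate: Mapping[str, float]
    eu_domains: Mapping[str, float]  # expected subutility per domain, nothing
    ranking: tuple[str, ...]
    ties: tuple[tuple[str, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "EU": [self.eu[a] for a in self.actions],
                "SE": [self.se[a] for a in self.actions],
                "SD": [self.sd[a] for a in self.actions],
                "ATE": [self.ate[a] for a in self.actions],
            },
            index=list(self.actions),
        )


def rank_targets(
    bns: Sequence[CategoricalBn],
    baseline: ProfileState,
    spec: UtilitySpec | None = None,
) -> DecisionResult:
    """Evaluate every do-action plus nothing and rank by posterior-mean EU.

    Ties are broken by registry order (with ``nothing`` last among equals);
    tied pairs are recorded on the result.
    """
    if len(bns) < 2:
        raise ValueError("rank_targets needs at least 2 posterior samples")
    spec = spec or UtilitySpec()
    registry = bns[0].registry
    actions = [NOTHING] + [Action(d) for d in registry]
    eu, se, sd, ates = {}, {}, {}, {}
    no_series = _eu_series(bns, baseline, NOTHING, spec)
    for a in actions:
        series = (
            no_series if a.is_nothing else _eu_series(bns, baseline, a, spec)
        )
        eu[a.name] = float(series.mean())
        sd[a.name] = float(series.std(ddof=1))
        se[a.name] = float(sd[a.name] / np.sqrt(effective_sample_size(series)))
        ates[a.name] = float((series - no_series).mean())

    def sort_key(a: Action):
        order = len(registry) if a.is_nothing else registry.index(a.target)
        return (-eu[a.name], order)

    ranked = sorted(actions, key=sort_key)
    ties = tuple(
        (x.name, y.name)
        for x, y in zip(ranked, ranked[1:])
        if eu[x.name] == eu[y.name]
    )

    marg = np.mean(
        [followup_marginals(bn, [baseline])[0] for bn in bns], axis=0
    )
    eu_domains = {
        d: float(marg[i] @ spec.u()) for i, d in enumerate(registry)
    }
    return DecisionResult(
        baseline=baseline,
        actions=tuple(a.name for a in actions),
        eu=eu,
        se=se,
        sd=sd,
        ate=ates,
        eu_domains=eu_domains,
        ranking=tuple(a.name for a in ranked),
        ties=ties,
    )


@dataclass(frozen=True)
class RecommendationSummary:
    """Domain-level recommendation probabilities marginalized over baselines.

    ``p_opt[d]``: probability the domain is the rank-1 intervention target;
    ``p_rec[d]``: probability it appears in the top ``top_n``.  Both are
    resolved per posterior sample and weighted by the baseline-state
    distribution; ``nothing`` is excluded from these tabulations.
    """

    registry: DomainRegistry
    p_opt: Mapping[str, float]
    p_rec: Mapping[str, float]
    top_n: int
    spec_name: str = "default"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_opt": [self.p_opt[d] for d in self.registry],
                f"p_rec({self.top_n})": [self.p_rec[d] for d in self.registry],
            },
            index=list(self.registry.names),
        )


def baseline_weights_from_panel(panel) -> list[tuple[ProfileState, float]]:
    """Empirical distribution of observed baseline profiles."""
    counts: dict[tuple[int, ...], int] = {}
    for s in panel.baseline_states():
        counts[s.levels] = counts.get(s.levels, 0) + 1
    total = sum(counts.values())
    return [
        (ProfileState(panel.registry, lv), c / total) for lv, c in counts.items()
    ]


def _eu_matrix_do_actions(
    bn: CategoricalBn,
    states: np.ndarray,
    u: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    """(n_states, k) matrix of EU under do(domain) for one network."""
    k = bn.k
    out = np.empty((states.shape[0], k))
    for i, d in enumerate(bn.registry):
        marg = followup_marginals(mutilate(bn, d), states)  # (n_states, k, 3)
        out[:, i] = (marg @ u) @ w
    return out


def p_opt_summary(
    bns: Sequence[CategoricalBn],
    baseline_weights: Iterable[tuple[ProfileState, float]],
    spec: UtilitySpec | None = None,
    top_n: int = 3,
) -> RecommendationSummary:
    """p_opt / p_rec(top_n) over posterior samples and baseline states.

    For each weighted baseline state and each posterior network, the seven
    do-actions are ranked by exact EU (ties broken by registry order);
    p_opt(d) is the baseline-weighted fraction of samples ranking d first,
    p_rec(d) the fraction placing d in the top ``top_n``.
    """
    spec = spec or UtilitySpec()
    pairs = list(baseline_weights)
    if not pairs:
        raise ValueError("baseline_weights is empty")
    weights = np.array([wt for _, wt in pairs], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("baseline weights must sum to 1")
    registry = bns[0].registry
    k = len(registry)
    if top_n < 1 or top_n > k:
        raise ValueError(f"top_n must be in 1..{k}")
    states = np.array([s.levels for s, _ in pairs], dtype=np.int64)
    u = spec.u()
    w = spec.weight_vector(registry)
    opt = np.zeros(k)
    rec = np.zeros(k)
    for bn in bns:
        eu = _eu_matrix_do_actions(bn, states, u, w)  # (n_states, k)
        # stable argsort on negated EU -> ties resolved by registry order
        order = np.argsort(-eu, axis=1, kind="stable")
        first = order[:, 0]
        np.add.at(opt, first, weights)
        for col in range(top_n):
            np.add.at(rec, order[:, col], weights)
    n = len(bns)
    p_opt = {d: float(opt[i] / n) for i, d in enumerate(registry)}
    p_rec = {d: float(rec[i] / n) for i, d in enumerate(registry)}
    return RecommendationSummary(registry, p_opt, p_rec, top_n, spec.name)


def sensitivity_table(
    bns: Sequence[CategoricalBn],
    baseline_weights: Iterable[tuple[ProfileState, float]],
    specs: Sequence[UtilitySpec] | None = None,
    top_n: int = 3,
) -> pd.DataFrame:
    """p_opt per utility specification, side by side (rows = specs)."""
    pairs = list(baseline_weights)
    if specs is None:
        specs = [UtilitySpec.preset(n) for n in SUBUTILITY_PRESETS]
    if not specs:
        raise ValueError("need at least one utility specification")
    rows = {}
    for spec in specs:
        summary = p_opt_summary(bns, pairs, spec, top_n)
        rows[spec.name] = summary.p_opt
    registry = bns[0].registry
    return pd.DataFrame(
        [[rows[s.name][d] for d in registry] for s in specs],
        index=[s.name for s in specs],
        columns=list(registry.names),
    )
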