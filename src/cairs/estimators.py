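"""End-to-end recommender: panel in, ranked intervention targets out.

:class:`InterventionRecommender` chains the three stages — posterior
structure sampling (partition MCMC + BGe), per-sample categorical network
fitting (Dirichlet-MAP CPTs), and expected-utility decision analysis — into
one scikit-learn style estimator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bayesnet import fit_cpts
from .bge import ordinal_encode
from .decision import (
    DecisionResult,
    RecommendationSummary,
    UtilitySpec,
    _eu_matrix_do_actions,
    baseline_weights_from_panel,
    p_opt_summary,
    rank_targets,
    sensitivity_table,
)
from .domains import DomainRegistry, ProfileState
from .graphs import temporal_nodes
from .mcmc import PartitionMCMC, consensus_graph
from .panel import PanelDataset

__all__ = ["InterventionRecommender"]


class InterventionRecommender(BaseEstimator):
    """Rank idealized intervention targets from a two-time-point panel.

    ``fit`` learns a posterior over temporally constrained DAGs from the
    ordinal panel, fits a categorical Bayesian network per retained draw,
    and stores the empirical baseline-state distribution.  ``predict``
    returns the EU-optimal do-target per baseline profile; ``rank`` gives
    the full per-action report for one profile, ``summarize`` the
    population-level p_opt / p_rec tables.

    Parameters mirror :class:`~cairs.mcmc.PartitionMCMC`, plus the CPT
    ``pseudocount``, the ``utility`` preset (or a :class:`UtilitySpec`),
    and ``n_networks``, the number of posterior draws converted to fitted
    networks (evenly spaced over the retained draws).
    """

    def __init__(
        self,
        n_chains: int = 8,
        n_iterations: int = 60_000,
        burn_in: int = 20_000,
        thin: int = 40,
        max_parents: int | None = 4,
        alpha_mu: float = 1.0,
        alpha_w: float | None = None,
        pseudocount: float = 1.0,
        utility: str | UtilitySpec = "default",
        top_n: int = 3,
        n_networks: int = 200,
        consensus_threshold: float = 0.10,
        random_state: int | None = None,
    ):
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.max_parents = max_parents
        self.alpha_mu = alpha_mu
        self.alpha_w = alpha_w
        self.pseudocount = pseudocount
        self.utility = utility
        self.top_n = top_n
        self.n_networks = n_networks
        self.consensus_threshold = consensus_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _spec(self) -> UtilitySpec:
        if isinstance(self.utility, UtilitySpec):
            return self.utility
        return UtilitySpec.preset(self.utility)

    @staticmethod
    def _as_panel(data) -> PanelDataset:
        if isinstance(data, PanelDataset):
            return data
        if isinstance(data, pd.DataFrame):
            domains = tuple(
                c[: -len("_t0")] for c in data.columns if c.endswith("_t0")
            )
            return PanelDataset.from_frame(data, DomainRegistry(domains))
        raise TypeError(
            "fit expects a PanelDataset or a panel DataFrame with "
            "<domain>_t0/<domain>_t1 columns"
        )

    def fit(self, X, y=None):
        panel = self._as_panel(X)
        registry = panel.registry
        names = tuple(v.name for v in temporal_nodes(registry))
        mcmc = PartitionMCMC(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            max_parents=self.max_parents,
            alpha_mu=self.alpha_mu,
            alpha_w=self.alpha_w,
            temporal=True,
            random_state=self.random_state,
        )
        mcmc.fit(ordinal_encode(panel), feature_names=names)
        self.structure_ = mcmc
        self.samples_ = mcmc.samples_
        self.edge_probabilities_ = mcmc.edge_probabilities_
        self.consensus_ = consensus_graph(
            self.samples_, self.consensus_threshold, n_baseline=len(registry)
        )
        n_draws = len(self.samples_)
        take = min(self.n_networks, n_draws)
        idx = np.unique(np.linspace(0, n_draws - 1, take).round().astype(int))
        self.networks_ = [
            fit_cpts(self.samples_.dag(i), panel, self.pseudocount) for i in idx
        ]
        self.baseline_weights_ = baseline_weights_from_panel(panel)
        self.registry_ = registry
        self.n_features_in_ = 2 * len(registry)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "networks_"):
            raise RuntimeError("this recommender has not been fitted yet")

    def _as_states(self, baselines) -> np.ndarray:
        k = len(self.registry_)
        if isinstance(baselines, ProfileState):
            return np.asarray([baselines.levels], dtype=np.int64)
        if isinstance(baselines, np.ndarray):
            return np.asarray(baselines, dtype=np.int64).reshape(-1, k)
        return np.asarray([s.levels for s in baselines], dtype=np.int64)

    def predict(self, baselines) -> np.ndarray:
        """EU-optimal do-target name per baseline profile (posterior mean EU,
        ties broken by registry order)."""
        self._check_fitted()
        states = self._as_states(baselines)
        spec = self._spec()
        u = spec.u()
        w = spec.weight_vector(self.registry_)
        eu = np.zeros((states.shape[0], len(self.registry_)))
        for bn in self.networks_:
            eu += _eu_matrix_do_actions(bn, states, u, w)
        best = eu.argmax(axis=1)  # first max -> registry-order tie-break
        names = np.array(self.registry_.names)
        return names[best]

    def rank(self, baseline: ProfileState, spec: UtilitySpec | None = None) -> DecisionResult:
        self._check_fitted()
        return rank_targets(self.networks_, baseline, spec or self._spec())

    def summarize(
        self,
        spec: UtilitySpec | None = None,
        top_n: int | None = None,
        baseline_weights=None,
    ) -> RecommendationSummary:
        self._check_fitted()
        return p_opt_summary(
            self.networks_,
            baseline_weights or self.baseline_weights_,
            spec or self._spec(),
            top_n or self.top_n,
        )

    def sensitivity(
        self, specs: Sequence[UtilitySpec] | None = None, top_n: int | None = None
    ) -> pd.DataFrame:
        self._check_fitted()
        return sensitivity_table(
            self.networks_,
            self.baseline_weights_,
            specs,
            top_n or self.top_n,
        )
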