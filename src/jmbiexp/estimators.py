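"""Estimator classes in the scikit-learn idiom.

Each estimator is configured in ``__init__`` (plain attributes, inherited
``get_params``/``set_params``), fitted with ``fit(dataset)`` where ``dataset``
is a :class:`~jmbiexp.data.BlockDataset`, and exposes fitted state through
trailing-underscore attributes. The module-level functions in
:mod:`jmbiexp.inference` are thin wrappers kept for script use.

``JointModel`` samples the full joint posterior (JE). ``TwoStageModel`` runs
the corrected two-stage fit (TS): stage-1 longitudinal plug-ins, then a
survival-plus-random-effects stage that keeps the longitudinal density — or,
with ``naive=True``, the classic biased two-stage that drops it (useful only
as a foil in bias experiments). ``BiExpMixedModel`` is the longitudinal-only
mixed model, usable on its own or as TS stage 1.

Default chain settings follow the reference analysis: three chains with 1000
warmup iterations and ~4000 pooled draws for JE/stage 1, and 500 warmup with
~1000 pooled draws for stage 2.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .biexp import biexp_mean
from .data import BlockDataset
from .inference import (PluginEstimates, convergence_report, fit_joint,
                        fit_stage1, fit_stage2)
from .prediction import (predict_cif, predict_cif_ts, predict_trajectory)
from .priors import PriorConfig

__all__ = ["BiExpMixedModel", "JointModel", "TwoStageModel"]


class BiExpMixedModel(BaseEstimator):
    """Bayesian bi-exponential nonlinear mixed model for one biomarker."""

    def __init__(self, biomarker_id=None, priors=None, chains=3,
                 n_warmup=1000, n_samples=1334, thin=1, seed=0):
        self.biomarker_id = biomarker_id
        self.priors = priors
        self.chains = chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.thin = thin
        self.seed = seed

    def fit(self, X, y=None):
        """Fit from a BlockDataset (with ``biomarker_id`` set) or a sequence of
        BiomarkerSeries of a single biomarker."""
        if isinstance(X, BlockDataset):
            if self.biomarker_id is None:
                raise ValueError("biomarker_id is required with a BlockDataset")
        self.plugins_, self.posterior_ = fit_stage1(
            X, biomarker_id=self.biomarker_id,
            priors=self.priors or PriorConfig(),
            chains=self.chains, n_warmup=self.n_warmup,
            n_samples=self.n_samples, thin=self.thin, seed=self.seed,
            return_samples=True)
        self.theta_ = self.plugins_.theta[0]
        self.omega_ = self.plugins_.omega[0]
        self.sigma_ = float(self.plugins_.sigma[0])
        self.converged_ = self.posterior_.converged
        self.diagnostics_ = self.posterior_.diagnostics
        return self

    def predict(self, T):
        """Population mean trajectory (random effects at zero) at times ``T``."""
        B, G, D = np.exp(self.theta_)
        return biexp_mean(B, G, D, np.asarray(T, dtype=float))


class _FittedPredictionMixin:
    def convergence_report(self):
        return convergence_report(self.posterior_)

    def predict_trajectory(self, history, time_grid, J=None, seed=0):
        plugins = getattr(self, "plugins_", None)
        return predict_trajectory(history, self.posterior_, time_grid, J=J,
                                  seed=seed, plugins=plugins)


class JointModel(BaseEstimator, _FittedPredictionMixin):
    """Joint estimation: one MCMC run over longitudinal and survival
    parameters of a block."""

    def __init__(self, priors=None, chains=3, n_warmup=1000, n_samples=1334,
                 thin=1, seed=0, event_columns=None, store_b=False,
                 max_doublings=0):
        self.priors = priors
        self.chains = chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.thin = thin
        self.seed = seed
        self.event_columns = event_columns
        self.store_b = store_b
        self.max_doublings = max_doublings

    def fit(self, X: BlockDataset, y=None):
        self.posterior_ = fit_joint(
            X, priors=self.priors or PriorConfig(), chains=self.chains,
            n_warmup=self.n_warmup, n_samples=self.n_samples, thin=self.thin,
            seed=self.seed, event_columns=self.event_columns,
            store_b=self.store_b, max_doublings=self.max_doublings)
        self.converged_ = self.posterior_.converged
        self.diagnostics_ = self.posterior_.diagnostics
        return self

    def predict_cif(self, history, horizons, J=None, seed=0,
                    quadrature_nodes=30):
        return predict_cif(history, self.posterior_, horizons, J=J, seed=seed,
                           quadrature_nodes=quadrature_nodes)


class TwoStageModel(BaseEstimator, _FittedPredictionMixin):
    """Corrected two-stage estimation; ``naive=True`` drops the longitudinal
    density from stage 2 (the biased classic two-stage, kept as a foil)."""

    def __init__(self, naive=False, priors=None, chains=3,
                 stage1_warmup=1000, stage1_samples=1334,
                 n_warmup=500, n_samples=334, thin=1, seed=0,
                 event_columns=None, store_b=False):
        self.naive = naive
        self.priors = priors
        self.chains = chains
        self.stage1_warmup = stage1_warmup
        self.stage1_samples = stage1_samples
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.thin = thin
        self.seed = seed
        self.event_columns = event_columns
        self.store_b = store_b

    def fit(self, X: BlockDataset, y=None):
        priors = self.priors or PriorConfig()
        parts = []
        self.stage1_posteriors_ = {}
        for j, k in enumerate(X.biomarker_ids):
            plugins, samples = fit_stage1(
                X, biomarker_id=k, priors=priors, chains=self.chains,
                n_warmup=self.stage1_warmup, n_samples=self.stage1_samples,
                thin=self.thin, seed=self.seed + 1000 * (j + 1),
                return_samples=True)
            parts.append(plugins)
            self.stage1_posteriors_[k] = samples
        self.plugins_ = PluginEstimates.concat(parts)
        self.posterior_ = fit_stage2(
            X, self.plugins_, priors=priors, chains=self.chains,
            n_warmup=self.n_warmup, n_samples=self.n_samples, thin=self.thin,
            seed=self.seed, event_columns=self.event_columns,
            include_longitudinal=not self.naive, store_b=self.store_b)
        stage1_ok = all(s.converged for s in self.stage1_posteriors_.values())
        self.converged_ = bool(self.posterior_.converged and stage1_ok)
        self.diagnostics_ = self.posterior_.diagnostics
        return self

    def predict_cif(self, history, horizons, J=None, seed=0,
                    quadrature_nodes=30):
        return predict_cif_ts(history, self.posterior_, self.plugins_,
                              horizons, J=J, seed=seed,
                              quadrature_nodes=quadrature_nodes)
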