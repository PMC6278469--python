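"""scikit-learn estimator interface to the EFO learner.

:class:`EFOClassifier` wraps the ranking-based fitting pipeline (descriptor
filtering, combination search, Hooke-Jeeves coefficient optimization,
rank-derived threshold, score-based probabilities) behind the standard
``fit`` / ``predict`` / ``predict_proba`` surface, so it composes with
sklearn pipelines, cloning and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import EFOConfig
from .engine import fit_efo
from .table import DescriptorTable

__all__ = ["EFOClassifier"]


class EFOClassifier(ClassifierMixin, BaseEstimator):
    """Sparse linear classifier trained by enrichment-factor optimization.

    The learner builds linear combinations of ``n_variables`` descriptors
    whose coefficients maximize a ranking-quality objective (cluster-profile
    skewness times first-cluster positive percentage) rather than a
    likelihood, which makes it robust on strongly unbalanced data.  Features
    are used raw — no standardization — and only descriptors whose
    single-column top-5% enrichment factor exceeds ``ef_filter_cutoff`` enter
    the combination search.

    Parameters
    ----------
    n_variables : int, default 6
        Number of descriptors per model.
    cluster_size : int or None, default None
        Cluster size of the quality function; ``None`` uses the number of
        training positives.
    ef_filter_cutoff : float, default 2.0
        Strict lower bound on a descriptor's best top-5% EF.  Use 0 to
        disable (required for balanced data, where the EF ceiling is 2).
    sampling_cycles_per_variable : int, default 12
        Random coefficient starts per included variable.
    hj_iterations, hj_rms_tol, hj_starts :
        Pattern-search budget, step-RMS stopping tolerance, and number of
        full searches launched from the best random starts.
    n_models_kept : int, default 20
        Models retained, best training quality first.
    max_combinations : int, default 20000
        Exhaustive-enumeration cap; beyond it a greedy forward search runs.
    bin_fraction : float, default 0.02
        Width of the percentile bins backing ``predict_proba``.
    random_state : int or None
        Seed for all randomness in the fit.

    Attributes
    ----------
    models_ : list of LinearModel
        Kept models, best first.
    best_model_ : LinearModel
        ``models_[0]``; used for prediction.
    filter_result_ : FilterResult
        Per-descriptor filter outcome.
    fit_result_ : FitResult
        Full fit record (models, training reports, config).
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the positive class.
    threshold_ : float
        Score cut separating the classes (>= is positive).
    """

    def __init__(
        self,
        n_variables: int = 6,
        cluster_size: int | None = None,
        ef_filter_cutoff: float = 2.0,
        sampling_cycles_per_variable: int = 12,
        hj_iterations: int = 5000,
        hj_rms_tol: float = 0.001,
        hj_starts: int = 3,
        n_models_kept: int = 20,
        max_combinations: int = 20000,
        bin_fraction: float = 0.02,
        random_state: int | None = None,
    ):
        self.n_variables = n_variables
        self.cluster_size = cluster_size
        self.ef_filter_cutoff = ef_filter_cutoff
        self.sampling_cycles_per_variable = sampling_cycles_per_variable
        self.hj_iterations = hj_iterations
        self.hj_rms_tol = hj_rms_tol
        self.hj_starts = hj_starts
        self.n_models_kept = n_models_kept
        self.max_combinations = max_combinations
        self.bin_fraction = bin_fraction
        self.random_state = random_state

    # ------------------------------------------------------------- internals
    def _to_config(self) -> EFOConfig:
        return EFOConfig(
            cluster_size=self.cluster_size,
            n_variables=self.n_variables,
            ef_filter_cutoff=self.ef_filter_cutoff,
            sampling_cycles_per_variable=self.sampling_cycles_per_variable,
            hj_iterations=self.hj_iterations,
            hj_rms_tol=self.hj_rms_tol,
            hj_starts=self.hj_starts,
            n_models_kept=self.n_models_kept,
            max_combinations=self.max_combinations,
            bin_fraction=self.bin_fraction,
            seed=self.random_state,
        )

    def _feature_names(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        return [f"x{j}" for j in range(np.asarray(X).shape[1])]

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or inf; missing values are rejected")
        return X

    def _make_table(self, X, y=None) -> DescriptorTable:
        if isinstance(X, pd.DataFrame):
            names = self._feature_names(X)
        else:
            names = getattr(self, "feature_names_in_", None)
            names = list(names) if names is not None else self._feature_names(X)
        M = self._as_matrix(X)
        labels = None
        if y is not None:
            y = np.asarray(y)
            labels = (y == self.classes_[1]).astype(np.int8)
        return DescriptorTable(
            instance_ids=[str(i) for i in range(M.shape[0])],
            descriptor_names=names,
            values=M,
            labels=labels,
        )

    # ------------------------------------------------------------------- API
    def fit(self, X, y):
        """Fit on a feature matrix (DataFrame keeps column names) and binary y."""
        y = np.asarray(y).ravel()
        M = self._as_matrix(X)
        if M.shape[0] != len(y):
            raise ValueError("X and y have inconsistent lengths")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"EFOClassifier is a binary classifier; got classes {classes}"
            )
        self.classes_ = classes
        self.n_features_in_ = M.shape[1]
        names = self._feature_names(X)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(names, dtype=object)
        table = self._make_table(X, y)
        self.fit_result_ = fit_efo(table, self._to_config())
        self.models_ = self.fit_result_.models
        self.best_model_ = self.models_[0]
        self.filter_result_ = self.fit_result_.filter_result
        self.threshold_ = self.best_model_.threshold
        self._fit_feature_names = names
        return self

    def decision_function(self, X) -> np.ndarray:
        """Best-model score minus the classification threshold (>= 0 is positive)."""
        check_is_fitted(self, "best_model_")
        table = self._make_table(X)
        return self.best_model_.score(table) - self.threshold_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d >= 0).astype(int)]

    def predict_proba(self, X) -> np.ndarray:
        """Score-based probabilities from the training-ranking percentile bins."""
        check_is_fitted(self, "best_model_")
        profile = self.best_model_.probability_profile
        if profile is None:
            raise ValueError("fitted model carries no probability profile")
        table = self._make_table(X)
        p = profile.probability(self.best_model_.score(table))
        return np.column_stack([1.0 - p, p])

    def score_samples(self, X) -> np.ndarray:
        """Raw best-model scores (higher = more likely positive)."""
        check_is_fitted(self, "best_model_")
        return self.best_model_.score(self._make_table(X))
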