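"""Scikit-learn estimator wrapping the FASSO-trained maxout network."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConfigurationError
from .fasso import FASSOConfig, optimize_network
from .maxout import Architecture, forward, unflatten_params


class MaxoutFassoClassifier(ClassifierMixin, BaseEstimator):
    """Deep maxout network classifier trained by the FASSO metaheuristic.

    The network's flat weight vector is searched directly by a
    population-based optimizer minimizing the mean-squared error of the raw
    class scores against one-hot targets — no gradients are used.  Features
    should be brought to roughly unit scale first (e.g. a
    ``StandardScaler``); on top of that the estimator divides inputs by
    ``sqrt(n_features)`` by default, which matches the optimizer's
    uniform(-1, 1) initialization to the input dimension so that
    random-init unit activations are O(1) instead of O(sqrt(n_features)).

    Because the search is stochastic, ``n_restarts`` independently seeded
    optimizations can be trained and their class scores averaged at
    prediction time; this is plain variance reduction — each committee
    member is a full maxout network trained by the same procedure.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Units of the hidden maxout layers.
    pieces : int
        Affine pieces per maxout unit.
    n_restarts : int
        Independently seeded training runs whose scores are averaged.
    input_scaling : {"sqrt_dim", "none"}
        Extra input scaling applied inside the estimator (see above).
    pop_size, max_iter, beta0, delta0, delta_max, n_communities, init_range,
    guard_eps : see :class:`~eegmotion.fasso.FASSOConfig`.
    random_state : int or None
        Base seed; member ``r`` uses ``random_state + 7919 * r``.  Fitting
        is deterministic given it.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    thetas_ : list of ndarray
        Best flat parameter vector of each restart.
    theta_ : ndarray
        The restart with the lowest training fitness.
    best_fitness_ : float
        Training MSE of ``theta_``.
    trace_ : OptimizationTrace
        Trace of the best restart; ``traces_`` holds all of them.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (32, 16),
        pieces: int = 2,
        n_restarts: int = 1,
        input_scaling: str = "sqrt_dim",
        pop_size: int = 20,
        max_iter: int = 200,
        beta0: float = 0.5,
        delta0: float = 0.5,
        delta_max: float = 1.0,
        n_communities: int = 4,
        init_range: tuple[float, float] = (-1.0, 1.0),
        guard_eps: float = 1e-8,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.pieces = pieces
        self.n_restarts = n_restarts
        self.input_scaling = input_scaling
        self.pop_size = pop_size
        self.max_iter = max_iter
        self.beta0 = beta0
        self.delta0 = delta0
        self.delta_max = delta_max
        self.n_communities = n_communities
        self.init_range = init_range
        self.guard_eps = guard_eps
        self.random_state = random_state

    def _input_scale(self, n_features: int) -> float:
        if self.input_scaling == "sqrt_dim":
            return float(np.sqrt(n_features))
        if self.input_scaling == "none":
            return 1.0
        raise ConfigurationError(
            f"input_scaling must be 'sqrt_dim' or 'none', got {self.input_scaling!r}"
        )

    def fit(self, X, y):
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        self.n_features_in_ = X.shape[1]
        self.input_scale_ = self._input_scale(X.shape[1])
        X_scaled = X / self.input_scale_
        class_index = {c: i for i, c in enumerate(self.classes_)}
        targets = np.zeros((len(y), len(self.classes_)))
        targets[np.arange(len(y)), [class_index[c] for c in y]] = 1.0
        self.architecture_ = Architecture(
            input_dim=X.shape[1],
            n_classes=len(self.classes_),
            hidden=tuple(self.hidden_layer_sizes),
            pieces=self.pieces,
        )
        self.thetas_, self.traces_ = [], []
        for r in range(self.n_restarts):
            seed = None if self.random_state is None else int(self.random_state) + 7919 * r
            config = FASSOConfig(
                pop_size=self.pop_size,
                max_iter=self.max_iter,
                beta0=self.beta0,
                delta0=self.delta0,
                delta_max=self.delta_max,
                n_communities=self.n_communities,
                init_range=tuple(self.init_range),
                guard_eps=self.guard_eps,
                seed=seed,
            )
            theta, trace = optimize_network(self.architecture_, X_scaled, targets, config)
            self.thetas_.append(theta)
            self.traces_.append(trace)
        finals = [t.best_fitness[-1] if t.best_fitness else np.inf for t in self.traces_]
        best = int(np.argmin(finals))
        self.theta_ = self.thetas_[best]
        self.trace_ = self.traces_[best]
        self.best_fitness_ = finals[best] if np.isfinite(finals[best]) else None
        self.params_ = [unflatten_params(t, self.architecture_) for t in self.thetas_]
        return self

    def decision_function(self, X):
        """Class scores averaged over the restart committee."""
        check_is_fitted(self, "thetas_")
        X = check_array(X) / self.input_scale_
        scores = np.mean([forward(p, X) for p in self.params_], axis=0)
        return scores

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
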