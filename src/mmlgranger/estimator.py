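"""Scikit-learn style estimator for MML graphical Granger inference."""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .mml import LambdaSearch
from .panel import LagConfig, TimeSeriesPanel
from .search import GAConfig, infer_graph


class MMLGraphicalGranger(BaseEstimator):
    """Infer a directed Granger-causal graph by MML87 model selection.

    For each of the p series the lagged values of every series form the
    candidate regressors of an intercept-free exponential-family GLM; the
    parent subset minimizing the MML87 message length (likelihood plus
    Fisher-information and structure code terms, ridge hyperparameter
    profiled out over [0.1, 1000]) is selected either exhaustively or by
    an elitist genetic search.  Row i of the fitted adjacency marks the
    inferred Granger-causes of series i.

    Parameters
    ----------
    lag : int, default 3
        Autoregressive order d; requires n - d > p*d.
    families : str or sequence of str, default "gaussian"
        Family label per series ("gaussian", "binomial", "poisson",
        "gamma", "inverse_gaussian"); a single string is broadcast.
    method : {"exhaustive", "genetic"}, default "exhaustive"
        Subset search strategy (all 2^p subsets vs the genetic algorithm).
    population_size : int, default 20
        Genetic-search population size m (even).
    n_generations : int, default 10
        Genetic-search generation count ng.
    lambda_box : tuple of float, default (0.1, 1000.0)
        Search interval H for the ridge hyperparameter.
    robust : bool, default False
        Use the robust (sandwich / overdispersed) weight matrices.
    count_coefficients : bool, default False
        Count d*k coefficients instead of k series in the code's prior
        and constant terms.
    random_state : int or None
        Master seed for the genetic search.

    Attributes
    ----------
    adjacency_ : ndarray of bool, shape (p, p)
        Inferred graph; ``adjacency_[i, j]`` means series j -> series i.
    scores_ : ndarray of float, shape (p,)
        Minimized per-target message lengths (nats).
    n_features_in_ : int
        Number of series p.

    Examples
    --------
    >>> est = MMLGraphicalGranger(lag=2, method="exhaustive")
    >>> est.fit(X)                      # X of shape (n_times, p) # doctest: +SKIP
    >>> est.adjacency_                  # doctest: +SKIP
    """

    def __init__(self, lag: int = 3, families="gaussian",
                 method: str = "exhaustive", population_size: int = 20,
                 n_generations: int = 10, lambda_box=(0.1, 1000.0),
                 robust: bool = False, count_coefficients: bool = False,
                 random_state=None):
        self.lag = lag
        self.families = families
        self.method = method
        self.population_size = population_size
        self.n_generations = n_generations
        self.lambda_box = lambda_box
        self.robust = robust
        self.count_coefficients = count_coefficients
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on a panel ``X`` of shape (n_times, p), one column per series."""
        X = check_array(X, ensure_min_features=2, ensure_min_samples=2)
        n, p = X.shape
        fams = self.families
        if isinstance(fams, str):
            fams = [fams] * p
        if len(fams) != p:
            raise ValueError("families must be a single label or one per series")
        seed = self.random_state if isinstance(self.random_state, numbers.Integral) \
            else None
        panel = TimeSeriesPanel(X.T, list(fams))
        graph = infer_graph(
            panel, LagConfig(self.lag), method=self.method,
            search=LambdaSearch(*self.lambda_box),
            ga=GAConfig(self.population_size, self.n_generations),
            seed=seed, robust=self.robust,
            count_coefficients=self.count_coefficients)
        self.adjacency_ = graph.adjacency
        self.scores_ = graph.scores
        self.graph_ = graph
        self.n_features_in_ = p
        return self

    def get_graph(self):
        """Return the fitted :class:`~mmlgranger.search.CausalGraph`."""
        check_is_fitted(self, "adjacency_")
        return self.graph_
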