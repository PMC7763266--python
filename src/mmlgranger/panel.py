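"""Multivariate time-series panels and lagged fixed-design matrices.

A panel holds :math:`p` time series of common length :math:`n`, each tagged
with an exponential-family label.  For a target series the lagged values of
a candidate set of source series form a fixed design matrix: response row
``t`` (for the observation at time ``t + d``, 1-based) contains, for each
selected series ``j``, the ``d`` values immediately preceding the response
time, ordered lag 1 (most recent) to lag ``d`` within the series block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FAMILY_NAMES = ("gaussian", "binomial", "poisson", "gamma", "inverse_gaussian")


@dataclass
class TimeSeriesPanel:
    """p series x n time points with per-series family labels.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        One row per series, no missing values.
    families : list of str
        Family label per series, each one of ``FAMILY_NAMES``.
    names : list of str, optional
        Series identifiers; defaults to ``x1 .. xp``.
    """

    values: np.ndarray
    families: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D (p, n) array")
        if not self.names:
            self.names = [f"x{i + 1}" for i in range(self.p)]
        self.validate()

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.p < 2:
            raise ValueError("panel needs at least 2 series")
        if self.n < 1:
            raise ValueError("panel needs at least one time point")
        if len(self.families) != self.p or len(self.names) != self.p:
            raise ValueError("families/names length must equal number of series")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains missing or non-finite values")
        for i, fam in enumerate(self.families):
            if fam not in FAMILY_NAMES:
                raise ValueError(f"series {self.names[i]!r}: unknown family {fam!r}")
            x = self.values[i]
            if fam == "binomial":
                if not np.all(np.isin(x, (0.0, 1.0))):
                    raise ValueError(f"series {self.names[i]!r}: binomial values must be 0/1")
            elif fam == "poisson":
                if np.any(x < 0) or np.any(x != np.round(x)):
                    raise ValueError(
                        f"series {self.names[i]!r}: poisson values must be nonnegative integers"
                    )
            elif fam in ("gamma", "inverse_gaussian"):
                if np.any(x <= 0):
                    raise ValueError(
                        f"series {self.names[i]!r}: {fam} values must be strictly positive"
                    )


@dataclass(frozen=True)
class LagConfig:
    """Autoregressive lag order d; requires n - d > p*d identifiability room."""

    d: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("lag d must be a positive integer")

    def check(self, panel: TimeSeriesPanel) -> None:
        if panel.n - self.d <= panel.p * self.d:
            raise ValueError(
                f"need n - d > p*d; got n={panel.n}, d={self.d}, p={panel.p}"
            )


@dataclass(frozen=True)
class CandidateSet:
    """Boolean indicator over the p possible parent series of one target.

    Self-loops are allowed: the target's own past is an admissible regressor.
    """

    Q: tuple[int, ...]
    target: int

    @property
    def k(self) -> int:
        return int(sum(self.Q))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(j for j, q in enumerate(self.Q) if q)

    @staticmethod
    def from_indices(indices, p: int, target: int) -> "CandidateSet":
        Q = [0] * p
        for j in indices:
            Q[j] = 1
        return CandidateSet(tuple(Q), target)


@dataclass
class DesignMatrix:
    """Lagged regressor matrix for one target and one candidate set.

    ``X`` has shape (n-d, d*k); ``column_map[c] = (series, lag)`` with lag in
    1..d meaning the value observed ``lag`` steps before the response time.
    """

    X: np.ndarray
    column_map: list[tuple[int, int]]
    target_vector: np.ndarray
    d: int
    p: int
    target: int

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def lagged_design(values: np.ndarray, d: int, target: int) -> DesignMatrix:
    """Lagged design from a raw (p, n) array, without panel validation.

    Row ``r`` (0-based) predicts observation ``r + d`` of the target; the
    block of series ``j`` holds lags 1..d left to right.
    """
    values = np.asarray(values, dtype=float)
    if d < 1:
        raise ValueError("lag d must be a positive integer")
    p, n = values.shape
    m = n - d
    if m < 1:
        raise ValueError("series too short for this lag")
    X = np.empty((m, d * p))
    column_map: list[tuple[int, int]] = []
    for j in range(p):
        for ell in range(1, d + 1):
            # column value at row r is x_j at index r + d - ell
            X[:, j * d + (ell - 1)] = values[j, d - ell : d - ell + m]
            column_map.append((j, ell))
    y = values[target, d:].copy()
    return DesignMatrix(X, column_map, y, d, p, target)


def build_full_design(panel: TimeSeriesPanel, lag: LagConfig, target: int) -> DesignMatrix:
    """Build the (n-d) x (d*p) design of all series' lags for one target."""
    lag.check(panel)
    return lagged_design(panel.values, lag.d, target)
def subset_design(full: DesignMatrix, cand: CandidateSet) -> DesignMatrix:
    """Keep the column blocks of the selected series, preserving order.

    An empty candidate set yields a 0-column matrix (the intercept-free
    null model).
    """
    if len(cand.Q) != full.p:
        raise ValueError("candidate indicator length must equal p")
    cols = [c for c, (j, _) in enumerate(full.column_map) if cand.Q[j]]
    X = full.X[:, cols]
    cmap = [full.column_map[c] for c in cols]
    return DesignMatrix(X, cmap, full.target_vector, full.d, full.p, full.target)
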