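"""Random causal graphs, GLM-forward panel simulation, and F-measure scoring.

The generator emulates the benchmark design of the mixed-family
experiments: draw a directed graph with a stated edge count uniformly at
random, then simulate each series forward in time under its family's GLM.
The linear predictor of series i at time t is

    eta_i(t) = sum_{j -> i} sum_{l=1..d} b * s_j(x_j^{t-l}),

where b = strength/d (the d lag coefficients of an edge are equal and sum
to ``strength``) and s_j standardizes the parent's value by its family's
baseline moments and clamps it to +-3 SD, which keeps the predictor
bounded and every family's mean inside its domain while remaining linear
over the bulk of each family's range.  Parentless series, and the first d
values of every series, are baseline draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import special

from .panel import LagConfig, TimeSeriesPanel
from .search import CausalGraph, GAConfig, infer_graph

#: Baseline (parent-free) distribution parameters per family:
#: gaussian N(0,1); Bernoulli(0.5); Poisson(1); gamma shape 2, scale 1;
#: inverse-Gaussian mean 1, shape 1.
BASELINES = {
    "gaussian": {"mean": 0.0, "sd": 1.0},
    "binomial": {"mean": 0.5, "sd": 0.5},
    "poisson": {"mean": 1.0, "sd": 1.0},
    "gamma": {"shape": 2.0, "scale": 1.0, "mean": 2.0, "sd": np.sqrt(2.0)},
    "inverse_gaussian": {"mean": 1.0, "shape": 1.0, "sd": 1.0},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """One benchmark cell: graph density, connection strength, family mix."""

    p: int
    n_edges: int
    strength: float
    families: tuple[str, ...]
    n: int
    d: int
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_edges <= self.p * (self.p - 1):
            raise ValueError("n_edges out of range for a simple digraph")
        if not 0 < self.strength <= 1:
            raise ValueError("strength must lie in (0, 1]")
        if len(self.families) != self.p:
            raise ValueError("need one family label per series")
        if self.n - self.d <= self.p * self.d:
            raise ValueError("need n - d > p*d")


def generate_graph(spec: SyntheticSpec, rng: np.random.Generator) -> CausalGraph:
    """Sample ``n_edges`` distinct directed edges (no self-loops) uniformly."""
    p = spec.p
    pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    adj = np.zeros((p, p), dtype=bool)
    for c in chosen:
        i, j = pairs[c]
        adj[i, j] = True  # j -> i
    return CausalGraph(adj)


#: Half-width (in baseline SDs) of the linear region of the squash.
_SQUASH_CLAMP = 3.0


def _squash(x: float, family: str) -> float:
    """Standardize by the family's baseline moments and clamp to +-3.

    Linear over the bulk of each family's range (so the lag-regression
    model the analysis fits is a faithful description of the dynamics) and
    bounded in the tails (so feedback cycles cannot diverge).
    """
    b = BASELINES[family]
    return float(np.clip((x - b["mean"]) / b["sd"], -_SQUASH_CLAMP, _SQUASH_CLAMP))


def _baseline_draw(family: str, rng: np.random.Generator) -> float:
    return _family_draw(family, 0.0, rng)


#: Total-predictor bound and positive-mean floor.  The clip keeps every
#: family's conditional mean within roughly one order of magnitude of its
#: baseline, so the simulated dynamics stay stationary and non-degenerate
#: (an unbounded predictor drives poisson/gamma series bimodal-extreme,
#: where no lag-regression method can track them).
_ETA_CLIP = 3.0
_ETA_FLOOR = 0.2


def _family_draw(family: str, eta: float, rng: np.random.Generator) -> float:
    """One draw with mean given by the family's own inverse link at the
    baseline-shifted predictor, so simulated panels live on the same mean
    model the analysis fits.  eta = 0 reproduces the baseline."""
    eta = float(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if family == "gaussian":
        return rng.normal(eta, 1.0)
    if family == "binomial":
        return float(rng.random() < special.expit(eta))
    if family == "poisson":
        return float(rng.poisson(np.exp(eta)))
    if family == "gamma":
        # reciprocal link: predictor shifted to the baseline 1/mean, floored
        shape = BASELINES["gamma"]["shape"]
        lin = max(1.0 / BASELINES["gamma"]["mean"] + eta, _ETA_FLOOR)
        mean = 1.0 / lin
        return rng.gamma(shape, mean / shape)
    if family == "inverse_gaussian":
        # identity mean around the baseline, floored to stay positive
        lam = BASELINES["inverse_gaussian"]["shape"]
        mean = max(BASELINES["inverse_gaussian"]["mean"] + eta, _ETA_FLOOR)
        return float(rng.wald(mean, lam))
    raise ValueError(f"unknown family {family!r}")


def simulate_panel(graph: CausalGraph, spec: SyntheticSpec,
                   rng: np.random.Generator) -> TimeSeriesPanel:
    """Simulate the panel forward in time under the GLM-forward mechanism."""
    if graph.p != spec.p:
        raise ValueError("graph size does not match spec")
    p, n, d, b = spec.p, spec.n, spec.d, spec.strength
    parents = [np.flatnonzero(graph.adjacency[i]) for i in range(p)]
    # positive per-lag coefficients of equal size summing to `strength`;
    # positive signs keep the shifted predictors of the positive-mean
    # families (gamma, inverse-Gaussian) away from their domain floor
    values = np.zeros((p, n))
    for t in range(n):
        for i in range(p):
            if t < d or len(parents[i]) == 0:
                values[i, t] = _baseline_draw(spec.families[i], rng)
            else:
                eta = 0.0
                for j in parents[i]:
                    for lag in range(1, d + 1):
                        eta += (b / d) * _squash(values[j, t - lag], spec.families[j])
                values[i, t] = _family_draw(spec.families[i], eta, rng)
    # Bernoulli draws can be constant on short panels; panel invariants only
    # require values in {0,1}, which holds by construction.
    return TimeSeriesPanel(values, list(spec.families))


def f_measure(predicted: CausalGraph, truth: CausalGraph) -> float:
    """Directed-edge F-measure 2PR/(P+R); both graphs empty scores 1."""
    if predicted.p != truth.p:
        raise ValueError("graphs must have the same number of nodes")
    pred = predicted.adjacency
    true = truth.adjacency
    tp = int(np.sum(pred & true))
    np_pred = int(np.sum(pred))
    np_true = int(np.sum(true))
    if np_pred == 0 and np_true == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / np_pred
    recall = tp / np_true
    return 2 * precision * recall / (precision + recall)


@dataclass
class BenchmarkReport:
    """Per-replicate F-measures and cell means, Table-style."""

    cells: pd.DataFrame          # one row per (method, cell, replicate)
    failures: int = 0

    def mean_table(self) -> pd.DataFrame:
        return (self.cells
                .groupby(["method", "p", "n_edges", "n", "d"], as_index=False)["f_measure"]
                .mean())


def random_graph_baseline(truth: CausalGraph, rng: np.random.Generator) -> float:
    """F-measure of an uninformed random guess: each admissible directed
    edge (off-diagonal) included independently with probability 1/2, the
    uniform distribution over parent subsets."""
    p = truth.p
    adj = rng.random((p, p)) < 0.5
    np.fill_diagonal(adj, False)
    return f_measure(CausalGraph(adj), truth)


def run_cell(spec: SyntheticSpec, method: str, *, ga: GAConfig = GAConfig(),
             rng: np.random.Generator | None = None,
             include_baselines: bool = False) -> pd.DataFrame:
    """Run one benchmark cell: n_replicates random graphs + panels, one
    inference per replicate, F-measure against the truth."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        truth = generate_graph(spec, rng)
        fams = list(spec.families)
        rng.shuffle(fams)  # family-to-node assignment randomized per replicate
        rep_spec = SyntheticSpec(spec.p, spec.n_edges, spec.strength,
                                 tuple(fams), spec.n, spec.d,
                                 spec.n_replicates, spec.seed)
        panel = simulate_panel(truth, rep_spec, rng)
        seed_i = int(rng.integers(0, 2 ** 31 - 1))
        pred = infer_graph(panel, LagConfig(spec.d), method=method,
                           ga=ga, seed=seed_i)
        rows.append({"method": method, "p": spec.p, "n_edges": spec.n_edges,
                     "n": spec.n, "d": spec.d, "replicate": rep,
                     "f_measure": f_measure(pred, truth)})
        if include_baselines:
            rows.append({"method": "random_baseline", "p": spec.p,
                         "n_edges": spec.n_edges, "n": spec.n, "d": spec.d,
                         "replicate": rep,
                         "f_measure": random_graph_baseline(truth, rng)})
            empty = CausalGraph(np.zeros((spec.p, spec.p), dtype=bool))
            rows.append({"method": "empty_baseline", "p": spec.p,
                         "n_edges": spec.n_edges, "n": spec.n, "d": spec.d,
                         "replicate": rep, "f_measure": f_measure(empty, truth)})
    return pd.DataFrame(rows)


def run_benchmark(grid: list[SyntheticSpec], methods: list[str], *,
                  ga: GAConfig = GAConfig(),
                  include_baselines: bool = False) -> BenchmarkReport:
    """Full benchmark over a grid of cells and a list of methods.

    Each (cell, method) pair reuses the cell's seed, so all methods see
    the same replicate graphs and panels.
    """
    frames = []
    failures = 0
    for spec, method in product(grid, methods):
        try:
            frames.append(run_cell(spec, method, ga=ga,
                                   include_baselines=include_baselines))
        except Exception:  # noqa: BLE001 - cell failures are reported, not fatal
            failures += 1
    cells = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return BenchmarkReport(cells, failures)
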