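"""Per-target search for the minimum-message-length parent set.

Two searches over the :math:`2^p` candidate subsets of each target's
possible Granger-parents: exhaustive enumeration (exHMML) and a small
elitist genetic algorithm (HMMLGA).  Both apply the parsimony tie-break:
among subsets whose scores tie at the minimum (within tolerance), the one
with the fewest selected series wins; remaining ties go to the last subset
in the score-sorted list (deterministic secondary key: bitstring value).

Per-target searches are independent; the causal graph stacks their
indicator vectors row-wise (row i = inferred parents of series i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import get_family
from .mml import LambdaSearch, hmml
from .panel import CandidateSet, LagConfig, TimeSeriesPanel, build_full_design

TIE_TOL = 1e-9
EXHAUSTIVE_GUARD = 20


@dataclass(frozen=True)
class GAConfig:
    """Genetic-search settings: population size m (even), generations ng."""

    m: int = 20
    ng: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2 or self.m % 2:
            raise ValueError("population size m must be even and >= 2")
        if self.ng < 1:
            raise ValueError("need at least one generation")


@dataclass
class CausalGraph:
    """p x p boolean adjacency; entry (i, j) = 1 iff series j is inferred to
    Granger-cause series i.  Diagonal (self-loop) entries are allowed."""

    adjacency: np.ndarray
    scores: np.ndarray = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if self.scores is None:
            self.scores = np.full(self.p, np.nan)
        if not self.names:
            self.names = [f"x{i + 1}" for i in range(self.p)]

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Directed (cause, effect) pairs."""
        return [(j, i) for i in range(self.p) for j in range(self.p)
                if self.adjacency[i, j]]


def _bits_to_int(Q) -> int:
    v = 0
    for b in Q:
        v = (v << 1) | int(b)
    return v


def parsimony_best(entries: list[tuple[tuple[int, ...], float]]) -> tuple[tuple[int, ...], float]:
    """Apply the minimum-score / fewest-ones / last-in-list tie-break.

    ``entries`` is a list of (Q bitstring, score).  The list is sorted
    ascending by (score, bitstring value); ties within TIE_TOL of the
    minimum are resolved to the fewest ones, then to the last such entry
    in the sorted list.
    """
    finite = [e for e in entries if np.isfinite(e[1])]
    if not finite:
        # every candidate infeasible: fall back to the empty set
        p = len(entries[0][0])
        return tuple([0] * p), np.inf
    finite.sort(key=lambda e: (e[1], _bits_to_int(e[0])))
    best_score = finite[0][1]
    tied = [e for e in finite if e[1] <= best_score + TIE_TOL]
    min_ones = min(sum(q) for q, _ in tied)
    slim = [e for e in tied if sum(e[0]) == min_ones]
    return slim[-1]


class _Scorer:
    """Memoized HMML evaluation for one target."""

    def __init__(self, panel: TimeSeriesPanel, lag: LagConfig, target: int,
                 search: LambdaSearch, robust: bool, count_coefficients: bool):
        self.full = build_full_design(panel, lag, target)
        self.family = get_family(panel.families[target])
        self.target = target
        self.search = search
        self.robust = robust
        self.count_coefficients = count_coefficients
        # gamma dispersion: one marginal ML fit per target, reused across subsets
        if self.family.name == "gamma":
            self.dispersion = self.family.dispersion(self.full.target_vector, None, 0)
        else:
            self.dispersion = None
        self.cache: dict[tuple[int, ...], float] = {}

    def __call__(self, Q: tuple[int, ...]) -> float:
        if Q not in self.cache:
            cand = CandidateSet(Q, self.target)
            self.cache[Q] = hmml(self.full, cand, self.family, self.search,
                                 dispersion=self.dispersion, robust=self.robust,
                                 count_coefficients=self.count_coefficients)
        return self.cache[Q]


def exhaustive_select(target: int, panel: TimeSeriesPanel, lag: LagConfig,
                      search: LambdaSearch = LambdaSearch(), *,
                      robust: bool = False, count_coefficients: bool = False,
                      scorer: _Scorer | None = None) -> tuple[CandidateSet, float]:
    """Enumerate all 2^p subsets of possible parents; return the minimizer
    under the parsimony tie-break, with its score."""
    p = panel.p
    if p > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"exhaustive search over 2^{p} subsets refused (p > {EXHAUSTIVE_GUARD}); "
            "use the genetic search")
    sc = scorer or _Scorer(panel, lag, target, search, robust, count_coefficients)
    entries = []
    for code in range(2 ** p):
        Q = tuple((code >> (p - 1 - b)) & 1 for b in range(p))
        entries.append((Q, sc(Q)))
    Q, score = parsimony_best(entries)
    return CandidateSet(Q, target), score


def genetic_select(target: int, panel: TimeSeriesPanel, lag: LagConfig,
                   search: LambdaSearch = LambdaSearch(),
                   ga: GAConfig = GAConfig(), *,
                   rng: np.random.Generator | None = None,
                   robust: bool = False, count_coefficients: bool = False,
                   scorer: _Scorer | None = None) -> tuple[CandidateSet, float]:
    """Elitist genetic search (HMMLGA) for the minimum-HMML parent set.

    Each generation: score the population, keep the best m/2 as the elite,
    produce children by single-point crossover of consecutive elite pairs
    at uniformly random cut positions, mutate a single random elite member
    at a single random bit, then refill to size m with the best children.
    Scores are memoized by bitstring, and the best subset ever seen is
    returned under the parsimony tie-break.
    """
    p = panel.p
    if rng is None:
        rng = np.random.default_rng(ga.seed)
    sc = scorer or _Scorer(panel, lag, target, search, robust, count_coefficients)

    pop = [tuple(rng.integers(0, 2, size=p).tolist()) for _ in range(ga.m)]
    seen: dict[tuple[int, ...], float] = {}

    def score_all(qs):
        for q in qs:
            seen[q] = sc(q)

    score_all(pop)
    for _ in range(ga.ng):
        pop.sort(key=lambda q: (seen[q], _bits_to_int(q)))
        elite = pop[: ga.m // 2]
        children: list[tuple[int, ...]] = []
        for a in range(0, len(elite) - 1, 2):
            q1, q2 = elite[a], elite[a + 1]
            cut = int(rng.integers(1, p)) if p > 1 else 0
            children.append(q1[:cut] + q2[cut:])
            children.append(q2[:cut] + q1[cut:])
        # single-bit mutation of one elite parent
        parent = elite[int(rng.integers(0, len(elite)))]
        pos = int(rng.integers(0, p))
        mut = list(parent)
        mut[pos] ^= 1
        children.append(tuple(mut))
        score_all(children)
        children.sort(key=lambda q: (seen[q], _bits_to_int(q)))
        pop = elite + children[: ga.m - len(elite)]
        while len(pop) < ga.m:  # not enough distinct children: pad with elite
            pop.append(elite[len(pop) % len(elite)])
        score_all(pop)

    Q, score = parsimony_best(list(seen.items()))
    return CandidateSet(Q, target), score


def infer_graph(panel: TimeSeriesPanel, lag: LagConfig, *,
                method: str = "exhaustive",
                search: LambdaSearch = LambdaSearch(),
                ga: GAConfig = GAConfig(), seed: int | None = None,
                robust: bool = False, count_coefficients: bool = False) -> CausalGraph:
    """Run the per-target search for every series and stack the results.

    Per-target RNG streams derive from ``seed`` and the target index, so
    rows are reproducible independently of each other.  A target whose
    search fails is recorded as an empty row with a NaN score.
    """
    if method not in ("exhaustive", "genetic"):
        raise ValueError("method must be 'exhaustive' or 'genetic'")
    p = panel.p
    if method == "exhaustive" and p > EXHAUSTIVE_GUARD:
        raise ValueError(
            f"exhaustive search over 2^{p} subsets refused; use method='genetic'")
    adj = np.zeros((p, p), dtype=bool)
    scores = np.full(p, np.nan)
    for i in range(p):
        try:
            if method == "exhaustive":
                cand, score = exhaustive_select(
                    i, panel, lag, search, robust=robust,
                    count_coefficients=count_coefficients)
            else:
                rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, i]))
                cand, score = genetic_select(
                    i, panel, lag, search, ga, rng=rng, robust=robust,
                    count_coefficients=count_coefficients)
            adj[i] = np.asarray(cand.Q, dtype=bool)
            scores[i] = score
        except (np.linalg.LinAlgError, ValueError):
            adj[i] = False  # flagged by NaN score
    return CausalGraph(adj, scores, list(panel.names))
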