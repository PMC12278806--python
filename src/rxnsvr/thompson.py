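"""Thompson-sampling comparator over the two reactant pools.

Each reactant of each component carries a Normal belief over the score of
combinations it participates in. After a warmup that scores every reactant
against a few random counterparts, each cycle samples one value from every
belief, picks the argmax reactant per component, scores that pair with the
supplied model and updates the two selected beliefs with the observation
(running mean and sample standard deviation). Sampling exploits promising
reactants early but can concentrate on few of them and miss the global
optimum — the diagnostic this module reports alongside its results.

``score_fn`` takes candidate indices ``(i, j)`` into the two pools and
returns the model score of that combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError
from .screening import ScoredCombination

SD_FLOOR = 1e-3


@dataclass
class Belief:
    """Running Normal belief over one reactant's combination scores."""

    reactant_id: str
    mean: float
    sd: float
    n_obs: int
    _sum: float = 0.0
    _sumsq: float = 0.0

    def update(self, score: float) -> None:
        self._sum += score
        self._sumsq += score * score
        self.n_obs += 1
        self.mean = self._sum / self.n_obs
        if self.n_obs > 1:
            var = max(
                (self._sumsq - self.n_obs * self.mean**2) / (self.n_obs - 1), 0.0
            )
            self.sd = max(float(np.sqrt(var)), SD_FLOOR)


def _new_belief(reactant_id: str) -> Belief:
    return Belief(reactant_id=reactant_id, mean=0.0, sd=SD_FLOOR, n_obs=0)


ScoreFn = Callable[[int, int], float]


def warmup(
    score_fn: ScoreFn,
    ids1: Sequence[str],
    ids2: Sequence[str],
    n_warm: int,
    rng: np.random.Generator,
) -> tuple[list[Belief], list[Belief], dict[tuple[int, int], float]]:
    """Initialize beliefs by scoring each reactant against random counterparts.

    Every reactant in each component is paired with ``n_warm`` random
    counterparts (with replacement when the counterpart pool is smaller);
    its belief starts from the sample mean and standard deviation of those
    scores. Returns the beliefs and all evaluated pairs with their scores.
    """
    if n_warm < 2:
        raise ContractError("n_warm must be >= 2")
    n1, n2 = len(ids1), len(ids2)
    beliefs1 = [_new_belief(s) for s in ids1]
    beliefs2 = [_new_belief(s) for s in ids2]
    evaluated: dict[tuple[int, int], float] = {}

    def sample_counterparts(n_pool: int) -> np.ndarray:
        replace = n_pool < n_warm
        return rng.choice(n_pool, size=n_warm, replace=replace)

    for i in range(n1):
        for j in sample_counterparts(n2):
            key = (i, int(j))
            if key not in evaluated:
                evaluated[key] = float(score_fn(*key))
            beliefs1[i].update(evaluated[key])
    for j in range(n2):
        for i in sample_counterparts(n1):
            key = (int(i), j)
            if key not in evaluated:
                evaluated[key] = float(score_fn(*key))
            beliefs2[j].update(evaluated[key])
    return beliefs1, beliefs2, evaluated


@dataclass
class ThompsonResult:
    """Scored pairs plus reactant-concentration diagnostics."""

    combinations: list[ScoredCombination]
    unique_reactants1: int
    unique_reactants2: int
    n_scored: int

    def best(self) -> ScoredCombination:
        return max(self.combinations, key=lambda c: (c.y_hat, -c.idx1, -c.idx2))


def run(
    score_fn: ScoreFn,
    ids1: Sequence[str],
    ids2: Sequence[str],
    n_total: int = 10_000,
    n_warm: int = 3,
    seed: int = 0,
) -> ThompsonResult:
    """Thompson sampling until ``n_total`` unique pairs have been scored.

    Warmup evaluations count toward the budget. Duplicate proposals after
    warmup are skipped without consuming budget; an attempt cap of
    ``50 * n_total`` guarantees termination on landscapes where sampling
    has collapsed onto few reactants. The number of unique scored pairs is
    ``min(n_total, n1 * n2)`` (up to the attempt cap).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = len(ids1), len(ids2)
    beliefs1, beliefs2, evaluated = warmup(score_fn, ids1, ids2, n_warm, rng)

    attempts = 0
    cap = 50 * n_total
    limit = min(n_total, n1 * n2)
    while len(evaluated) < limit and attempts < cap:
        attempts += 1
        means1 = np.array([b.mean for b in beliefs1])
        sds1 = np.array([b.sd for b in beliefs1])
        means2 = np.array([b.mean for b in beliefs2])
        sds2 = np.array([b.sd for b in beliefs2])
        i = int(np.argmax(rng.normal(means1, sds1)))
        j = int(np.argmax(rng.normal(means2, sds2)))
        if (i, j) in evaluated:
            continue
        score = float(score_fn(i, j))
        evaluated[(i, j)] = score
        beliefs1[i].update(score)
        beliefs2[j].update(score)

    combos = [
        ScoredCombination(idx1=i, idx2=j, y_hat=y)
        for (i, j), y in sorted(
            evaluated.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1])
        )
    ][: n_total]
    return ThompsonResult(
        combinations=combos,
        unique_reactants1=len({c.idx1 for c in combos}),
        unique_reactants2=len({c.idx2 for c in combos}),
        n_scored=len(evaluated),
    )
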