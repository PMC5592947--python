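"""Evolutionary scenario definition and validation.

A :class:`Scenario` bundles everything needed to run a single-locus
Wright-Fisher forward simulation under the Poisson Random Field (PRF)
model: per-generation, per-population parameter functions for mutation
rate, census size, inbreeding, dominance, selection and migration, plus
run controls (number of sites, generations, compaction interval, RNG
seed, initial state, sampling instructions) and population-founding
events for splits.

Parameter functions follow the glossary conventions of forward SFS
simulators:

* ``mutation_rate(j, t)`` -- per-site, per-chromosome rate mu >= 0
* ``census_size(j, t)`` -- individuals N >= 0; N == 0 means population
  ``j`` is not extant at generation ``t``
* ``inbreeding(j, t)`` -- Wright's F in [0, 1]; F = 0 diploid, F = 1 haploid
* ``dominance(j, t)`` -- h, unrestricted (h < 0 / h > 1 give under/over-
  dominance)
* ``selection(j, t, x)`` -- s > -1, may depend on the allele frequency
  ``x`` (scalar or ndarray; must broadcast over ``x``)
* ``migration(k, j, t)`` -- proportion of chromosomes in population ``j``
  that are immigrants from population ``k`` (k != j); the diagonal is
  implied as ``m(j,j,t) = 1 - sum_k m(k,j,t)`` (conservative migration).

Time convention: generation 0 is the initialized state, and the update
producing generation ``t`` evaluates all parameter functions at the
offspring index ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ScenarioError",
    "FoundingEvent",
    "Scenario",
    "effective_chromosomes",
    "validate_scenario",
    "migration_matrix",
    "constant",
    "epoch_function",
]


class ScenarioError(ValueError):
    """A scenario parameter or invariant is invalid."""


def effective_chromosomes(n: float, f: float) -> int:
    """Effective number of chromosomes, Ne = 2N / (1 + F).

    Interpolates between the diploid chromosome count 2N (F = 0) and the
    haploid count N (F = 1).  Ne is the binomial trial count used for
    drift and must be an integer, so the ratio is rounded to the nearest
    integer, floored at 1 for any extant population.  N = 0 (population
    not yet founded, or extinct) returns 0.

    Parameters
    ----------
    n : float
        Census size in individuals, >= 0.
    f : float
        Inbreeding coefficient in [0, 1].
    """
    if n < 0:
        raise ScenarioError(f"census size must be >= 0, got {n}")
    if not 0.0 <= f <= 1.0:
        raise ScenarioError(f"inbreeding coefficient must be in [0, 1], got {f}")
    if n == 0:
        return 0
    return max(1, int(round(2.0 * n / (1.0 + f))))


@dataclass(frozen=True)
class FoundingEvent:
    """A population split: ``target`` is founded from ``source``.

    At the update producing ``generation``, the target column of the
    mutation array is seeded with a copy of the source population's
    frequencies; the target's own (typically bottlenecked) Ne then
    governs drift in that same update.
    """

    generation: int
    source: int
    target: int


@dataclass
class Scenario:
    num_populations: int
    num_sites: float
    num_generations: int
    mutation_rate: Callable[[int, int], float]
    census_size: Callable[[int, int], float]
    inbreeding: Callable[[int, int], float] = lambda j, t: 0.0
    dominance: Callable[[int, int], float] = lambda j, t: 0.5
    selection: Callable[[int, int, np.ndarray], np.ndarray | float] = (
        lambda j, t, x: 0.0
    )
    migration: Callable[[int, int, int], float] = lambda k, j, t: 0.0
    founding_events: Sequence[FoundingEvent] = field(default_factory=tuple)
    compact_interval: int = 10
    seed: int = 0
    initial_state: object = "blank"  # "blank" | "equilibrium" | MutationArray
    sampling: Sequence[tuple[int, int]] = field(default_factory=tuple)

    def extant(self, j: int, t: int) -> bool:
        return self.census_size(j, t) > 0

    def extant_mask(self, t: int) -> np.ndarray:
        return np.array(
            [self.census_size(j, t) > 0 for j in range(self.num_populations)]
        )

    def ne(self, j: int, t: int) -> int:
        return effective_chromosomes(self.census_size(j, t), self.inbreeding(j, t))


def migration_matrix(scenario: Scenario, t: int, extant: np.ndarray) -> np.ndarray:
    """Conservative migration matrix M at generation ``t``.

    ``M[k, j]`` is the proportion of population ``j``'s chromosomes drawn
    from population ``k``, so the post-migration frequency is the
    column-weighted average ``x_mig[:, j] = sum_k M[k, j] * x[:, k]``.
    Columns of extant populations sum to 1; non-extant populations
    neither send nor receive migrants (their rows and columns are zero,
    except the diagonal of extant columns which absorbs the remainder).
    """
    p = scenario.num_populations
    m = np.zeros((p, p))
    for j in range(p):
        if not extant[j]:
            continue
        off = 0.0
        for k in range(p):
            if k == j or not extant[k]:
                continue
            rate = float(scenario.migration(k, j, t))
            if rate < 0:
                raise ScenarioError(
                    f"migration rate m({k},{j},{t}) = {rate} is negative"
                )
            m[k, j] = rate
            off += rate
        if off > 1.0 + 1e-9:
            raise ScenarioError(
                f"immigrant proportions into population {j} at generation {t} "
                f"sum to {off} > 1"
            )
        m[j, j] = 1.0 - off
    cols = m.sum(axis=0)
    if np.any(np.abs(cols[extant] - 1.0) > 1e-9):
        raise ScenarioError(f"migration columns do not sum to 1 at t={t}: {cols}")
    return m


def validate_scenario(
    scenario: Scenario,
    *,
    num_time_points: int = 101,
    num_freq_points: int = 21,
) -> Scenario:
    """Check scenario invariants on a sampled grid of (j, t, x).

    Raises :class:`ScenarioError` naming the first violated invariant;
    returns the scenario unchanged when all checks pass.  Checks are by
    necessity sampled -- arbitrary callables cannot be verified for every
    generation -- so the sampling grid includes generation 0, the final
    generation, and every founding generation (plus its neighbours).
    """
    sc = scenario
    if sc.num_populations < 1:
        raise ScenarioError("num_populations must be >= 1")
    if sc.num_sites < 1:
        raise ScenarioError("num_sites must be >= 1")
    if sc.num_generations < 0:
        raise ScenarioError("num_generations must be >= 0")
    if sc.compact_interval < 1:
        raise ScenarioError("compact_interval must be >= 1")

    tmax = sc.num_generations
    ts = set(np.linspace(0, tmax, min(tmax + 1, num_time_points), dtype=int).tolist())
    for ev in sc.founding_events:
        ts.update(g for g in (ev.generation - 1, ev.generation, ev.generation + 1)
                  if 0 <= g <= tmax)
    xs = np.linspace(0.0, 1.0, num_freq_points)

    for t in sorted(ts):
        extant = sc.extant_mask(t)
        for j in range(sc.num_populations):
            n = sc.census_size(j, t)
            if n < 0:
                raise ScenarioError(f"N({j},{t}) = {n} is negative")
            f = sc.inbreeding(j, t)
            if not 0.0 <= f <= 1.0:
                raise ScenarioError(f"F({j},{t}) = {f} outside [0, 1]")
            mu = sc.mutation_rate(j, t)
            if mu < 0:
                raise ScenarioError(f"mu({j},{t}) = {mu} is negative")
            if n > 0:
                if effective_chromosomes(n, f) < 1:
                    raise ScenarioError(f"Ne({j},{t}) < 1")
                s = np.asarray(sc.selection(j, t, xs), dtype=float)
                if np.any(s <= -1.0):
                    raise ScenarioError(
                        f"s({j},{t},x) <= -1 for some x in [0,1] "
                        "(fitness would be non-positive)"
                    )
        migration_matrix(sc, t, extant)

    for ev in sc.founding_events:
        if not (0 <= ev.source < sc.num_populations
                and 0 <= ev.target < sc.num_populations):
            raise ScenarioError(f"founding event references unknown population: {ev}")
        if ev.source == ev.target:
            raise ScenarioError(f"founding event source == target: {ev}")
        if not (1 <= ev.generation <= tmax):
            raise ScenarioError(f"founding generation outside run: {ev}")
        if not sc.extant(ev.source, ev.generation):
            raise ScenarioError(
                f"founding event at t={ev.generation}: source population "
                f"{ev.source} is not extant"
            )
        if sc.census_size(ev.target, ev.generation - 1) > 0:
            raise ScenarioError(
                f"founding event at t={ev.generation}: target population "
                f"{ev.target} already extant before the split"
            )
        if not sc.extant(ev.target, ev.generation):
            raise ScenarioError(
                f"founding event at t={ev.generation}: target population "
                f"{ev.target} has N = 0 at its founding generation"
            )
    return scenario


# ---------------------------------------------------------------------------
# Parameter-function builders


def constant(value: float) -> Callable[..., float]:
    """A parameter function returning ``value`` for every (j, t[, x])."""

    def fn(*args):
        return value

    return fn


def epoch_function(
    epochs: Sequence[dict], default: float = 0.0
) -> Callable[[int], float]:
    """Build a piecewise function of t from epoch dicts.

    Each epoch is a dict with integer ``start`` and ``end`` (inclusive)
    and either ``value`` (constant over the epoch) or ``value_from`` /
    ``value_to`` (exponential interpolation across the epoch, the usual
    parameterization of exponential growth).  Outside all epochs the
    function returns ``default``.
    """
    spans = []
    for ep in epochs:
        start, end = int(ep["start"]), int(ep["end"])
        if end < start:
            raise ScenarioError(f"epoch end {end} < start {start}")
        if "value" in ep:
            spans.append((start, end, float(ep["value"]), None))
        else:
            v0, v1 = float(ep["value_from"]), float(ep["value_to"])
            if v0 <= 0 or v1 <= 0:
                raise ScenarioError("exponential epoch endpoints must be > 0")
            spans.append((start, end, v0, v1))

    def fn(t: int) -> float:
        for start, end, v0, v1 in spans:
            if start <= t <= end:
                if v1 is None:
                    return v0
                if end == start:
                    return v1
                return v0 * (v1 / v0) ** ((t - start) / (end - start))
        return default

    return fn
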