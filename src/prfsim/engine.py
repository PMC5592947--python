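"""Forward Wright-Fisher engine under the Poisson Random Field model.

Mutations are the unit of simulation: a generation is represented by an
array of segregating mutations and their derived-allele frequencies in
each population.  Each generation the frequencies are updated by the
deterministic forces of migration and selection and the stochastic force
of binomial drift,

    x_t,j  ->  x_mig  ->  x_mig,sel  ->  x_mig,sel,drift = x_{t+1,j},

after which new mutations enter each extant population as a Poisson draw
with mean Ne * mu * L at starting frequency 1/Ne.  Frequencies 0 (lost)
and 1 (fixed) are absorbing; mutations lost or fixed across all extant
populations are filtered out ("compacted") every ``compact_interval``
generations and once more before the simulation returns, with fixations
logged as divergence.

All updates are vectorized over the mutation array.  Randomness is drawn
from substreams derived deterministically from
(seed, operation tag, generation, population), so a run is reproducible
for a given seed regardless of how the array is laid out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scenario import (
    Scenario,
    ScenarioError,
    effective_chromosomes,
    migration_matrix,
)

__all__ = [
    "MutationArray",
    "FixationLog",
    "TrajectoryRecord",
    "migrate",
    "select",
    "drift",
    "add_new_mutations",
    "compact",
    "step_generation",
    "simulate",
]

logger = logging.getLogger(__name__)

# Operation tags for RNG substream derivation.
_TAG_INIT = 1
_TAG_DRIFT = 2
_TAG_MUTATION = 3
_TAG_SAMPLE = 4


def substream(seed: int, tag: int, t: int = 0, pop: int = 0) -> np.random.Generator:
    """Deterministic RNG substream for (seed, operation, generation, population)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tag, t, pop)))


class MutationArray:
    """Per-mutation frequencies across populations, with origin IDs.

    Rows are mutations, columns are populations.  Each mutation carries
    the triple (origin_generation, origin_population, origin_index)
    which is unique within a run and allows mutation ages and individual
    frequency trajectories to be tracked.  Appending amortizes through
    capacity doubling so per-generation growth is cheap.
    """

    def __init__(self, num_populations: int):
        self.num_populations = int(num_populations)
        self._cap = 1024
        self._n = 0
        self._freq = np.zeros((self._cap, self.num_populations))
        self._gen = np.zeros(self._cap, dtype=np.int64)
        self._pop = np.zeros(self._cap, dtype=np.int64)
        self._idx = np.zeros(self._cap, dtype=np.int64)

    # -- views over the active rows -------------------------------------
    def __len__(self) -> int:
        return self._n

    @property
    def freq(self) -> np.ndarray:
        return self._freq[: self._n]

    @property
    def origin_generation(self) -> np.ndarray:
        return self._gen[: self._n]

    @property
    def origin_population(self) -> np.ndarray:
        return self._pop[: self._n]

    @property
    def origin_index(self) -> np.ndarray:
        return self._idx[: self._n]

    # -- construction ----------------------------------------------------
    @classmethod
    def from_arrays(cls, freq, origin_generation, origin_population, origin_index):
        freq = np.atleast_2d(np.asarray(freq, dtype=float))
        out = cls(freq.shape[1])
        out._reserve(freq.shape[0])
        n = freq.shape[0]
        out._freq[:n] = freq
        out._gen[:n] = origin_generation
        out._pop[:n] = origin_population
        out._idx[:n] = origin_index
        out._n = n
        return out

    def _reserve(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._cap:
            return
        cap = max(2 * self._cap, need)
        freq = np.zeros((cap, self.num_populations))
        gen = np.zeros(cap, dtype=np.int64)
        pop = np.zeros(cap, dtype=np.int64)
        idx = np.zeros(cap, dtype=np.int64)
        freq[: self._n] = self._freq[: self._n]
        gen[: self._n] = self._gen[: self._n]
        pop[: self._n] = self._pop[: self._n]
        idx[: self._n] = self._idx[: self._n]
        self._freq, self._gen, self._pop, self._idx, self._cap = freq, gen, pop, idx, cap

    def append_block(
        self, freq_block: np.ndarray, generation: int, population: int,
        start_index: int = 0,
    ) -> None:
        """Append rows sharing one origin (generation, population)."""
        k = freq_block.shape[0]
        if k == 0:
            return
        self._reserve(k)
        n = self._n
        self._freq[n : n + k] = freq_block
        self._gen[n : n + k] = generation
        self._pop[n : n + k] = population
        self._idx[n : n + k] = start_index + np.arange(k)
        self._n = n + k

    def filtered(self, keep: np.ndarray) -> "MutationArray":
        """New array with only the rows where ``keep`` is True, order preserved."""
        return MutationArray.from_arrays(
            self.freq[keep],
            self.origin_generation[keep],
            self.origin_population[keep],
            self.origin_index[keep],
        )

    def copy(self) -> "MutationArray":
        return self.filtered(np.ones(self._n, dtype=bool))


@dataclass
class FixationLog:
    """Per-population counts of mutations removed as fixed.

    A mutation is removed (and logged) only when fixed across *all*
    extant populations; removed fixations contribute to divergence even
    though they leave the active array.
    """

    num_populations: int
    events: list = field(default_factory=list)  # (generation, counts per pop)

    def record(self, generation: int, counts: np.ndarray) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if np.any(counts < 0):
            raise ValueError("fixation counts must be >= 0")
        self.events.append((generation, counts.copy()))

    def cumulative(self, pop: int) -> int:
        return int(sum(c[pop] for _, c in self.events))

    @property
    def totals(self) -> np.ndarray:
        out = np.zeros(self.num_populations, dtype=np.int64)
        for _, c in self.events:
            out += c
        return out


@dataclass
class TrajectoryRecord:
    """Frequency observations of one mutation through time.

    ``points`` holds (generation, population, frequency) triples at the
    sampling generations, strictly increasing in generation.
    """

    mutation_id: tuple[int, int, int]
    points: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Generation-cycle operations


def migrate(freq: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Conservative migration: column-weighted average of frequencies.

    ``x_mig[:, j] = sum_k m[k, j] * x[:, k]``.  ``m`` must have columns
    summing to 1 for extant populations (see
    :func:`prfsim.scenario.migration_matrix`); a convex combination of
    frequencies stays in [0, 1].
    """
    cols = m.sum(axis=0)
    active = cols > 0
    if np.any(np.abs(cols[active] - 1.0) > 1e-9):
        raise ScenarioError(f"migration columns must sum to 1, got {cols}")
    return freq @ m


def select(
    x: np.ndarray, s: np.ndarray | float, h: float, f: float
) -> np.ndarray:
    """Deterministic selection update of the expected offspring frequency.

    Implements the one-generation viability-selection recursion with
    dominance h and inbreeding F,

        x' = [x^2 s + x(1-x) s (F + h - hF) + x]
             / [x^2 s + x(1-x) s (F + 2h - 2hF) + 1],

    which at F = 0 reduces to the textbook diploid recursion
    x' = (x^2(1+s) + x(1-x)(1+hs)) / w-bar and at F = 1 to the haploid
    one.  s may be an array (frequency-dependent selection evaluated at
    the post-migration frequency).  x = 0 and x = 1 are fixed points.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s <= -1.0):
        raise ScenarioError("selection coefficient must be > -1")
    xx = x * x
    x1x = x * (1.0 - x)
    num = xx * s + x1x * s * (f + h - h * f) + x
    den = xx * s + x1x * s * (f + 2.0 * h - 2.0 * h * f) + 1.0
    if np.any(den <= 0):
        raise ScenarioError("selection denominator (mean fitness) <= 0")
    return np.clip(num / den, 0.0, 1.0)


def drift(
    x: np.ndarray, ne: int, rng: np.random.Generator
) -> np.ndarray:
    """Binomial drift: x_{t+1} = k / Ne with k ~ Binomial(Ne, x).

    The offspring generation's effective chromosome count is the trial
    number, so the result lies on the lattice {0, 1/Ne, ..., 1} and has
    mean x and variance x(1-x)/Ne.  Absorbed frequencies (exactly 0 or
    1) are passed through without consuming random draws.
    """
    if ne < 1:
        raise ScenarioError(f"drift requires Ne >= 1, got {ne}")
    x = np.asarray(x, dtype=float)
    out = x.copy()
    seg = (x > 0.0) & (x < 1.0)
    if np.any(seg):
        out[seg] = rng.binomial(ne, x[seg]) / ne
    return out


def add_new_mutations(
    scenario: Scenario,
    t: int,
    array: MutationArray,
    rng_for_pop=None,
) -> MutationArray:
    """Append the generation-``t`` mutation influx to ``array`` in place.

    For each extant population j the number of new mutations is
    Poisson(Ne(j,t) * mu(j,t) * L), per the PRF assumptions; each enters
    at frequency 1/Ne(j,t) in population j and 0 elsewhere, with origin
    ID (t, j, running index).
    """
    if t < 1:
        raise ScenarioError("new mutations enter from generation 1 onward")
    for j in range(scenario.num_populations):
        n_ind = scenario.census_size(j, t)
        if n_ind <= 0:
            continue
        ne = effective_chromosomes(n_ind, scenario.inbreeding(j, t))
        lam = ne * scenario.mutation_rate(j, t) * scenario.num_sites
        if lam == 0:
            continue
        rng = rng_for_pop(j) if rng_for_pop else substream(
            scenario.seed, _TAG_MUTATION, t, j
        )
        count = int(rng.poisson(lam))
        if count == 0:
            continue
        block = np.zeros((count, scenario.num_populations))
        block[:, j] = 1.0 / ne
        array.append_block(block, t, j, 0)
    return array


def compact(
    array: MutationArray, log: FixationLog, t: int, extant: np.ndarray
) -> tuple[MutationArray, FixationLog]:
    """Filter out mutations lost or fixed across all extant populations.

    Rows at frequency 0 in every extant population are dropped; rows at
    frequency 1 in every extant population are dropped and counted in
    the fixation log at generation ``t`` (they contribute to divergence).
    Relative order of the surviving rows is preserved.
    """
    if len(array) == 0:
        return array, log
    sub = array.freq[:, extant]
    if sub.shape[1] == 0:
        return array, log
    lost = np.all(sub == 0.0, axis=1)
    fixed = np.all(sub == 1.0, axis=1)
    n_fixed = int(fixed.sum())
    if n_fixed:
        counts = np.where(extant, n_fixed, 0)
        log.record(t, counts)
    keep = ~(lost | fixed)
    if keep.all():
        return array, log
    return array.filtered(keep), log


def step_generation(
    scenario: Scenario, t: int, array: MutationArray
) -> MutationArray:
    """Advance the array from generation ``t`` to ``t + 1``.

    Parameter functions are evaluated at the offspring index ``t + 1``.
    Founding events scheduled at ``t + 1`` are applied first (the target
    column is seeded with a copy of the source column, after which the
    target's own bottlenecked Ne governs drift in this same update).
    The update is synchronous: all post-migration frequencies are
    computed from generation-``t`` frequencies before any column is
    overwritten.  New mutations are appended after drift and first
    experience selection and drift in the following generation.
    """
    t1 = t + 1
    for ev in scenario.founding_events:
        if ev.generation == t1 and len(array):
            array.freq[:, ev.target] = array.freq[:, ev.source]

    extant = scenario.extant_mask(t1)
    if len(array):
        m = migration_matrix(scenario, t1, extant)
        identity = np.array_equal(m, np.eye(scenario.num_populations))
        x = array.freq
        x_mig = x if identity else migrate(x, m)
        for j in range(scenario.num_populations):
            if not extant[j]:
                if not identity:
                    array.freq[:, j] = 0.0
                continue
            col = x_mig[:, j]
            s = scenario.selection(j, t1, col)
            h = scenario.dominance(j, t1)
            f = scenario.inbreeding(j, t1)
            x_sel = select(col, s, h, f)
            ne = effective_chromosomes(scenario.census_size(j, t1), f)
            rng = substream(scenario.seed, _TAG_DRIFT, t1, j)
            array.freq[:, j] = drift(x_sel, ne, rng)

    add_new_mutations(scenario, t1, array)
    return array


def simulate(
    scenario: Scenario,
    *,
    seed: int | None = None,
    track_ids: list[tuple[int, int, int]] | None = None,
    track_every: int = 1,
):
    """Run the full forward simulation described by ``scenario``.

    Initializes the mutation array (blank, mutation-selection
    equilibrium, or a supplied :class:`MutationArray`), iterates the
    migration -> selection -> drift -> mutation cycle for
    ``num_generations`` generations, compacts every ``compact_interval``
    generations and one final time before returning.

    Parameters
    ----------
    seed : int, optional
        Overrides ``scenario.seed`` for this run.
    track_ids : list of (generation, population, index) triples, optional
        Mutation IDs whose frequency trajectories are recorded every
        ``track_every`` generations (and at the final generation).

    Returns
    -------
    (MutationArray, FixationLog) or (MutationArray, FixationLog, list of
    TrajectoryRecord) when ``track_ids`` is given.
    """
    from .equilibrium import initialize_equilibrium  # cycle-free at runtime

    import dataclasses

    if seed is not None:
        scenario = dataclasses.replace(scenario, seed=seed)

    init = scenario.initial_state
    if isinstance(init, MutationArray):
        array = init.copy()
    elif init == "equilibrium":
        array = initialize_equilibrium(scenario)
    elif init == "blank":
        array = MutationArray(scenario.num_populations)
    else:
        raise ScenarioError(f"unknown initial_state: {init!r}")

    log = FixationLog(scenario.num_populations)
    tracks = None
    if track_ids is not None:
        tracks = {tuple(i): TrajectoryRecord(tuple(i)) for i in track_ids}

    def record(t):
        if not tracks or not len(array):
            return
        key = {
            (g, p, i): row
            for row, (g, p, i) in enumerate(
                zip(
                    array.origin_generation.tolist(),
                    array.origin_population.tolist(),
                    array.origin_index.tolist(),
                )
            )
        }
        extant = scenario.extant_mask(t)
        for mid, rec in tracks.items():
            row = key.get(mid)
            if row is None:
                continue
            for j in range(scenario.num_populations):
                if extant[j]:
                    rec.points.append((t, j, float(array.freq[row, j])))

    record(0)
    for t in range(scenario.num_generations):
        array = step_generation(scenario, t, array)
        t1 = t + 1
        if t1 % scenario.compact_interval == 0:
            before = len(array)
            array, log = compact(array, log, t1, scenario.extant_mask(t1))
            logger.debug(
                "generation %d: compacted %d -> %d mutations", t1, before, len(array)
            )
        if tracks and (t1 % track_every == 0 or t1 == scenario.num_generations):
            record(t1)

    array, log = compact(
        array, log, scenario.num_generations,
        scenario.extant_mask(scenario.num_generations),
    )
    if tracks is not None:
        return array, log, list(tracks.values())
    return array, log
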