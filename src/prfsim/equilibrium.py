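"""Mutation-selection equilibrium initialization.

Under the Poisson Random Field model the number of segregating
mutations at population frequency x, at mutation-selection-drift
equilibrium, is Poisson with mean

    lambda_mu(x) = 2 mu L / (x (1 - x) psi(x))
                   * Int_x^1 psi(y) dy / Int_0^1 psi(y) dy,

    psi(y) = exp(-Ne s(y) y {(2h + (1 - 2h) y)(1 - F) + 2 F}),

where psi is the scale density of the Wright-Fisher diffusion with
selection s, dominance h and inbreeding F (so 1/psi(x) =
exp(+Ne s x {...}) appears in the prefactor).  In the genic case
(h = 1/2, F = 0) this is the Sawyer-Hartl density
2 mu L (1 - e^{-gamma(1-x)}) / (x (1 - x) (1 - e^{-gamma})) with
gamma = Ne s,

evaluated on the drift lattice x = i/Ne, i = 1..Ne-1, with lambda_mu
read directly as the expected count per lattice class.  In the neutral
limit this reduces to lambda(x) = 2 mu L / x, so the expected number of
segregating sites is 2 mu L Ne H_{Ne-1} -- the classic theta-scaled
harmonic sum with theta = 2 Ne mu per site.

Initialization draws the count in each frequency class from a Poisson
with mean lambda_mu(i/Ne) (inverse-CDF Poisson sampling), which starts
the simulation in equilibrium without a burn-in.  The routine covers a
single population, or several with no initial migration; equilibrium
with active migration has no product-form solution here and requires a
burn-in instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .engine import MutationArray, substream, _TAG_INIT
from .scenario import Scenario, ScenarioError, effective_chromosomes

__all__ = [
    "EquilibriumDensity",
    "equilibrium_density",
    "initialize_equilibrium",
    "write_density_tsv",
]

_MIN_GRID = 65536  # quadrature resolution floor; trapezoid error O(h^2) < 1e-7


@dataclass
class EquilibriumDensity:
    """Expected mutation counts per frequency class at equilibrium."""

    frequencies: np.ndarray  # i/Ne for i = 1..Ne-1, strictly increasing
    expected_counts: np.ndarray  # lambda_mu(i/Ne) >= 0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.expected_counts = np.asarray(self.expected_counts, dtype=float)
        if self.frequencies.shape != self.expected_counts.shape:
            raise ValueError("frequencies and expected_counts must align")

    @property
    def total(self) -> float:
        """Expected number of segregating mutations, sum of class means."""
        return float(self.expected_counts.sum())


def _exponent(ne, s, x, h, f):
    # -Ne s(x) x {(2h + (1-2h)x)(1-F) + 2F}; s already evaluated at x
    return -ne * s * x * ((2.0 * h + (1.0 - 2.0 * h) * x) * (1.0 - f) + 2.0 * f)


def equilibrium_density(
    ne: int,
    mu: float,
    num_sites: float,
    s,
    h: float = 0.5,
    f: float = 0.0,
) -> EquilibriumDensity:
    """Expected equilibrium counts lambda_mu(i/Ne) for i = 1..Ne-1.

    Parameters
    ----------
    ne : int
        Effective chromosome count (>= 2).
    mu : float
        Per-site, per-chromosome mutation rate.
    num_sites : float
        Number of simulated sites L.
    s : float or callable
        Selection coefficient, constant or a vectorized function of the
        frequency x.
    h, f : float
        Dominance and inbreeding coefficients.

    The inner integrals are evaluated once with a composite trapezoid on
    a uniform grid of max(Ne, 4096) intervals; cached cumulative sums
    give the tail integral for every x in a single pass, so the whole
    density costs O(grid).  The quadrature is deterministic.
    """
    if ne < 2:
        raise ScenarioError(f"equilibrium density requires Ne >= 2, got {ne}")
    if mu < 0:
        raise ScenarioError("mutation rate must be >= 0")
    if num_sites < 1:
        raise ScenarioError("num_sites must be >= 1")

    x = np.arange(1, ne) / ne
    if mu == 0:
        return EquilibriumDensity(x, np.zeros(ne - 1))

    s_of = s if callable(s) else (lambda xv: np.full_like(xv, float(s)))

    ngrid = max(ne, _MIN_GRID)
    y = np.linspace(0.0, 1.0, ngrid + 1)
    with np.errstate(over="raise"):
        try:
            g = np.exp(_exponent(ne, np.asarray(s_of(y), dtype=float), y, h, f))
        except FloatingPointError:
            raise ScenarioError(
                "equilibrium integrand overflows; |Ne s| too large for "
                "a finite sojourn density"
            )
    if not np.all(np.isfinite(g)):
        bad = y[~np.isfinite(g)][0]
        raise ScenarioError(f"equilibrium integrand non-finite at x = {bad}")

    cum = cumulative_trapezoid(g, y, initial=0.0)
    total = cum[-1]
    if not np.isfinite(total) or total <= 0:
        raise ScenarioError("equilibrium normalizing integral is degenerate")
    tail = np.interp(x, y, total - cum)

    sx = np.asarray(s_of(x), dtype=float)
    # prefactor is 1/psi(x): the positive of the scale-density exponent
    lam = (
        2.0 * mu * num_sites / (x * (1.0 - x))
        * np.exp(-_exponent(ne, sx, x, h, f))
        * tail / total
    )
    if not np.all(np.isfinite(lam)):
        bad = x[~np.isfinite(lam)][0]
        raise ScenarioError(f"equilibrium density non-finite at x = {bad}")
    return EquilibriumDensity(x, lam)


def initialize_equilibrium(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> MutationArray:
    """Draw a generation-0 mutation array in mutation-selection equilibrium.

    For each extant population the count in each frequency class i/Ne is
    an independent Poisson draw with mean lambda_mu(i/Ne); drawn
    mutations receive origin IDs (generation 0, population j, running
    index).  Supported for a single population or for multiple
    populations with no migration at generation 0 (each then
    equilibrates independently); initial migration has no equilibrium
    solution here and raises instead.
    """
    extant = [
        j for j in range(scenario.num_populations) if scenario.census_size(j, 0) > 0
    ]
    if len(extant) > 1:
        for j in extant:
            for k in extant:
                if k != j and scenario.migration(k, j, 0) != 0:
                    raise ScenarioError(
                        "equilibrium initialization does not support migration "
                        "between multiple populations; use a burn-in instead"
                    )

    array = MutationArray(scenario.num_populations)
    for j in extant:
        ne = effective_chromosomes(
            scenario.census_size(j, 0), scenario.inbreeding(j, 0)
        )
        if ne < 2:
            continue
        dens = equilibrium_density(
            ne,
            scenario.mutation_rate(j, 0),
            scenario.num_sites,
            lambda xv, _j=j: scenario.selection(_j, 0, xv),
            scenario.dominance(j, 0),
            scenario.inbreeding(j, 0),
        )
        gen = rng if rng is not None else substream(scenario.seed, _TAG_INIT, 0, j)
        counts = gen.poisson(dens.expected_counts)
        n = int(counts.sum())
        if n == 0:
            continue
        block = np.zeros((n, scenario.num_populations))
        block[:, j] = np.repeat(dens.frequencies, counts)
        array.append_block(block, 0, j, 0)
    return array


def write_density_tsv(density: EquilibriumDensity, path) -> None:
    """Write the density as two-column TSV (x, lambda) for inspection."""
    with open(path, "w") as fh:
        fh.write("x\tlambda\n")
        for x, lam in zip(density.frequencies, density.expected_counts):
            fh.write(f"{x:.10g}\t{lam:.10g}\n")
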