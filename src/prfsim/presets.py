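"""Ready-made scenarios used in validation and examples.

The centrepiece is the classic two-population Yoruba / Northern-European
(AF-EU) split-with-growth demography from the dadi example set, the
standard benchmark for comparing forward simulators against diffusion
solvers: an ancestral population at mutation-selection equilibrium
doubles instantaneously, evolves for T1 generations, then splits; the
derived (EU) population passes through a severe bottleneck of
0.05 N_ref and grows exponentially over T2 generations to 5 N_ref, with
weak symmetric migration and weakly deleterious codominant selection
throughout.
"""

from __future__ import annotations

import dataclasses

from .scenario import FoundingEvent, Scenario

__all__ = ["yri_ceu_split_scenario", "two_epoch_scenario", "rescaled"]


def yri_ceu_split_scenario(
    n_ref: int = 10_000,
    *,
    mu: float = 1e-9,
    num_sites: float = 2e9,
    t1: int = 100,
    t2: int = 900,
    migration_rate: float = 5e-5,
    s: float = -0.0002,
    h: float = 0.5,
    bottleneck: float = 0.05,
    growth_factor: float = 5.0,
    compact_interval: int = 10,
    seed: int = 0,
    sample_n: int = 1001,
) -> Scenario:
    """Two-population split-with-growth scenario (AF = pop 0, EU = pop 1).

    Defaults correspond to N_ref = 10,000 diploids (F = 0): the
    ancestral population at equilibrium expands to 2 N_ref, runs for
    t1 = 100 generations, then founds the EU population at 0.05 N_ref,
    which grows exponentially over t2 = 900 generations to 5 N_ref.
    Symmetric migration m = 1/(2 N_ref) = 5e-5 applies after the split;
    selection is weakly deleterious and codominant (2 N_ref s = -4,
    h = 0.5) with mu = 1e-9 over L = 2e9 sites.
    """
    split_gen = t1 + 1  # EU extant from the first post-split generation
    total = t1 + t2
    n_bottleneck = bottleneck * n_ref
    n_final = growth_factor * n_ref

    def census(j, t):
        if j == 0:
            return n_ref if t == 0 else 2.0 * n_ref
        if t < split_gen:
            return 0.0
        # exponential growth from the bottleneck to n_final over t2 gens
        frac = (t - t1) / t2
        return n_bottleneck * (n_final / n_bottleneck) ** frac

    def migration(k, j, t):
        return migration_rate if t >= split_gen else 0.0

    return Scenario(
        num_populations=2,
        num_sites=num_sites,
        num_generations=total,
        mutation_rate=lambda j, t: mu,
        census_size=census,
        inbreeding=lambda j, t: 0.0,
        dominance=lambda j, t: h,
        selection=lambda j, t, x: s,
        migration=migration,
        founding_events=(FoundingEvent(split_gen, source=0, target=1),),
        compact_interval=compact_interval,
        seed=seed,
        initial_state="equilibrium",
        sampling=((1, sample_n),),
    )


def two_epoch_scenario(
    n0: float,
    n1: float,
    change_at: int,
    num_generations: int,
    *,
    mu: float = 1e-8,
    num_sites: float = 1e7,
    s: float = 0.0,
    h: float = 0.5,
    compact_interval: int = 10,
    seed: int = 0,
) -> Scenario:
    """Single population at size n0, stepping to n1 at ``change_at``."""
    return Scenario(
        num_populations=1,
        num_sites=num_sites,
        num_generations=num_generations,
        mutation_rate=lambda j, t: mu,
        census_size=lambda j, t: n0 if t < change_at else n1,
        dominance=lambda j, t: h,
        selection=lambda j, t, x: s,
        compact_interval=compact_interval,
        seed=seed,
        initial_state="equilibrium",
    )


def rescaled(builder, scale: int, **kwargs):
    """Build a population-size/time rescaled variant of a preset.

    Dividing population sizes and times by ``scale`` while multiplying
    s, mu and m by ``scale`` leaves all products Ne s, Ne m and the
    per-generation influx Ne mu L invariant, so the simulation generates
    the same normalized spectra (and the same expected mutation counts)
    at a fraction of the cost.  Works for the presets in this module,
    whose size/time/rate arguments are keywords.
    """
    if builder is yri_ceu_split_scenario:
        base = dict(
            n_ref=10_000, mu=1e-9, t1=100, t2=900,
            migration_rate=5e-5, s=-0.0002,
        )
        base.update(kwargs)
        if base["t1"] % scale or base["t2"] % scale:
            raise ValueError("scale must divide t1 and t2")
        return yri_ceu_split_scenario(
            n_ref=base["n_ref"] // scale,
            mu=base["mu"] * scale,
            t1=base["t1"] // scale,
            t2=base["t2"] // scale,
            migration_rate=base["migration_rate"] * scale,
            s=base["s"] * scale,
            **{k: v for k, v in kwargs.items()
               if k not in ("n_ref", "mu", "t1", "t2", "migration_rate", "s")},
        )
    raise ValueError("rescaled() supports yri_ceu_split_scenario")
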