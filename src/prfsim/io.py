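"""Configuration parsing, serialization and run manifests.

Scenarios are expressible as YAML with epoch-based (piecewise constant /
step / exponential) parameter segments -- enough for every standard
demographic scenario; arbitrary time- or frequency-dependent callables
are available through the programmatic API only.

Config layout::

    run:
      num_sites: 2.0e9
      num_generations: 1000
      compact_interval: 10
      seed: 42
      initial_state: equilibrium      # blank | equilibrium | path to TSV
    populations:
      - name: AF
        inbreeding: 0.0               # scalar or epoch list
        epochs:
          - {start: 0, end: 0, size: 10000}
          - {start: 1, end: 1000, size: 20000}
      - name: EU
        founded: {generation: 101, source: 0}
        epochs:
          - {start: 101, end: 1000, size_from: 500, size_to: 50000}
    mutation: {rate: 1.0e-9}          # scalar or per-population list
    selection: {s: -0.0002, h: 0.5}   # scalars or epoch lists
    migration:
      - {source: 0, target: 1, rate: 5.0e-5, start: 101, end: 1000}
      - {source: 1, target: 0, rate: 5.0e-5, start: 101, end: 1000}
    sampling:
      - {population: 1, n: 1001}

A population with no epoch covering generation t has size 0 there (not
yet founded, or extinct).  ``size_from``/``size_to`` epochs interpolate
exponentially, the usual growth parameterization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import FixationLog, MutationArray
from .scenario import FoundingEvent, Scenario, ScenarioError, epoch_function

__all__ = [
    "scenario_from_dict",
    "load_scenario",
    "config_digest",
    "RunManifest",
    "write_mutation_array",
    "read_mutation_array",
    "write_fixation_log",
]


def _per_population(spec, num_pops, key, default):
    """Normalize a scalar / list / epoch-list parameter to fn(j, t)."""
    if spec is None:
        return lambda j, t: default
    if isinstance(spec, (int, float)):
        return lambda j, t: float(spec)
    if isinstance(spec, list) and spec and isinstance(spec[0], dict):
        fn = epoch_function([{**e, "value": e[key]} if key in e else e for e in spec])
        return lambda j, t: fn(t)
    if isinstance(spec, list):
        vals = [float(v) for v in spec]
        if len(vals) != num_pops:
            raise ScenarioError(f"expected {num_pops} per-population values")
        return lambda j, t: vals[j]
    raise ScenarioError(f"cannot interpret parameter spec: {spec!r}")


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a :class:`Scenario` from a parsed configuration mapping."""
    try:
        run = cfg["run"]
        pops = cfg["populations"]
    except KeyError as e:
        raise ScenarioError(f"config missing required section: {e}")
    num_pops = len(pops)
    if num_pops == 0:
        raise ScenarioError("config defines no populations")

    size_fns = []
    inbreeding_fns = []
    founding = []
    for j, pop in enumerate(pops):
        epochs = []
        for ep in pop.get("epochs", []):
            ep = dict(ep)
            if "size" in ep:
                ep["value"] = ep.pop("size")
            if "size_from" in ep:
                ep["value_from"] = ep.pop("size_from")
                ep["value_to"] = ep.pop("size_to")
            epochs.append(ep)
        size_fns.append(epoch_function(epochs, default=0.0))
        fspec = pop.get("inbreeding", 0.0)
        inbreeding_fns.append(
            _per_population(fspec, num_pops, "value", 0.0)
        )
        if "founded" in pop:
            founding.append(
                FoundingEvent(
                    int(pop["founded"]["generation"]),
                    int(pop["founded"]["source"]),
                    j,
                )
            )

    mut = cfg.get("mutation", {})
    mu_fn = _per_population(mut.get("rate", 0.0), num_pops, "value", 0.0)
    sel = cfg.get("selection", {})
    s_fn = _per_population(sel.get("s", 0.0), num_pops, "value", 0.0)
    h_fn = _per_population(sel.get("h", 0.5), num_pops, "value", 0.5)

    mig_entries = []
    for entry in cfg.get("migration", []) or []:
        mig_entries.append(
            (
                int(entry["source"]),
                int(entry["target"]),
                float(entry["rate"]),
                int(entry.get("start", 0)),
                int(entry.get("end", run["num_generations"])),
            )
        )

    def migration(k, j, t):
        rate = 0.0
        for src, tgt, r, start, end in mig_entries:
            if src == k and tgt == j and start <= t <= end:
                rate += r
        return rate

    init = run.get("initial_state", "blank")
    sampling = tuple(
        (int(s["population"]), int(s["n"])) for s in cfg.get("sampling", []) or []
    )

    return Scenario(
        num_populations=num_pops,
        num_sites=float(run["num_sites"]),
        num_generations=int(run["num_generations"]),
        mutation_rate=mu_fn,
        census_size=lambda j, t: size_fns[j](t),
        inbreeding=lambda j, t: inbreeding_fns[j](j, t),
        dominance=h_fn,
        selection=lambda j, t, x: s_fn(j, t),
        migration=migration,
        founding_events=tuple(founding),
        compact_interval=int(run.get("compact_interval", 10)),
        seed=int(run.get("seed", 0)),
        initial_state=init,
        sampling=sampling,
    )


def load_scenario(path) -> Scenario:
    """Parse a YAML scenario configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ScenarioError(f"{path}: not a mapping")
    return scenario_from_dict(cfg)


def config_digest(path) -> str:
    """SHA-256 digest of the configuration file bytes (provenance)."""
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    scenario_digest: str
    seed: int
    version: str
    start_generation: int
    end_generation: int
    compact_interval: int
    outputs: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Mutation array / fixation log TSV


def write_mutation_array(
    array: MutationArray, path, header_comment: str | None = None
) -> None:
    """TSV columns: origin_generation, origin_population, origin_index,
    freq_pop0, freq_pop1, ...  Frequencies are written in full precision
    so a round trip is exact."""
    cols = {
        "origin_generation": array.origin_generation,
        "origin_population": array.origin_population,
        "origin_index": array.origin_index,
    }
    for j in range(array.num_populations):
        cols[f"freq_pop{j}"] = array.freq[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_mutation_array(path) -> MutationArray:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    freq_cols = [c for c in df.columns if c.startswith("freq_pop")]
    if not freq_cols:
        raise ScenarioError(f"{path}: no freq_pop columns found")
    freq_cols.sort(key=lambda c: int(c.removeprefix("freq_pop")))
    return MutationArray.from_arrays(
        df[freq_cols].to_numpy(dtype=float).reshape(len(df), len(freq_cols)),
        df["origin_generation"].to_numpy(dtype=np.int64),
        df["origin_population"].to_numpy(dtype=np.int64),
        df["origin_index"].to_numpy(dtype=np.int64),
    )


def write_fixation_log(
    log: FixationLog, path, header_comment: str | None = None
) -> None:
    """TSV columns: generation, fixed_pop0, fixed_pop1, ..."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        heads = "\t".join(f"fixed_pop{j}" for j in range(log.num_populations))
        fh.write(f"generation\t{heads}\n")
        for gen, counts in log.events:
            fh.write(f"{gen}\t" + "\t".join(str(int(c)) for c in counts) + "\n")
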