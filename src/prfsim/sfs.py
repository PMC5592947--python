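"""Site frequency spectra from a mutation array.

The SFS is a histogram in which bin k counts the mutations whose
derived allele is carried by exactly k chromosomes -- either in the
whole population (k = i on the drift lattice i/Ne) or in a sample of n
chromosomes drawn from the population frequencies.  Classes 0 and n are
non-segregating and are excluded both from the spectrum and from the
segregating-site count, so normalization is by the number of
segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import MutationArray
from .scenario import ScenarioError

__all__ = [
    "SFS",
    "population_sfs",
    "sample_sfs",
    "normalize_sfs",
    "expected_sample_sfs",
    "write_sfs_tsv",
    "write_dadi",
]


@dataclass
class SFS:
    """Mutation counts by derived-allele count class 1..n-1.

    ``counts[k - 1]`` is the number of mutations in class k; fixed and
    absent classes (0 and n) are excluded.  ``sample_size`` is n
    chromosomes (the population's Ne for a population spectrum).
    """

    counts: np.ndarray
    sample_size: int
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.sample_size - 1,):
            raise ValueError(
                f"expected {self.sample_size - 1} classes, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be >= 0")

    @property
    def num_segregating(self) -> float:
        return float(self.counts.sum())


def population_sfs(array: MutationArray, pop: int, ne: int) -> SFS:
    """Bin mutations by their lattice frequency class i/Ne in ``pop``.

    Frequencies are rounded to the nearest lattice class; classes 0 and
    Ne (lost / fixed in this population) are excluded.
    """
    if not 0 <= pop < array.num_populations:
        raise ScenarioError(f"population {pop} out of range")
    if ne < 2:
        raise ScenarioError("population SFS requires Ne >= 2")
    i = np.rint(array.freq[:, pop] * ne).astype(np.int64)
    seg = (i >= 1) & (i <= ne - 1)
    counts = np.bincount(i[seg], minlength=ne)[1:ne]
    return SFS(counts.astype(float), ne)


def sample_sfs(
    array: MutationArray,
    pop: int,
    n: int,
    rng: np.random.Generator,
    *,
    method: str = "binomial",
    ne: int | None = None,
) -> SFS:
    """Spectrum of a sample of ``n`` chromosomes drawn from ``pop``.

    For each mutation at population frequency x the sampled derived
    count is k ~ Binomial(n, x); outcomes with 0 < k < n increment class
    k.  Binomial sampling (with replacement) is the PRF convention and
    is accurate for n << Ne; ``method="hypergeometric"`` switches to
    sampling without replacement from the Ne population chromosomes
    (requires ``ne``).
    """
    if n < 2:
        raise ScenarioError("sample size must be >= 2")
    x = array.freq[:, pop]
    x = x[x > 0.0]
    if method == "binomial":
        k = rng.binomial(n, x)
    elif method == "hypergeometric":
        if ne is None:
            raise ScenarioError("hypergeometric sampling requires ne")
        good = np.rint(x * ne).astype(np.int64)
        k = rng.hypergeometric(good, ne - good, n)
    else:
        raise ScenarioError(f"unknown sampling method: {method}")
    seg = (k >= 1) & (k <= n - 1)
    counts = np.bincount(k[seg], minlength=n)[1:n]
    return SFS(counts.astype(float), n)


def expected_sample_sfs(pop_sfs: SFS, n: int) -> np.ndarray:
    """Binomial projection of a population SFS to sample size ``n``.

    E[counts_n[k]] = sum_i pop_counts[i] C(n,k) (i/Ne)^k (1 - i/Ne)^(n-k)
    for k = 1..n-1.  Used as the analytic cross-check for
    :func:`sample_sfs`.
    """
    from scipy.stats import binom

    ne = pop_sfs.sample_size
    x = np.arange(1, ne) / ne
    k = np.arange(1, n)
    # classes x (sample classes) pmf matrix
    pmf = binom.pmf(k[None, :], n, x[:, None])
    return pop_sfs.counts @ pmf


def normalize_sfs(sfs: SFS) -> SFS:
    """Return a copy with ``normalized = counts / num_segregating``."""
    total = sfs.num_segregating
    if total <= 0:
        raise ScenarioError("cannot normalize an SFS with zero segregating sites")
    return SFS(sfs.counts.copy(), sfs.sample_size, sfs.counts / total)


def write_sfs_tsv(sfs: SFS, path, header_comment: str | None = None) -> None:
    """Two-column TSV (class, count), plus a normalized column if set."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cols = "class\tcount" + ("\tnormalized" if sfs.normalized is not None else "")
        fh.write(cols + "\n")
        for k in range(1, sfs.sample_size):
            line = f"{k}\t{sfs.counts[k - 1]:.10g}"
            if sfs.normalized is not None:
                line += f"\t{sfs.normalized[k - 1]:.10g}"
            fh.write(line + "\n")


def write_dadi(sfs: SFS, path, header_comment: str | None = None) -> None:
    """Write a dadi-style single-population frequency spectrum file.

    Format: a header line ``{n+1} unfolded``, then n+1 space-separated
    entries for classes 0..n (the excluded corner classes are written as
    0), then a mask line with 1 marking the masked corners.
    """
    n = sfs.sample_size
    full = np.zeros(n + 1)
    full[1:n] = sfs.counts
    mask = np.zeros(n + 1, dtype=int)
    mask[0] = mask[n] = 1
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"{n + 1} unfolded\n")
        fh.write(" ".join(f"{v:.10g}" for v in full) + "\n")
        fh.write(" ".join(str(v) for v in mask) + "\n")
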