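"""Exact finite-N Wright-Fisher references for testing.

A single-population Wright-Fisher process with selection is a Markov
chain on derived-allele counts 0..Ne whose one-step transition row from
count i is the Binomial(Ne, x'_i) pmf, where x'_i is the deterministic
post-selection expected frequency of i/Ne.  At test scale (Ne <= 500)
the full transition matrix is cheap to build, and matrix powers /
linear solves give exact finite-population distributions and fixation
probabilities to compare the stochastic engine against.

The matrix deliberately reuses :func:`prfsim.engine.select` for x'_i so
the comparison isolates the drift and absorption machinery; the
selection recursion itself is guarded separately in the test suite by
an independently coded viability recursion.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .engine import select
from .scenario import ScenarioError

__all__ = [
    "build_transition_matrix",
    "absorption_probability",
    "kimura_fixation_probability",
]

_MAX_NE = 500  # quadratic memory; oracle is test-scale only


def build_transition_matrix(
    ne: int, s: float = 0.0, h: float = 0.5, f: float = 0.0
) -> np.ndarray:
    """(Ne+1) x (Ne+1) transition matrix of the WF chain with selection.

    Entry (i, k) is P(count k at t+1 | count i at t).  Rows 0 and Ne are
    absorbing unit vectors; every row sums to 1 (binomial pmf).
    """
    if not 2 <= ne <= _MAX_NE:
        raise ScenarioError(f"oracle transition matrix limited to 2 <= Ne <= {_MAX_NE}")
    x = np.arange(ne + 1) / ne
    x_sel = select(x, s, h, f)
    k = np.arange(ne + 1)
    mat = binom.pmf(k[None, :], ne, x_sel[:, None])
    # guard against pmf roundoff at the absorbing rows
    mat[0] = 0.0
    mat[0, 0] = 1.0
    mat[ne] = 0.0
    mat[ne, ne] = 1.0
    return mat


def absorption_probability(matrix: np.ndarray, start: int) -> float:
    """Probability of absorption at count Ne starting from ``start``.

    Solves the standard first-step system (I - Q) u = b over the
    transient states, where Q is the transient block and b the one-step
    probabilities of hitting the fixed state.
    """
    ne = matrix.shape[0] - 1
    if not 0 <= start <= ne:
        raise ScenarioError("start count out of range")
    if start == 0:
        return 0.0
    if start == ne:
        return 1.0
    q = matrix[1:ne, 1:ne]
    b = matrix[1:ne, ne]
    u = np.linalg.solve(np.eye(ne - 1) - q, b)
    if not np.all(np.isfinite(u)):
        raise ScenarioError("absorption solve did not converge")
    return float(u[start - 1])


def kimura_fixation_probability(ne: int, s: float, p: float) -> float:
    """Diffusion approximation to the fixation probability, genic case.

    For codominant selection (h = 1/2, F = 0) the chain's per-allele
    effect is s/2, giving u(p) = (1 - exp(-Ne s p)) / (1 - exp(-Ne s))
    in the diffusion limit with Ne chromosomes.  Neutral limit: u = p.
    """
    if s == 0:
        return p
    a = ne * s
    return float(np.expm1(-a * p) / np.expm1(-a))
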