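"""Probability that an MPA fully covers individual home ranges.

Consider a marine protected area protecting ``S`` km² of reef-slope
habitat, laid out along the (linear) reef axis, and a population of sharks
whose home-range sizes ``UD_j`` are known.  Place a shark's range centred
anywhere in the protected habitat, each location equally likely and each
shark drawn from the observed UD sample.  The model discretises the
protected habitat into ``n = ceil(S/dS)`` intervals of width ``dS``
(1 km² by default).  For interval ``i`` with centre ``c_i``, the indicator

    P_ij = 1  iff  [c_i - UD_j/2, c_i + UD_j/2] ⊆ [0, S]

states whether shark ``j`` centred there keeps its whole range inside the
MPA.  Averaging over sharks gives ``P_i``, and averaging the ``P_i`` over
intervals gives the overall probability Π that a randomly placed shark's
home range is fully covered.  Intervals are treated independently
(homogeneous use of the MPA, no habitat limits at its edges), so Π is
conservative for isolated reefs.

In the continuum limit ``dS → 0`` the model has the closed form
``Π = mean_j max(0, S - UD_j) / S``, used as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CoverageResult:
    """Coverage model output for one MPA size ``S``."""

    S: float
    dS: float
    n: int
    P_i: np.ndarray                 # per-interval coverage probability
    Pi_overall: float
    ud_sample: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class CoverageCurve:
    """Π evaluated on a grid of MPA sizes for one subgroup and UD metric."""

    S_grid: np.ndarray
    Pi: np.ndarray
    subgroup: str = "all"
    metric: str = "ud100"


def _check_inputs(ud_values, S, dS):
    ud = np.asarray(ud_values, dtype=float)
    if ud.size == 0:
        raise ValueError("UD sample must be non-empty")
    if np.any(ud < 0):
        raise ValueError("UD values must be non-negative")
    if S <= 0 or dS <= 0:
        raise ValueError("S and dS must be positive")
    return ud


def interval_centres(S: float, dS: float = 1.0) -> np.ndarray:
    """Centres of the ``ceil(S/dS)`` discretisation intervals of ``[0, S]``.

    Interval ``i`` spans ``[(i-1)·dS, i·dS]`` with its centre at the
    midpoint; when ``dS`` does not divide ``S`` the last interval is
    truncated at ``S`` and its centre is the midpoint of the truncated
    piece.
    """
    n = int(np.ceil(S / dS - 1e-12))
    edges = np.minimum(np.arange(n + 1, dtype=float) * dS, S)
    return 0.5 * (edges[:-1] + edges[1:])


def coverage_probability(ud_values, S: float, dS: float = 1.0) -> CoverageResult:
    """Discretised coverage probability Π for an MPA of reef-slope area S."""
    ud = _check_inputs(ud_values, S, dS)
    c = interval_centres(S, dS)
    half = ud[None, :] / 2.0                       # n_intervals x n_sharks
    covered = (c[:, None] - half >= -1e-12) & (c[:, None] + half <= S + 1e-12)
    p_i = covered.mean(axis=1)
    return CoverageResult(S=float(S), dS=float(dS), n=len(c), P_i=p_i,
                          Pi_overall=float(p_i.mean()), ud_sample=ud)


def coverage_curve(ud_values, S_grid, dS: float = 1.0, subgroup: str = "all",
                   metric: str = "ud100") -> CoverageCurve:
    """Evaluate Π over a sorted grid of MPA sizes."""
    grid = np.asarray(S_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
        raise ValueError("S grid must be positive and sorted ascending")
    pi = np.array([coverage_probability(ud_values, s, dS).Pi_overall for s in grid])
    return CoverageCurve(S_grid=grid, Pi=pi, subgroup=subgroup, metric=metric)


def analytic_coverage(ud_values, S: float) -> float:
    """Continuum-limit closed form ``mean_j max(0, S - UD_j) / S``."""
    ud = _check_inputs(ud_values, S, 1.0)
    return float(np.mean(np.maximum(0.0, S - ud)) / S)


def min_size_for_target(ud_values, target_fraction: float, dS: float = 1.0,
                        max_S: float | None = None) -> float:
    """Smallest MPA size S (on the dS grid) with Π(S) ≥ target.

    Π is non-decreasing in S, so the answer is found by doubling to bracket
    the target and bisecting on multiples of ``dS``.  Raises if the target
    is not reached by ``max_S`` (default ``1e6 * dS``).
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    ud = _check_inputs(ud_values, dS, dS)
    bound = max_S if max_S is not None else 1e6 * dS
    hi = dS
    while coverage_probability(ud, hi, dS).Pi_overall < target_fraction:
        hi *= 2
        if hi > bound:
            raise ValueError(f"target {target_fraction} not reachable below S = {bound}")
    hi_k = int(np.ceil(hi / dS))
    lo_k = 1
    while lo_k < hi_k:
        mid_k = (lo_k + hi_k) // 2
        if coverage_probability(ud, mid_k * dS, dS).Pi_overall >= target_fraction:
            hi_k = mid_k
        else:
            lo_k = mid_k + 1
    return float(hi_k * dS)
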