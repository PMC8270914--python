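"""Permutation and bootstrap statistics for home-range values.

Home-range areas are strongly right-skewed with a point mass at zero
(animals seen on a single receiver), so classical ANOVA theory is
avoided: values are transformed as ``y = log10(1 + x)`` and all p-values
come from permutation null distributions.

* :func:`permanova_two_way` — two-way permutation ANOVA with sequential
  (type-I) sums of squares for factor A, factor B and their interaction;
  the null distribution of each term's SS is obtained by unrestricted
  permutation of the responses, with block-sequential early stopping of
  the permutation stream once the p-value estimate is stable (stop when
  its standard error falls below one tenth of the estimate).
* :func:`pairwise_permutation_t` — two-sample Student t statistics with
  permutation p-values per group pair, switching to exhaustive split
  enumeration whenever the pair is small enough.
* bootstrap helpers for group-mean confidence intervals, empirical
  cumulative curves with confidence bands and threshold proportions.

All p-values use the add-one correction ``(1 + #extreme) / (1 + n_perm)``
so they can never be exactly zero under finitely many permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

PERMANOVA_MAX_ITER = 5000
PAIRWISE_N_PERM = 999
BOOTSTRAP_RUNS = 200

_SS_TIE_EPS = 1e-12


def transform_ud(values) -> np.ndarray:
    """Variance-stabilising transform ``y = log10(1 + x)`` for UD areas."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("UD values must be non-negative")
    return np.log10(1.0 + x)


# ---------------------------------------------------------------------------
# Two-way permutation ANOVA
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    term: str                 # "sex" | "maturity" | "interaction" | "residuals"
    df: int
    sum_of_squares: float
    mean_square: float
    iterations_used: int | None = None
    p_perm: float | None = None


def _dummy(labels: np.ndarray) -> np.ndarray:
    """Drop-first dummy coding, columns for levels 2..k."""
    levels = sorted(set(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))


def _sequential_projectors(factor_a: np.ndarray, factor_b: np.ndarray):
    """Orthonormal bases for the sequential model terms A, B, A:B.

    Columns are orthogonalised in model order (intercept, A, B, A:B), so
    ``||Q_termᵀ y||²`` is the sequential (type-I) sum of squares of the
    term and the decomposition adds up exactly.
    """
    n = len(factor_a)
    xa, xb = _dummy(factor_a), _dummy(factor_b)
    xab = np.einsum("ij,ik->ijk", xa, xb).reshape(n, -1)
    blocks = [np.ones((n, 1)), xa, xb, xab]
    qs, basis = [], np.zeros((n, 0))
    for blk in blocks:
        resid = blk - basis @ (basis.T @ blk) if basis.shape[1] else blk.copy()
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max(initial=0.0))
        q = q[:, keep]
        qs.append(q)
        basis = np.hstack([basis, q])
    return qs  # [intercept, A, B, AB]


def permanova_two_way(values, factor_a, factor_b, max_iter: int = PERMANOVA_MAX_ITER,
                      seed: int | None = None, factor_names=("sex", "maturity"),
                      block: int = 100, min_iter: int = 50) -> list[GroupTestResult]:
    """Two-way permutation ANOVA on (already transformed) response values.

    Sequential sums of squares are computed for ``factor_a``, ``factor_b``
    and their interaction; each term's p-value is the add-one-corrected
    share of response permutations whose term SS reaches the observed one.
    Permutations are generated in blocks and a term stops early once the
    standard error of its p-value estimate drops below ``0.1 * p``; the
    number of permutations actually used is reported per term.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    n = len(y)
    if len(a) != n or len(b) != n or n < 4:
        raise ValueError("need n >= 4 with matching factor lengths")
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise ValueError("each factor needs at least two levels")

    q_int, q_a, q_b, q_ab = _sequential_projectors(a, b)
    terms = [(factor_names[0], q_a), (factor_names[1], q_b), ("interaction", q_ab)]
    yc = y - y.mean()
    total_ss = float(yc @ yc)
    obs_ss = [float(np.sum((q.T @ y) ** 2)) for _, q in terms]
    resid_ss = total_ss - sum(obs_ss)
    df_terms = [q.shape[1] for _, q in terms]
    df_resid = n - 1 - sum(df_terms)

    rng = np.random.default_rng(seed)
    counts = np.zeros(3, dtype=int)
    done = [False] * 3
    iters = np.zeros(3, dtype=int)
    total_done = 0
    while total_done < max_iter and not all(done):
        m = min(block, max_iter - total_done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        yp = y[perms]                                  # m x n
        for k, (_, q) in enumerate(terms):
            if done[k]:
                continue
            ss = np.sum((yp @ q) ** 2, axis=1)
            counts[k] += int(np.sum(ss >= obs_ss[k] - _SS_TIE_EPS))
            iters[k] += m
            p_hat = (1 + counts[k]) / (1 + iters[k])
            se = np.sqrt(p_hat * (1 - p_hat) / iters[k])
            if iters[k] >= min_iter and se <= 0.1 * p_hat:
                done[k] = True
        total_done += m

    results = []
    for k, (name, _) in enumerate(terms):
        ss = obs_ss[k]
        df = max(df_terms[k], 1)
        results.append(GroupTestResult(
            term=name, df=df, sum_of_squares=ss, mean_square=ss / df,
            iterations_used=int(iters[k]),
            p_perm=float((1 + counts[k]) / (1 + iters[k]))))
    results.append(GroupTestResult(
        term="residuals", df=max(df_resid, 1), sum_of_squares=resid_ss,
        mean_square=resid_ss / max(df_resid, 1)))
    return results


# ---------------------------------------------------------------------------
# Pairwise permutation Student tests
# ---------------------------------------------------------------------------

def _student_t(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-variance two-sample t; ±inf for zero variance with a mean gap."""
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    if sp2 <= 0:
        return 0.0 if diff == 0 else np.copysign(np.inf, diff)
    return float(diff / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def pairwise_permutation_t(values, group_labels, n_perm: int = PAIRWISE_N_PERM,
                           seed: int | None = None) -> pd.DataFrame:
    """Symmetric matrix of permutation p-values for all group pairs.

    For each pair the observed pooled Student t is compared with the |t|
    distribution under relabelling.  When the number of distinct splits of
    the pooled sample does not exceed ``n_perm`` the enumeration is
    exhaustive (exact test); otherwise ``n_perm`` random relabellings are
    drawn and the add-one correction applies.  Pairs involving a group of
    fewer than two observations are reported as missing.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = sorted(set(g))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    pmat = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for g1, g2 in combinations(groups, 2):
        x, y = v[g == g1], v[g == g2]
        if len(x) < 2 or len(y) < 2:
            pmat.loc[g1, g2] = pmat.loc[g2, g1] = np.nan
            continue
        pooled = np.concatenate([x, y])
        nx, ntot = len(x), len(pooled)
        t_obs = abs(_student_t(x, y))
        if comb(ntot, nx) <= n_perm + 1:
            hits = 0
            total = 0
            for idx in combinations(range(ntot), nx):
                mask = np.zeros(ntot, dtype=bool)
                mask[list(idx)] = True
                total += 1
                if abs(_student_t(pooled[mask], pooled[~mask])) >= t_obs - _SS_TIE_EPS:
                    hits += 1
            p = hits / total  # exact: observed split is one of the enumerated
        else:
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(ntot)
                if abs(_student_t(pooled[perm[:nx]], pooled[perm[nx:]])) >= t_obs - _SS_TIE_EPS:
                    hits += 1
            p = (1 + hits) / (1 + n_perm)
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
    return pmat


# ---------------------------------------------------------------------------
# Bootstrap summaries
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(values, n_boot: int = BOOTSTRAP_RUNS, level: float = 0.95,
                      seed: int | None = None) -> tuple[float, float, float]:
    """Percentile-bootstrap confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    means = v[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return float(v.mean()), float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


@dataclass
class CumulativeCurve:
    """ECDF of UD values with a bootstrap confidence band.

    ``fraction[i]`` is the share of animals with a value ≤ ``values[i]``;
    ``lower``/``upper`` bound it from ``n_boot`` resamples of individuals.
    """

    values: np.ndarray
    fraction: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def fraction_at(self, x: float) -> float:
        return float(np.mean(self.values <= x))


def cumulative_curve(values, n_boot: int = BOOTSTRAP_RUNS, level: float = 0.95,
                     seed: int | None = None) -> CumulativeCurve:
    """Empirical cumulative curve of UD values with a 95 % bootstrap band."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    n = len(v)
    frac = np.arange(1, n + 1) / n
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.sort(v[idx], axis=1)
    # bootstrap ECDF evaluated at each observed value
    ecdfs = np.mean(boot[:, :, None] <= v[None, None, :], axis=1)  # n_boot x n
    alpha = (1 - level) / 2
    lo = np.minimum(np.quantile(ecdfs, alpha, axis=0), frac)
    hi = np.maximum(np.quantile(ecdfs, 1 - alpha, axis=0), frac)
    return CumulativeCurve(v, frac, lo, hi)


def proportion_below(values, threshold_km2: float, n_boot: int = BOOTSTRAP_RUNS,
                     seed: int | None = None) -> tuple[float, float, float]:
    """Share of animals with UD strictly below a threshold, with bootstrap CI."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    indicator = (v < threshold_km2).astype(float)
    return bootstrap_mean_ci(indicator, n_boot=n_boot, seed=seed)


def group_summary(ud: pd.DataFrame, metric: str = "ud100_km2", n_boot: int = BOOTSTRAP_RUNS,
                  seed: int | None = None) -> pd.DataFrame:
    """Group means with bootstrap CIs per sex × maturity group (raw km²)."""
    rows = []
    for (mat, sex), grp in ud.groupby(["maturity", "sex"]):
        mean, lo, hi = bootstrap_mean_ci(grp[metric].to_numpy(), n_boot=n_boot, seed=seed)
        rows.append({"group": f"{mat}_{sex}", "n": len(grp), "mean_km2": mean,
                     "ci_lo_km2": lo, "ci_hi_km2": hi})
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
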