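"""Variance decomposition and significance/power calculations.

Implements the relative-importance (averaged sequential R-squared over all
orderings of model entry) decomposition by exact enumeration over predictor
subsets, Gaussian nested-model likelihood-ratio tests, incremental adjusted
R-squared, the Bonferroni family-wise threshold, and a two-group
normal-approximation power model for beta-value mean differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

MAX_LMG_PREDICTORS = 12


@dataclass
class VarianceDecomposition:
    shares: dict[str, float]
    total_r2: float
    n: int
    predictors: list[str]


@dataclass(frozen=True)
class PowerSpec:
    alpha_family: float = 0.05
    m_tests: int = 530_639
    delta: float = 0.05
    n: int = 120
    group_split: float = 0.5
    probe_sd: float | np.ndarray = 0.05

    def validate(self) -> None:
        if self.alpha_family <= 0 or self.m_tests < 1 or self.delta < 0 or self.n < 2:
            raise ValueError("power spec fields must be positive (n >= 2, m_tests >= 1)")
        if not 0.0 < self.group_split < 1.0:
            raise ValueError("group_split must lie strictly inside (0, 1)")
        sd = np.atleast_1d(np.asarray(self.probe_sd, dtype=float))
        if np.any(sd < 0) or not np.all(np.isfinite(sd)):
            raise ValueError("probe_sd must be finite and nonnegative")


@dataclass
class PowerResult:
    power: np.ndarray
    fraction_at_target: float
    target: float
    degenerate: np.ndarray


def _r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """Centred R-squared of OLS with intercept (0 for the empty model)."""
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    if X is None or X.shape[1] == 0:
        return 0.0
    Z = np.column_stack([np.ones(len(y)), X])
    coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    rss = float(np.sum((y - Z @ coef) ** 2))
    return 1.0 - rss / tss


def lmg_shares(
    outcome,
    predictors,
    groups: dict[str, list[str]] | None = None,
) -> VarianceDecomposition:
    """Relative-importance decomposition of the outcome variance.

    The share of predictor (group) ``j`` is the average, over all orderings
    of model entry, of the increase in R-squared when ``j`` enters — computed
    by exact enumeration over predictor subsets with the standard ordering
    weights ``|S|! (p - |S| - 1)! / p!``.  Shares are nonnegative up to
    rounding and sum exactly to the full-model R-squared.

    ``predictors`` is a DataFrame (or 2-D array); ``groups`` optionally maps
    group names to column lists so correlated blocks (e.g. cell fractions)
    enter as one predictor.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        Xdf = predictors.astype(float)
    else:
        arr = np.asarray(predictors, dtype=float)
        Xdf = pd.DataFrame(arr, columns=[f"x{i+1}" for i in range(arr.shape[1])])
    if groups is None:
        groups = {c: [c] for c in Xdf.columns}
    names = list(groups)
    p = len(names)
    if p < 1:
        raise ValueError("at least one predictor (group) is required")
    if p > MAX_LMG_PREDICTORS:
        raise ValueError(
            f"{p} predictors exceed the exact-enumeration bound of "
            f"{MAX_LMG_PREDICTORS}; group correlated blocks into fewer predictors"
        )
    full_X = Xdf[[c for name in names for c in groups[name]]].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), full_X])) < full_X.shape[1] + 1:
        raise ValueError("rank-deficient design; remove collinear predictors")

    cols = {name: Xdf[groups[name]].to_numpy() for name in names}
    r2_cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            if subset:
                X = np.hstack([cols[name] for name in names if name in subset])
            else:
                X = None
            r2_cache[subset] = _r2(y, X)
        return r2_cache[subset]

    fact = [math.factorial(i) for i in range(p + 1)]
    shares = {name: 0.0 for name in names}
    others = {name: [o for o in names if o != name] for name in names}
    for name in names:
        for size in range(p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for combo in combinations(others[name], size):
                S = frozenset(combo)
                shares[name] += w * (r2_of(S | {name}) - r2_of(S))

    total = r2_of(frozenset(names))
    return VarianceDecomposition(
        shares=shares, total_r2=total, n=len(y), predictors=names
    )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i+1}" for i in range(arr.shape[1])])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    Z = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    return float(np.sum((y - Z @ coef) ** 2))


def nested_lrt(outcome, full_design, reduced_design) -> tuple[float, int, float]:
    """Gaussian likelihood-ratio test of nested OLS models.

    Log-likelihoods are the Gaussian profile likelihoods from the residual
    sums of squares, so ``chi2 = n * log(RSS_reduced / RSS_full)`` with
    degrees of freedom equal to the column-count difference.
    """
    y = np.asarray(outcome, dtype=float)
    full = _as_frame(full_design)
    reduced = _as_frame(reduced_design) if reduced_design is not None else pd.DataFrame(index=full.index)
    if isinstance(full_design, pd.DataFrame) and isinstance(reduced_design, pd.DataFrame):
        if not set(reduced.columns) <= set(full.columns):
            raise ValueError("designs are not nested: reduced columns must be a subset of full")
    else:
        fcols = [full.iloc[:, j].to_numpy() for j in range(full.shape[1])]
        for j in range(reduced.shape[1]):
            r = reduced.iloc[:, j].to_numpy()
            if not any(np.allclose(r, f) for f in fcols):
                raise ValueError("designs are not nested: a reduced column is absent from full")
    df = full.shape[1] - reduced.shape[1]
    if df < 0:
        raise ValueError("designs are not nested: full has fewer columns than reduced")
    n = len(y)
    rss_full = _rss(y, full.to_numpy())
    rss_red = _rss(y, reduced.to_numpy())
    if rss_full <= 0:
        chi2 = 0.0 if rss_red <= 0 else float("inf")
    else:
        chi2 = max(n * math.log(rss_red / rss_full), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    if df == 0:
        chi2 = 0.0
    return chi2, df, p


def incremental_adj_r2(outcome, base_design, added_block) -> tuple[float, float, float, float]:
    """Adjusted R-squared before/after adding a predictor block.

    Returns ``(adj_r2_before, adj_r2_after, delta, p)`` with the p-value from
    the nested likelihood-ratio test of the added block.
    """
    y = np.asarray(outcome, dtype=float)
    base = _as_frame(base_design)
    added = _as_frame(added_block) if added_block is not None else pd.DataFrame(index=base.index)
    added = added.set_axis([f"__added_{c}" for c in added.columns], axis=1)
    combined = pd.concat([base.reset_index(drop=True), added.reset_index(drop=True)], axis=1)
    n = len(y)
    k_after = combined.shape[1]
    if n <= k_after + 1:
        raise ValueError("too few observations for the combined design")
    Z = np.column_stack([np.ones(n), combined.to_numpy()])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("combined design is rank deficient")

    def adj(r2: float, k: int) -> float:
        return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)

    r2_before = _r2(y, base.to_numpy() if base.shape[1] else None)
    r2_after = _r2(y, combined.to_numpy())
    a_before = adj(r2_before, base.shape[1])
    a_after = adj(r2_after, k_after)
    if added.shape[1] == 0:
        return a_before, a_after, 0.0, 1.0
    _, _, p = nested_lrt(y, combined, base.reset_index(drop=True))
    return a_before, a_after, a_after - a_before, p


def bonferroni_threshold(alpha_family: float, m_tests: int) -> float:
    """Per-test significance threshold ``alpha_family / m_tests``."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0 < alpha_family <= 1:
        raise ValueError("alpha_family must lie in (0, 1]")
    return alpha_family / m_tests


def round_sig(x: float, digits: int = 2) -> float:
    """Round to the given number of significant figures (display helper)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + digits - 1)


def probe_power(
    spec: PowerSpec,
    per_test_alpha: float,
    target: float = 0.80,
) -> PowerResult:
    """Two-sided two-group power for a mean beta-value difference.

    Normal approximation with group sizes ``n * split`` and ``n * (1 -
    split)``: ``power = Phi(-z + delta/se) + Phi(-z - delta/se)`` with ``se =
    sd * sqrt(1/n1 + 1/n2)`` and ``z`` the two-sided critical value at
    ``per_test_alpha``.  Probes with zero SD get power 1 and are flagged
    degenerate.  Also reports the fraction of probes with power >= target.
    """
    spec.validate()
    if not 0 < per_test_alpha < 1:
        raise ValueError("per_test_alpha must lie strictly inside (0, 1)")
    sd = np.atleast_1d(np.asarray(spec.probe_sd, dtype=float))
    n1 = spec.n * spec.group_split
    n2 = spec.n * (1.0 - spec.group_split)
    z = stats.norm.isf(per_test_alpha / 2.0)
    degenerate = sd == 0
    with np.errstate(divide="ignore"):
        se = sd * math.sqrt(1.0 / n1 + 1.0 / n2)
        shift = np.where(degenerate, np.inf, spec.delta / se)
    power = stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift)
    power = np.where(degenerate, 1.0, power)
    return PowerResult(
        power=power,
        fraction_at_target=float(np.mean(power >= target)),
        target=target,
        degenerate=degenerate,
    )
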