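"""Stability competitive adaptive reweighted sampling (SCARS).

SCARS selects informative wavenumbers for a PLS1 calibration.  It runs
N iterations; in each one, M Monte-Carlo subsets of the calibration
samples (a fixed fraction, default 0.6, drawn without replacement) are
fitted by PLS on the currently retained variables, and each variable j
is scored by its *stability*

    c_j = |mean(b_j)| / sd(b_j)

over the M coefficient vectors — a large, reproducible coefficient
beats a large but erratic one.  The retained-variable count is forced
down an exponentially decreasing schedule (all variables at iteration
1, two at iteration N); within each iteration the cut happens in two
stages: an enforced top-stability cut to a competition pool, then
adaptive reweighted sampling (ARS, weight proportional to stability)
down to the scheduled count.  Each iteration's subset is scored by
leave-one-out RMSECV of a PLS model on the full calibration set, and
the best subset of the run is the trace minimum.

(N, M) are tuned on a grid by repeated runs (lowest mean best-RMSECV),
and the final wavelength set is chosen by frequency of appearance over
many runs at the tuned (N, M): for every observed selection frequency
threshold, a PLS model on the variables at or above it is scored by
RMSEP on an independent prediction set, and the threshold with the
smallest RMSEP wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .pls_core import PLSModel, fit_pls, loo_rmsecv, monte_carlo_final_coefs, predict

__all__ = [
    "ScarsConfig",
    "StabilityVector",
    "ScarsRunResult",
    "NMOptimizationResult",
    "FrequencyTable",
    "stability",
    "edf_retention_schedule",
    "ars_sample",
    "run_scars_once",
    "optimize_nm",
    "frequency_select",
]


@dataclass(frozen=True)
class ScarsConfig:
    """Tunable parameters of the SCARS procedure.

    ``nm_grid`` lists the candidate values tried for each of N and M
    during tuning; ``nm_repetitions`` runs average the best RMSECV per
    (N, M) pair; ``final_runs`` SCARS runs at the tuned pair feed the
    frequency diagram.
    """

    n_iterations: int = 100
    m_samplings: int = 100
    sampling_ratio: float = 0.6
    nm_grid: tuple[int, ...] = (20, 50, 100, 200, 500)
    nm_repetitions: int = 30
    final_runs: int = 100
    max_lvs: int = 10
    ars_with_replacement: bool = False
    mrmsecv_statistic: str = "best"  # or "final": average the last-iteration RMSECV

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_ratio < 1.0:
            raise ValueError("sampling_ratio must be in (0, 1)")
        for name in ("n_iterations", "m_samplings", "nm_repetitions", "final_runs", "max_lvs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mrmsecv_statistic not in ("best", "final"):
            raise ValueError("mrmsecv_statistic must be 'best' or 'final'")

    @classmethod
    def reduced(cls) -> "ScarsConfig":
        """Reduced settings for small selection problems (tens of
        variables): a 2x2 (N, M) grid with 5 repetitions and 20 final
        runs."""
        return cls(nm_grid=(20, 50), nm_repetitions=5, final_runs=20, max_lvs=8)

    @classmethod
    def screening(cls) -> "ScarsConfig":
        """Screening-scale settings for full-grid (~950-variable)
        problems: fixed N=25 iterations, M=12 Monte-Carlo samplings,
        5 final runs.  Far below the reference settings
        (N, M tuned on {20..500}, 100 final runs) but enough to expose
        the selection-versus-full-spectrum comparison."""
        return cls(n_iterations=25, m_samplings=12, final_runs=5, max_lvs=10)


@dataclass
class StabilityVector:
    c: np.ndarray
    b_mean: np.ndarray
    b_sd: np.ndarray


@dataclass
class ScarsRunResult:
    subsets: list[np.ndarray]
    rmsecv_trace: np.ndarray
    best_subset: np.ndarray
    best_rmsecv: float
    best_lv: int


@dataclass
class NMOptimizationResult:
    best_n: int
    best_m: int
    mrmsecv: dict  # (N, M) -> mean RMSECV over repetitions

    @property
    def best(self) -> tuple[int, int]:
        return (self.best_n, self.best_m)


@dataclass
class FrequencyTable:
    counts: np.ndarray  # per-variable selection count over final_runs
    frequency_levels: np.ndarray  # candidate thresholds, descending
    rmsep_by_level: dict  # level -> prediction RMSEP
    chosen_level: int
    chosen_variables: np.ndarray
    final_runs: int


def stability(b_samples: np.ndarray) -> StabilityVector:
    """Stability c_j = |mean(b_j)| / sd(b_j) over Monte-Carlo fits.

    ``b_samples`` has one row per Monte-Carlo fit.  A variable whose
    coefficient never varies but is nonzero is maximally stable
    (c_j = +inf); an identically zero coefficient gives c_j = 0.
    """
    b = np.asarray(b_samples, dtype=float)
    if b.ndim != 2 or b.shape[0] < 2:
        raise ValueError("stability needs at least 2 Monte-Carlo coefficient rows")
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(mean) / sd
    c[(sd == 0.0) & (mean != 0.0)] = np.inf
    c[(sd == 0.0) & (mean == 0.0)] = 0.0
    return StabilityVector(c=c, b_mean=mean, b_sd=sd)


def edf_retention_schedule(N: int, p: int) -> np.ndarray:
    """Retained-variable counts r_i*p for the N iterations.

    The exponentially decreasing function r_i = a*exp(-k*i) is pinned
    so iteration 1 retains all p variables and iteration N retains 2:
    a*exp(-k) = 1 and a*exp(-k*N) = 2/p.  Counts are rounded, clamped
    to >= 2, and forced non-increasing.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if p < 2:
        raise ValueError("p must be >= 2")
    k = math.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    ratios = np.exp(-k * (i - 1))  # == a*exp(-k*i) with a = e^k
    counts = np.rint(ratios * p).astype(int)
    counts = np.clip(counts, 2, p)
    counts[0] = p
    counts[-1] = 2
    return np.minimum.accumulate(counts)


def ars_sample(weights: np.ndarray, count: int, rng: np.random.Generator, *, with_replacement: bool = False) -> np.ndarray:
    """Adaptive reweighted sampling: draw ``count`` variable indices.

    The default draws without replacement, sequentially, with selection
    probability proportional to the stability weight (realized via
    exponential sort keys).  ``+inf`` weights are selected before any
    finite ones.  Zero-weight variables are never selected; if fewer
    than ``count`` variables have positive weight, all of them are
    returned.  The ``with_replacement`` variant draws ``count`` times
    with replacement and deduplicates, so it can return fewer indices.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("weights must be 1-D")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    positive = np.flatnonzero(w > 0)
    if positive.size == 0:
        raise ValueError("all-zero weights: nothing to sample")
    if count >= positive.size:
        return np.sort(positive)
    infinite = positive[np.isinf(w[positive])]
    if infinite.size >= count:
        return np.sort(rng.choice(infinite, size=count, replace=False))
    finite = positive[np.isfinite(w[positive])]
    remaining = count - infinite.size
    if with_replacement:
        probs = w[finite] / w[finite].sum()
        drawn = np.unique(rng.choice(finite, size=remaining, p=probs, replace=True))
        return np.sort(np.concatenate([infinite, drawn]))
    keys = rng.exponential(size=finite.size) / w[finite]
    drawn = finite[np.argsort(keys)[:remaining]]
    return np.sort(np.concatenate([infinite, drawn]))


def _inner_lv_cap(config: ScarsConfig, n_rows: int, n_vars: int) -> int:
    return max(1, min(config.max_lvs, n_rows - 2, n_vars))


def run_scars_once(
    X: np.ndarray,
    y: np.ndarray,
    config: ScarsConfig,
    rng: np.random.Generator,
    *,
    N: int | None = None,
    M: int | None = None,
) -> ScarsRunResult:
    """One SCARS run: N elimination iterations, best subset by RMSECV.

    Iteration 1 always evaluates the full variable set, so the trace
    minimum can never exceed the full-spectrum RMSECV of the same data.
    A degenerate iteration (zero stability everywhere) is skipped with
    a warning, keeping the previous subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("SCARS needs at least 3 variables")
    N = config.n_iterations if N is None else N
    M = config.m_samplings if M is None else M

    def scored(subset: np.ndarray) -> tuple[float, int]:
        cv = loo_rmsecv(X[:, subset], y, max_lvs=_inner_lv_cap(config, n, subset.size))
        return cv.best_rmsecv, cv.best_lv

    if N == 1:
        full = np.arange(p)
        rmsecv, lv = scored(full)
        return ScarsRunResult(
            subsets=[full],
            rmsecv_trace=np.array([rmsecv]),
            best_subset=full,
            best_rmsecv=rmsecv,
            best_lv=lv,
        )

    schedule = edf_retention_schedule(N, p)
    n_sub = math.ceil(config.sampling_ratio * n)
    current = np.arange(p)
    subsets: list[np.ndarray] = []
    trace = np.empty(N)
    lvs = np.empty(N, dtype=int)
    for i, target in enumerate(schedule):
        lv_mc = _inner_lv_cap(config, n_sub, current.size)
        rows = np.empty((M, n_sub), dtype=np.int64)
        for m in range(M):
            rows[m] = rng.choice(n, size=n_sub, replace=False)
        coefs = monte_carlo_final_coefs(
            np.ascontiguousarray(X[:, current]), y, rows, lv_mc
        )
        stab = stability(coefs).c
        if not np.any(stab > 0):
            warnings.warn(f"degenerate iteration {i + 1}: zero stability everywhere; skipping")
        elif target < current.size:
            # enforced cut to a competition pool of twice the scheduled
            # count, then ARS down to the schedule
            pool_size = min(current.size, 2 * int(target))
            order = np.argsort(-stab, kind="stable")
            pool = order[:pool_size]
            if int(target) >= pool.size:
                keep = pool
            else:
                keep = pool[
                    ars_sample(
                        stab[pool],
                        int(target),
                        rng,
                        with_replacement=config.ars_with_replacement,
                    )
                ]
            current = np.sort(current[keep])
        subsets.append(current)
        trace[i], lvs[i] = scored(current)
    best_i = int(np.argmin(trace))
    return ScarsRunResult(
        subsets=subsets,
        rmsecv_trace=trace,
        best_subset=subsets[best_i],
        best_rmsecv=float(trace[best_i]),
        best_lv=int(lvs[best_i]),
    )


def _child_rngs(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [np.random.default_rng(int(s)) for s in seeds]


def optimize_nm(
    X: np.ndarray,
    y: np.ndarray,
    config: ScarsConfig,
    rng: np.random.Generator,
    *,
    nm_grid: tuple[int, ...] | None = None,
) -> NMOptimizationResult:
    """Tune (N, M) on the grid by mean best-RMSECV over repetitions.

    Each (N, M) pair gets ``config.nm_repetitions`` independent SCARS
    runs with fresh randomness; the pair with the lowest mean RMSECV
    wins, ties broken by grid order.  Deterministic given the generator
    state.
    """
    grid = config.nm_grid if nm_grid is None else tuple(nm_grid)
    if not grid:
        raise ValueError("nm_grid must be non-empty")
    table: dict[tuple[int, int], float] = {}
    best_pair = None
    best_val = np.inf
    for N, M in product(grid, grid):
        vals = []
        for child in _child_rngs(rng, config.nm_repetitions):
            result = run_scars_once(X, y, config, child, N=N, M=M)
            if config.mrmsecv_statistic == "best":
                vals.append(result.best_rmsecv)
            else:
                vals.append(float(result.rmsecv_trace[-1]))
        table[(N, M)] = float(np.mean(vals))
        if table[(N, M)] < best_val:
            best_val = table[(N, M)]
            best_pair = (N, M)
    return NMOptimizationResult(best_n=best_pair[0], best_m=best_pair[1], mrmsecv=table)


def frequency_select(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    n_star: int,
    m_star: int,
    config: ScarsConfig,
    rng: np.random.Generator,
) -> tuple[FrequencyTable, PLSModel]:
    """Final variable choice by selection frequency over many runs.

    Runs SCARS ``config.final_runs`` times at (N*, M*), counts how
    often each variable appears in a run's best subset, and for every
    distinct nonzero count (descending) fits a LOO-tuned PLS model on
    the variables at or above that threshold, scoring it by RMSEP on
    the prediction set.  Returns the frequency table and the winning
    model.  Thresholds leaving no variables are skipped; RMSEP ties go
    to the higher threshold (smaller subset).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_pred = np.asarray(X_pred, dtype=float)
    p = X_cal.shape[1]
    counts = np.zeros(p, dtype=int)
    for child in _child_rngs(rng, config.final_runs):
        result = run_scars_once(X_cal, y_cal, config, child, N=n_star, M=m_star)
        counts[result.best_subset] += 1
    levels = np.unique(counts[counts > 0])[::-1]
    if levels.size == 0:
        raise RuntimeError("no variable was ever selected")
    best_level = None
    best_rmsep = np.inf
    best_model = None
    best_vars = None
    rmsep_by_level: dict[int, float] = {}
    for level in levels:
        variables = np.flatnonzero(counts >= level)
        if variables.size < 1:
            continue
        cv = loo_rmsecv(
            X_cal[:, variables],
            y_cal,
            max_lvs=_inner_lv_cap(config, X_cal.shape[0], variables.size),
        )
        model = fit_pls(X_cal[:, variables], y_cal, cv.best_lv)
        resid = predict(model, X_pred[:, variables]) - y_pred
        rmsep = float(np.sqrt(np.mean(resid**2)))
        rmsep_by_level[int(level)] = rmsep
        if rmsep < best_rmsep:
            best_rmsep = rmsep
            best_level = int(level)
            best_model = model
            best_vars = variables
    table = FrequencyTable(
        counts=counts,
        frequency_levels=levels,
        rmsep_by_level=rmsep_by_level,
        chosen_level=best_level,
        chosen_variables=best_vars,
        final_runs=config.final_runs,
    )
    return table, best_model
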