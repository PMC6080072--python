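"""Random-frog variable selection and its bagged modification.

``rfa_run`` performs a single reversible-jump-like stochastic search over
variable subsets, scoring candidates by cross-validated PLS error; the
per-variable visit frequency is its importance score.  ``mrfa`` repeats the
search under bagged resampling (default 70 % of samples per run), summing
the per-run frequency vectors into an accumulated probability ``P`` whose
argmax is the selected variable.

Every stochastic choice derives from one master seed, so results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import _nipals, _pls_beta, rmse_eq1

__all__ = ["RFAParams", "SelectionResult", "rfa_run", "mrfa", "select_top"]


@dataclass(frozen=True)
class RFAParams:
    """Hyperparameters of one random-frog search.

    Defaults follow the published random-frog conventions (iteration count
    scaled down for desk-size problems; pass ``n_iterations=10_000`` for a
    full-scale run).
    """

    n_iterations: int = 1000
    init_subset_size: int = 2  # Q
    candidate_spread: float = 0.3  # theta: sd of candidate size, relative to Q
    oversample_factor: int = 3  # omega: extra variables drawn when growing
    acceptance_damping: float = 0.1  # eta in (0, 1]
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_subset_size < 1:
            raise ValueError("init_subset_size must be >= 1")
        if self.candidate_spread <= 0:
            raise ValueError("candidate_spread must be > 0")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")
        if not 0 < self.acceptance_damping <= 1:
            raise ValueError("acceptance_damping must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    """Accumulated selection probabilities from a bagged run."""

    probabilities: np.ndarray  # P_j in [0, n_runs]
    n_runs: int
    selected_index: int
    run_frequencies: np.ndarray | None = field(repr=False, default=None)
    holdout_rmse: np.ndarray | None = field(repr=False, default=None)


def _lean_fit(x: np.ndarray, y: np.ndarray, n_factors: int):
    """Centered PLS returning (beta, x_mean, y_mean); raises on degeneracy."""
    a = min(n_factors, x.shape[0] - 1, x.shape[1])
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    w, p, q = _nipals(x - x_mean, y - y_mean, a)
    return _pls_beta(w, p, q), x_mean, y_mean


def _cv_error(
    x: np.ndarray, y: np.ndarray, n_factors: int, folds: list[np.ndarray]
) -> float:
    n = x.shape[0]
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for test in folds:
        mask[:] = True
        mask[test] = False
        try:
            beta, xm, ym = _lean_fit(x[mask], y[mask], n_factors)
        except ValueError:
            return np.inf
        preds[test] = (x[test] - xm) @ beta + ym
    return rmse_eq1(y, preds)


def _rank_by_coefficient(
    x: np.ndarray, y: np.ndarray, subset: np.ndarray, n_factors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subset variables ordered by decreasing |PLS regression coefficient|."""
    try:
        beta, _, _ = _lean_fit(x[:, subset], y, n_factors)
    except ValueError:
        order = rng.permutation(subset.size)
        return subset[order]
    order = np.argsort(-np.abs(beta), kind="stable")
    return subset[order]


def rfa_run(
    x: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    params: RFAParams = RFAParams(),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> np.ndarray:
    """One random-frog search; returns per-variable visit frequencies in
    ``[0, 1]``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if p == 0:
        raise ValueError("no variables to select from")
    if n < 6:
        raise ValueError("need at least 6 samples")
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    rng = np.random.default_rng(seed)

    k = min(params.cv_folds, n)
    folds = [np.sort(f) for f in np.array_split(rng.permutation(n), k)]
    cache: dict[tuple, float] = {}

    def fitness(subset: np.ndarray) -> float:
        key = tuple(subset.tolist())
        if key not in cache:
            cache[key] = _cv_error(x[:, subset], y, n_factors, folds)
        return cache[key]

    q0 = min(params.init_subset_size, p)
    current = np.sort(rng.choice(p, size=q0, replace=False))
    err_current = fitness(current)
    counts = np.zeros(p)

    for _ in range(params.n_iterations):
        q = current.size
        q_star = int(np.rint(rng.normal(q, params.candidate_spread * q)))
        q_star = min(max(q_star, 1), p)
        if q_star < q:
            ranked = _rank_by_coefficient(x, y, current, n_factors, rng)
            candidate = np.sort(ranked[:q_star])
        elif q_star > q:
            outside = np.setdiff1d(np.arange(p), current, assume_unique=False)
            n_add = min(params.oversample_factor * (q_star - q), outside.size)
            extra = rng.choice(outside, size=n_add, replace=False)
            pool = np.concatenate([current, extra])
            if pool.size > q_star:
                ranked = _rank_by_coefficient(x, y, pool, n_factors, rng)
                candidate = np.sort(ranked[:q_star])
            else:
                candidate = np.sort(pool)
        else:
            candidate = current
        err_candidate = fitness(candidate)
        if err_candidate <= err_current:
            accept = True
        elif not np.isfinite(err_candidate):
            accept = False
        else:
            accept = rng.random() < params.acceptance_damping * (
                err_current / err_candidate
            )
        if accept:
            current, err_current = candidate, err_candidate
        counts[current] += 1.0
    return counts / params.n_iterations


def mrfa(
    x: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    n_runs: int = 1000,
    train_fraction: float = 0.7,
    params: RFAParams = RFAParams(),
    seed: int = 0,
    keep_run_frequencies: bool = False,
) -> SelectionResult:
    """Bagged random frog: ``n_runs`` searches on random ``train_fraction``
    sample subsets; per-run frequencies summed into ``P``.

    The held-out fraction of each run is scored once (PLS on the run's
    above-mean-frequency variables) and logged for audit; it never drives
    the within-run search.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 6 or n - n_train < 1:
        raise ValueError(
            f"train fraction {train_fraction} leaves too few samples "
            f"({n_train} train / {n - n_train} holdout)"
        )

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_runs)
    accumulated = np.zeros(p)
    run_freqs = np.empty((n_runs, p)) if keep_run_frequencies else None
    holdout = np.empty(n_runs)

    for b, child in enumerate(children):
        split_ss, rfa_ss = child.spawn(2)
        rng = np.random.default_rng(split_ss)
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        freq = rfa_run(x[train_idx], y[train_idx], n_factors, params, rfa_ss)
        accumulated += freq
        if run_freqs is not None:
            run_freqs[b] = freq
        keep = np.flatnonzero(freq > freq.mean()) if p > 1 else np.array([0])
        if keep.size == 0:
            keep = np.array([int(np.argmax(freq))])
        try:
            beta, xm, ym = _lean_fit(
                x[np.ix_(train_idx, keep)], y[train_idx], n_factors
            )
            pred = (x[np.ix_(test_idx, keep)] - xm) @ beta + ym
            holdout[b] = (
                rmse_eq1(y[test_idx], pred) if test_idx.size >= 2 else np.nan
            )
        except ValueError:
            holdout[b] = np.nan

    selected = int(np.argmax(accumulated))  # ties -> lowest index
    return SelectionResult(
        probabilities=accumulated,
        n_runs=n_runs,
        selected_index=selected,
        run_frequencies=run_freqs,
        holdout_rmse=holdout,
    )


def select_top(result: SelectionResult, k: int) -> np.ndarray:
    """Indices of the ``k`` largest accumulated probabilities; ties broken
    by lowest index."""
    p = result.probabilities.size
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    order = np.lexsort((np.arange(p), -result.probabilities))
    return order[:k]
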