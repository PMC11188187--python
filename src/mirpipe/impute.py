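"""Missing-value strategies for the expression matrix.

Six strategies, named by what they do (field labels in parentheses):

* ``impute_constant``                    — fill with a constant, default 1 (A)
* ``impute_rf_iterative``                — iterative random-forest, missForest-style (B)
* ``replace_negative_with_smallest_positive`` — for BG-subtraction data (C)
* ``impute_sample_minimum``              — per-sample observed minimum (D)
* ``impute_knn``                         — k-nearest miRNA rows, Euclidean (E)
* ``impute_em``                          — multivariate-normal EM (F)

Orientation conventions (documented per imputer): kNN neighbors *miRNA rows*
(the gene-neighbor convention of expression kNN imputation); EM and the
iterative forest treat *sample columns* as variables and miRNA rows as
observations — a ~75-variable model over ~2000 observations is estimable,
whereas the transpose is not.

All imputers leave observed entries bit-identical and return a matrix with
an empty mask (preconditions permitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import ImputationError
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnnParams:
    """k-nearest-neighbor imputation parameters (k=10, max missing 0.95)."""

    k: int = 10
    max_missing: float = 0.95

    def validate(self) -> None:
        if self.k < 1:
            raise ImputationError("k must be >= 1")
        if not 0.0 < self.max_missing <= 1.0:
            raise ImputationError("max_missing must be in (0, 1]")


@dataclass(frozen=True)
class EmParams:
    """EM imputation parameters; m=1 with a deterministic conditional mean
    by default, or a single seeded draw (``stochastic_draw``) emulating one
    random imputation."""

    m: int = 1
    max_iter: int = 100
    tol: float = 1e-4
    ridge: float = 1e-6
    seed: int = 0
    draw_mode: str = "conditional_mean"  # or "stochastic_draw"

    def validate(self) -> None:
        if self.m < 1:
            raise ImputationError("m must be >= 1")
        if self.tol <= 0:
            raise ImputationError("tol must be > 0")
        if self.ridge < 0:
            raise ImputationError("ridge must be >= 0")
        if self.draw_mode not in ("conditional_mean", "stochastic_draw"):
            raise ImputationError(f"unknown draw_mode {self.draw_mode!r}")


@dataclass(frozen=True)
class RfParams:
    """Iterative random-forest parameters (ntree=100, mtry=sqrt(p) as in the
    standard iterative-forest defaults)."""

    n_trees: int = 100
    max_iter: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ImputationError("n_trees must be >= 1")
        if self.max_iter < 1:
            raise ImputationError("max_iter must be >= 1")


# ---------------------------------------------------------------------------
# simple strategies
# ---------------------------------------------------------------------------


def impute_constant(matrix: ExpressionMatrix, value: float = 1.0) -> ExpressionMatrix:
    """Fill every missing entry with ``value`` (default 1)."""
    out = matrix.values.copy()
    out[np.isnan(out)] = value
    return matrix.with_values(out)


def impute_sample_minimum(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing entries with the minimum observed value of their own
    sample column."""
    out = matrix.values.copy()
    mask = np.isnan(out)
    for c in range(out.shape[1]):
        col_missing = mask[:, c]
        if not col_missing.any():
            continue
        observed = out[~col_missing, c]
        if observed.size == 0:
            raise ImputationError(
                f"sample {matrix.sample_ids[c]}: no observed value to take a minimum from"
            )
        out[col_missing, c] = observed.min()
    return matrix.with_values(out)


def replace_negative_with_smallest_positive(
    matrix: ExpressionMatrix,
) -> ExpressionMatrix:
    """Replace every negative and every missing entry by the smallest
    strictly positive observed value of its sample column (the
    BG-subtraction-variant replacement)."""
    out = matrix.values.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        replace = np.isnan(col) | (col < 0)
        if not replace.any():
            continue
        positive = col[(~np.isnan(col)) & (col > 0)]
        if positive.size == 0:
            raise ImputationError(
                f"sample {matrix.sample_ids[c]}: no strictly positive value available"
            )
        col[replace] = positive.min()
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# k-nearest-neighbor rows
# ---------------------------------------------------------------------------


def impute_knn(matrix: ExpressionMatrix, params: KnnParams = KnnParams()) -> ExpressionMatrix:
    """kNN imputation over miRNA rows.

    For each row with missing entries (and missing fraction <= max_missing):
    candidate neighbors are all other rows; the distance to a candidate is
    the Euclidean distance over coordinates observed in *both* rows, divided
    by sqrt(#shared coordinates) so rows with more overlap are not penalized.
    The k nearest candidates' observed values at the missing column are
    averaged (candidates missing there are skipped).  Fallbacks: rows above
    max_missing or with no usable neighbor use the row mean of observed
    entries, then the column mean.  Fully deterministic; ties broken by row
    order.
    """
    params.validate()
    X = matrix.values
    n_rows, n_cols = X.shape
    if n_rows < 2:
        raise ImputationError("kNN needs at least 2 rows")
    mask = np.isnan(X)
    out = X.copy()
    row_rate = mask.mean(axis=1)
    col_counts = (~mask).sum(axis=0)
    col_means = np.divide(
        np.where(mask, 0.0, X).sum(axis=0),
        col_counts,
        out=np.full(n_cols, np.nan),
        where=col_counts > 0,
    )
    fallbacks = 0

    obs = ~mask
    X0 = np.where(mask, 0.0, X)
    for r in np.flatnonzero(mask.any(axis=1)):
        miss_cols = np.flatnonzero(mask[r])
        row_obs = obs[r]
        row_mean = X[r, row_obs].mean() if row_obs.any() else np.nan

        if row_rate[r] > params.max_missing or not row_obs.any():
            fill = row_mean if np.isfinite(row_mean) else col_means[miss_cols]
            out[r, miss_cols] = fill
            fallbacks += len(miss_cols)
            continue

        shared = obs & row_obs[None, :]  # candidates x cols
        shared[r] = False
        n_shared = shared.sum(axis=1)
        diff = (X0 - X0[r][None, :]) * shared
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
        dist[r] = np.inf
        dist[n_shared == 0] = np.inf

        order = np.argsort(dist, kind="stable")
        order = order[np.isfinite(dist[order])]
        neighbors = order[: params.k]
        for c in miss_cols:
            usable = neighbors[obs[neighbors, c]]
            if usable.size:
                out[r, c] = X[usable, c].mean()
            else:
                out[r, c] = row_mean if np.isfinite(row_mean) else col_means[c]
                fallbacks += 1
    if fallbacks:
        log.info("knn imputation: %d fallback fills", fallbacks)
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# EM under a multivariate normal over sample columns
# ---------------------------------------------------------------------------


def _em_fit(
    X: np.ndarray, mask: np.ndarray, params: EmParams
) -> tuple[np.ndarray, np.ndarray, int]:
    """EM for (mu, Sigma) of a p-variate normal from rows with missing
    coordinates.  Returns (mu, Sigma, n_iter)."""
    n, p = X.shape
    # initialize with column means / diagonal covariance of observed data
    Xf = np.where(mask, np.nan, X)
    mu = np.nanmean(Xf, axis=0)
    var0 = np.nanvar(Xf, axis=0, ddof=1)
    var0[~np.isfinite(var0)] = 1.0
    var0[var0 <= 0] = 1.0
    Sigma = np.diag(var0)

    patterns: dict[bytes, np.ndarray] = {}
    for r in range(n):
        patterns.setdefault(mask[r].tobytes(), []).append(r)
    patterns = {k: np.array(v) for k, v in patterns.items()}

    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        S = np.zeros((p, p))
        M = np.zeros(p)
        Xhat = X.copy()
        for key, rows in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            o = ~miss
            if miss.any():
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(miss, o)]
                solve = np.linalg.solve(Soo, (X[np.ix_(rows, o)] - mu[o]).T)
                cond_mean = mu[miss][None, :] + (Smo @ solve).T
                cond_cov = Sigma[np.ix_(miss, miss)] - Smo @ np.linalg.solve(
                    Soo, Smo.T
                )
                Xhat[np.ix_(rows, miss)] = cond_mean
                # accumulate the conditional-covariance correction
                C = np.zeros((p, p))
                C[np.ix_(miss, miss)] = cond_cov * len(rows)
                S += C
            M += Xhat[rows].sum(axis=0)
            centered = Xhat[rows]
            S += centered.T @ centered
        mu_new = M / n
        Sigma_new = S / n - np.outer(mu_new, mu_new)
        Sigma_new[np.diag_indices(p)] += params.ridge
        change = max(
            np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max()
        )
        mu, Sigma = mu_new, Sigma_new
        if change < params.tol:
            break
    return mu, Sigma, n_iter


def impute_em(matrix: ExpressionMatrix, params: EmParams = EmParams()) -> ExpressionMatrix:
    """EM imputation under a multivariate normal over sample columns.

    The E step computes conditional expectations (and second moments) of each
    row's missing coordinates given its observed ones; the M step updates the
    mean vector and covariance (ridge added to the diagonal); iteration stops
    when the maximum absolute parameter change drops below ``tol``.  Missing
    entries are then filled with the converged conditional means, or with one
    seeded draw from the conditional normal when ``draw_mode ==
    "stochastic_draw"`` (a single random imputation).
    """
    params.validate()
    X = matrix.values
    n, p = X.shape
    mask = np.isnan(X)
    if not mask.any():
        return matrix.copy()
    if p > n and params.ridge <= 0:
        raise ImputationError(
            f"{p} columns over {n} rows: covariance is singular without ridge > 0"
        )
    if mask.all(axis=1).any():
        raise ImputationError("a row with no observed entry cannot be conditioned on")

    X0 = np.where(mask, 0.0, X)
    mu, Sigma, n_iter = _em_fit(X0, mask, params)
    log.info("em imputation: converged in %d iterations", n_iter)

    rng = np.random.default_rng(params.seed)
    out = X.copy()
    for r in np.flatnonzero(mask.any(axis=1)):
        miss = mask[r]
        o = ~miss
        Soo = Sigma[np.ix_(o, o)]
        Smo = Sigma[np.ix_(miss, o)]
        cond_mean = mu[miss] + Smo @ np.linalg.solve(Soo, X[r, o] - mu[o])
        if params.draw_mode == "stochastic_draw":
            cond_cov = Sigma[np.ix_(miss, miss)] - Smo @ np.linalg.solve(Soo, Smo.T)
            cond_cov = (cond_cov + cond_cov.T) / 2.0
            out[r, miss] = rng.multivariate_normal(
                cond_mean, cond_cov, method="svd"
            )
        else:
            out[r, miss] = cond_mean
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# iterative random forest (missForest-style)
# ---------------------------------------------------------------------------


def impute_rf_iterative(
    matrix: ExpressionMatrix, params: RfParams = RfParams()
) -> ExpressionMatrix:
    """Iterative random-forest imputation over sample columns.

    Missing entries start at their column means.  Each sweep visits columns
    in ascending order of missingness, trains a random-forest regressor of
    the column on all other columns using rows observed in the target, and
    re-predicts the originally missing rows.  Sweeps stop at the first rise
    of the normalized squared difference between successive imputations
    (returning the previous sweep's values) or at ``max_iter``.
    """
    params.validate()
    X = matrix.values
    n, p = X.shape
    if p < 2:
        raise ImputationError("iterative forest needs >= 2 columns")
    mask = np.isnan(X)
    if not mask.any():
        log.info("rf imputation: matrix complete, zero refit iterations")
        return matrix.copy()
    if mask.all(axis=0).any():
        raise ImputationError("a fully missing column cannot be trained on")

    col_means = np.nanmean(X, axis=0)
    cur = X.copy()
    for c in range(p):
        cur[mask[:, c], c] = col_means[c]

    col_order = np.argsort(mask.sum(axis=0), kind="stable")
    rng = np.random.default_rng(params.seed)
    prev = cur.copy()
    prev_criterion = np.inf
    stop_reason = "max_iter"
    n_sweeps = 0
    for n_sweeps in range(1, params.max_iter + 1):
        new = cur.copy()
        for c in col_order:
            rows_miss = mask[:, c]
            if not rows_miss.any():
                continue
            rows_obs = ~rows_miss
            others = np.arange(p) != c
            forest = RandomForestRegressor(
                n_estimators=params.n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(new[np.ix_(rows_obs, others)], X[rows_obs, c])
            new[rows_miss, c] = forest.predict(new[np.ix_(rows_miss, others)])
        imput = new[mask]
        criterion = ((imput - cur[mask]) ** 2).sum() / max((imput**2).sum(), 1e-300)
        if criterion > prev_criterion:
            stop_reason = "criterion_rose"
            cur = prev  # previous sweep's values
            break
        prev, cur = cur, new
        prev_criterion = criterion
    log.info(
        "rf imputation: %d sweeps, stop reason %s", n_sweeps, stop_reason
    )
    out = X.copy()
    out[mask] = cur[mask]
    return matrix.with_values(out)
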