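"""Parametric empirical-Bayes batch correction (ComBat) without covariates.

The model assumes, per miRNA g, sample j in batch b:

    Y_gjb = alpha_g + gamma_gb + delta_gb * eps_gjb,   eps ~ N(0, sigma_g^2)

gamma (additive) and delta (multiplicative) are per-batch, per-miRNA batch
effects, shrunk across miRNAs toward batch-level priors — normal for gamma,
inverse-gamma for delta, hyperparameters estimated by method of moments —
and removed from the standardized data.  The arithmetic follows the
reference implementation (batch-size-weighted grand mean; pooled variance
with a 1/n denominator; within-batch variance of the standardized data with
n-1; fixed-point iteration of the posterior equations).

A single-batch input has no batch contrast to correct: gamma*=0, delta*=1
and the data are returned unchanged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BatchCorrectionError
from .matrix import LOG2, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CombatFit:
    """Audit record of one ComBat fit."""

    batches: list[str]
    grand_mean: np.ndarray          # per miRNA
    pooled_variance: np.ndarray     # per miRNA
    batch_design: dict[str, str]    # sample -> batch
    gamma_hat: np.ndarray           # batch x miRNA
    delta_hat: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    hyperparams: dict[str, list[float]] = field(default_factory=dict)
    n_iter: list[int] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "batches": self.batches,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_variance": self.pooled_variance.tolist(),
            "batch_design": self.batch_design,
            "gamma_hat": self.gamma_hat.tolist(),
            "delta_hat": self.delta_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "hyperparams": self.hyperparams,
            "n_iter": self.n_iter,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv, max_iter):
    """Fixed-point iteration for one batch's EB posteriors."""
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = np.inf
    count = 0
    while change > conv and count < max_iter:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        denom_g = np.maximum(np.abs(g_old), 1e-12)
        denom_d = np.maximum(np.abs(d_old), 1e-12)
        change = max(
            (np.abs(g_new - g_old) / denom_g).max(),
            (np.abs(d_new - d_old) / denom_d).max(),
        )
        g_old, d_old = g_new, d_new
        count += 1
    if change > conv:
        warnings.warn(
            f"ComBat EB iteration stopped at max_iter={max_iter} with "
            f"residual change {change:.3g} (final delta range "
            f"[{d_old.min():.4g}, {d_old.max():.4g}])",
            stacklevel=3,
        )
    return g_old, d_old, count


def combat_fit_transform(
    matrix: ExpressionMatrix,
    batch_labels: dict[str, str] | None = None,
    parametric: bool = True,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[ExpressionMatrix, CombatFit]:
    """Remove per-batch location/scale effects from a complete log2 matrix.

    ``batch_labels`` defaults to the matrix's own ``batch_of`` metadata.
    Returns the adjusted matrix and a :class:`CombatFit` audit record.
    """
    if not parametric:
        raise BatchCorrectionError("only the parametric EB variant is implemented")
    if not matrix.is_complete:
        raise BatchCorrectionError(
            f"matrix has {matrix.n_missing} missing entries; impute before correction"
        )
    if matrix.scale != LOG2:
        raise BatchCorrectionError("batch correction expects log2-scale data")
    labels = batch_labels if batch_labels is not None else matrix.batch_of
    try:
        sample_batches = np.array([labels[s] for s in matrix.sample_ids])
    except KeyError as exc:
        raise BatchCorrectionError(f"sample {exc} has no batch label") from exc

    batches = sorted(set(sample_batches))
    X = matrix.values
    G, n = X.shape
    batch_cols = [np.flatnonzero(sample_batches == b) for b in batches]
    n_b = np.array([len(c) for c in batch_cols])
    for b, nb in zip(batches, n_b):
        if nb < 2:
            raise BatchCorrectionError(f"batch {b!r} has {nb} sample(s); need >= 2")

    batch_means = np.column_stack([X[:, c].mean(axis=1) for c in batch_cols])
    grand_mean = batch_means @ (n_b / n)
    fitted = np.empty_like(X)
    for k, cols in enumerate(batch_cols):
        fitted[:, cols] = batch_means[:, [k]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        bad = matrix.mirna_ids[int(np.argmax(var_pooled <= 0))]
        raise BatchCorrectionError(f"miRNA {bad} has zero within-batch variance")

    if len(batches) == 1:
        # no contrast to correct
        fit = CombatFit(
            batches=batches,
            grand_mean=grand_mean,
            pooled_variance=var_pooled,
            batch_design=dict(zip(matrix.sample_ids, sample_batches)),
            gamma_hat=np.zeros((1, G)),
            delta_hat=np.ones((1, G)),
            gamma_star=np.zeros((1, G)),
            delta_star=np.ones((1, G)),
            n_iter=[0],
        )
        return matrix.copy(), fit

    sd = np.sqrt(var_pooled)
    Z = (X - grand_mean[:, None]) / sd[:, None]

    gamma_hat = np.stack([Z[:, c].mean(axis=1) for c in batch_cols])
    delta_hat = np.stack([Z[:, c].var(axis=1, ddof=1) for c in batch_cols])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    hyper = {"gamma_bar": [], "t2": [], "a_prior": [], "b_prior": []}
    n_iters = []
    for k, cols in enumerate(batch_cols):
        g = gamma_hat[k]
        d = delta_hat[k]
        g_bar, t2 = g.mean(), g.var(ddof=1)
        m, s2 = d.mean(), d.var(ddof=1)
        if s2 <= 0:
            # degenerate prior (all delta_hat equal): nothing to shrink
            a = b = float("nan")
            gamma_star[k] = np.full(G, g_bar) if t2 <= 0 else _postmean(
                g, g_bar, len(cols), d, t2
            )
            delta_star[k] = d
            n_iters.append(0)
        else:
            a = (2.0 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
            gamma_star[k], delta_star[k], count = _it_sol(
                Z[:, cols], g, d, g_bar, t2, a, b, tol, max_iter
            )
            n_iters.append(count)
        hyper["gamma_bar"].append(float(g_bar))
        hyper["t2"].append(float(t2))
        hyper["a_prior"].append(float(a))
        hyper["b_prior"].append(float(b))

    adjusted = Z.copy()
    for k, cols in enumerate(batch_cols):
        adjusted[:, cols] = (Z[:, cols] - gamma_star[k][:, None]) / np.sqrt(
            delta_star[k][:, None]
        )
    adjusted = adjusted * sd[:, None] + grand_mean[:, None]

    log.info(
        "combat: %d batches, EB iterations %s", len(batches), n_iters
    )
    fit = CombatFit(
        batches=batches,
        grand_mean=grand_mean,
        pooled_variance=var_pooled,
        batch_design=dict(zip(matrix.sample_ids, sample_batches)),
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        hyperparams=hyper,
        n_iter=n_iters,
    )
    return matrix.with_values(adjusted), fit
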