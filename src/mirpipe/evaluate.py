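"""Agreement and batch-effect metrics.

Agreement between two batches is judged on the common sample pairs.  All
(pair, miRNA) units are pooled as the "subjects" of a two-way random-effects
ANOVA whose two "raters" are the batches; the single-measure intraclass
correlation is

    ICC(2,1) = (MS_C - MS_E) / (MS_C + MS_E + (2/N) (MS_B - MS_E))

with MS_C, MS_B, MS_E the mean squares for subjects (combined common samples
and miRNAs), batches, and residuals, and N the pooled unit count.  The 95%
interval is the standard two-way-random absolute-agreement construction and
the test of H0: ICC = 0 uses F = MS_C / MS_E on (N-1, N-1) df.

RMSE is the root mean squared between-batch difference over the pooled
units; NRMSE divides by the range of the batch-1 values.

Batch effects are scored by Welch t-tests comparing the two batches' scores
on the first two principal components of the common-sample columns
(per-miRNA centering, no scaling), with Benjamini-Hochberg adjustment across
the whole report.

Units are split by pre-imputation NA rate: per common pair, an NA rate of
0.5 means the miRNA was missing in exactly one batch (so one side is an
imputed value) and 0 means it was measured in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import EvaluationError
from .matrix import LINEAR, ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PairedValues:
    """Aligned (batch-1, batch-2) value vectors over common sample pairs."""

    pairs: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = []
        for b1, b2 in self.pairs:
            b1 = np.asarray(b1, dtype=float)
            b2 = np.asarray(b2, dtype=float)
            if b1.shape != b2.shape:
                raise EvaluationError("pair vectors differ in length")
            if b1.size:  # pairs with no units contribute nothing
                clean.append((b1, b2))
        self.pairs = clean

    @property
    def n_total(self) -> int:
        return int(sum(b1.size for b1, _ in self.pairs))

    @property
    def b1(self) -> np.ndarray:
        if not self.pairs:
            return np.empty(0)
        return np.concatenate([p[0] for p in self.pairs])

    @property
    def b2(self) -> np.ndarray:
        if not self.pairs:
            return np.empty(0)
        return np.concatenate([p[1] for p in self.pairs])


@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way (subjects x 2 raters) mean squares without replication."""

    ms_subjects: float
    ms_raters: float
    ms_error: float
    df_subjects: int
    df_raters: int
    df_error: int


@dataclass
class AgreementResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    rmse: float
    nrmse: float
    n_total: int


@dataclass
class BatchEffectResult:
    p_pc1: float
    p_pc2: float
    variance_explained: tuple[float, float]
    checkpoint: str
    adj_p_pc1: float = float("nan")
    adj_p_pc2: float = float("nan")


# ---------------------------------------------------------------------------
# NA-rate subsetting
# ---------------------------------------------------------------------------


def extract_pair_subsets(
    premask: np.ndarray,
    sample_ids: list[str],
    common_pairs: list[tuple[str, str]],
    na_rate: float,
) -> list[np.ndarray]:
    """Per-pair miRNA row indices at the requested pre-imputation NA rate.

    na_rate 0.5: missing in exactly one of the two batches for that pair;
    na_rate 0: observed in both.  miRNAs missing in both batches (rate 1.0)
    belong to neither set.
    """
    if na_rate not in (0.5, 0.0):
        raise EvaluationError(f"na_rate must be 0.5 or 0, got {na_rate}")
    col = {s: i for i, s in enumerate(sample_ids)}
    out = []
    for s1, s2 in common_pairs:
        if s1 not in col or s2 not in col:
            raise EvaluationError(f"pair ({s1}, {s2}) references unknown sample ids")
        m1 = premask[:, col[s1]]
        m2 = premask[:, col[s2]]
        chosen = (m1 ^ m2) if na_rate == 0.5 else (~m1 & ~m2)
        out.append(np.flatnonzero(chosen))
    return out


def paired_from_matrix(
    matrix: ExpressionMatrix,
    common_pairs: list[tuple[str, str]],
    row_subsets: list[np.ndarray] | None = None,
) -> PairedValues:
    """Aligned pair vectors pulled from a (complete) checkpoint matrix.

    Linear-scale snapshots are log2-transformed first, since agreement is
    judged on log-normalized values.
    """
    values = matrix.values
    if matrix.scale == LINEAR:
        if (values[~np.isnan(values)] <= 0).any():
            raise EvaluationError("linear snapshot has entries <= 0; cannot log2")
        values = np.log2(values)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    pairs = []
    for i, (s1, s2) in enumerate(common_pairs):
        rows = (
            np.arange(values.shape[0]) if row_subsets is None else row_subsets[i]
        )
        pairs.append((values[rows, col[s1]], values[rows, col[s2]]))
    return PairedValues(pairs=pairs)


# ---------------------------------------------------------------------------
# ICC(2,1) and RMSE / NRMSE
# ---------------------------------------------------------------------------


def icc_2_1(paired: PairedValues) -> tuple[AgreementResult, AnovaDecomposition]:
    """Two-way random-effects single-measure ICC over the pooled layout.

    Subjects are the pooled (pair, miRNA) units; raters are the two batches.
    Returns the agreement result (RMSE fields NaN; see :func:`rmse_nrmse`)
    and the ANOVA decomposition.
    """
    N = paired.n_total
    if N < 2:
        raise EvaluationError(f"need >= 2 pooled units for ICC, got {N}")
    Y = np.column_stack([paired.b1, paired.b2])  # N x 2
    k = 2
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    rater_means = Y.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = N * ((rater_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    df_subj, df_rater, df_err = N - 1, k - 1, (N - 1) * (k - 1)
    msc = ss_subj / df_subj
    msb = ss_rater / df_rater
    mse = max(ss_err / df_err, 0.0)
    anova = AnovaDecomposition(msc, msb, mse, df_subj, df_rater, df_err)

    denom = msc + mse + (2.0 / N) * (msb - mse)
    if denom == 0:
        raise EvaluationError("zero subject and error variance: ICC undefined")
    icc = (msc - mse) / denom

    # F test of H0: ICC = 0
    if mse == 0:
        p = 0.0 if msc > 0 else float("nan")
        ci_low = ci_high = 1.0
    else:
        F = msc / mse
        p = float(stats.f.sf(F, df_subj, df_err))
        ci_low, ci_high = _icc_ci(icc, msc, msb, mse, N, k)
    result = AgreementResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        rmse=float("nan"),
        nrmse=float("nan"),
        n_total=N,
    )
    return result, anova


def _icc_ci(r, msr, msc, mse, n, k, alpha=0.05):
    """95% interval for the two-way-random absolute-agreement single-measure
    ICC (the construction used by standard reliability software).

    Here ``msr`` is the subjects MS, ``msc`` the raters MS, ``mse`` the
    residual MS."""
    one_minus = max(1.0 - r, 1e-15)
    a = (k * r) / (n * one_minus)
    b = 1.0 + (k * r * (n - 1.0)) / (n * one_minus)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    fl = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    fu = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - fl * mse)) / (
        fl * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (fu * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * fu * msr
    )
    return lower, upper


def rmse_nrmse(paired: PairedValues) -> tuple[float, float]:
    """RMSE over pooled units and RMSE normalized by the batch-1 range."""
    N = paired.n_total
    if N < 1:
        raise EvaluationError("need >= 1 pooled unit for RMSE")
    b1, b2 = paired.b1, paired.b2
    rmse = float(np.sqrt(((b1 - b2) ** 2).sum() / N))
    rng = b1.max() - b1.min()
    if rng == 0:
        raise EvaluationError("zero batch-1 range: NRMSE undefined")
    return rmse, float(rmse / rng)


def agreement(paired: PairedValues) -> tuple[AgreementResult, AnovaDecomposition]:
    """ICC(2,1) plus RMSE/NRMSE in one result."""
    result, anova = icc_2_1(paired)
    result.rmse, result.nrmse = rmse_nrmse(paired)
    return result, anova


# ---------------------------------------------------------------------------
# PCA batch test and BH adjustment
# ---------------------------------------------------------------------------


def pca_batch_test(
    matrix: ExpressionMatrix,
    common_pairs: list[tuple[str, str]],
    batch_labels: dict[str, str] | None = None,
    checkpoint: str = "",
) -> BatchEffectResult:
    """Welch t-tests on PC1/PC2 scores of the common-sample columns.

    The matrix is restricted to the two batch copies of each common sample,
    each miRNA is centered (no unit-variance scaling) and PCA is taken over
    samples; scores are compared between batches.  A zero-variance contrast
    (no batch signal at all) yields p = 1.
    """
    if len(common_pairs) < 2:
        raise EvaluationError("need >= 2 common pairs for the PCA batch test")
    if not matrix.is_complete:
        raise EvaluationError("PCA batch test needs a complete matrix")
    # batch membership of the selected columns is positional: the first
    # element of each pair is the batch-1 copy (batch_labels kept for
    # signature compatibility / future multi-batch layouts)
    b1_ids = [p[0] for p in common_pairs]
    b2_ids = [p[1] for p in common_pairs]
    sub = matrix.subset_columns(b1_ids + b2_ids)
    X = sub.values.T  # samples x miRNAs
    X = X - X.mean(axis=0, keepdims=True)  # per-miRNA centering
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    group = np.array([0] * len(b1_ids) + [1] * len(b2_ids))
    pvals = []
    for comp in range(2):
        s1, s2 = scores[group == 0, comp], scores[group == 1, comp]
        if np.allclose(s1.var() + s2.var(), 0.0) or np.allclose(s1, s2):
            pvals.append(1.0)
            continue
        t = stats.ttest_ind(s1, s2, equal_var=False)
        pvals.append(1.0 if np.isnan(t.pvalue) else float(t.pvalue))
    return BatchEffectResult(
        p_pc1=pvals[0],
        p_pc2=pvals[1],
        variance_explained=tuple(pca.explained_variance_ratio_[:2]),
        checkpoint=checkpoint,
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise EvaluationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Tidy per-pipeline metric tables.

    ``agreement``: one row per pipeline x checkpoint x NA rate (ICC, CI,
    p, adjusted p, RMSE, NRMSE, unit count, status).
    ``batch``: one row per pipeline x checkpoint x component (raw and
    BH-adjusted t-test p, variance explained).
    ``failures``: pipeline ids that could not be evaluated, with reasons.
    """

    agreement: pd.DataFrame
    batch: pd.DataFrame
    failures: dict[int, str] = field(default_factory=dict)

    def to_csv(self, agreement_path, batch_path) -> None:
        self.agreement.to_csv(agreement_path, index=False)
        self.batch.to_csv(batch_path, index=False)

    def to_json(self) -> str:
        import json

        def _default(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        return json.dumps(
            {
                "agreement": self.agreement.to_dict(orient="records"),
                "batch": self.batch.to_dict(orient="records"),
                "failures": {str(k): v for k, v in self.failures.items()},
            },
            default=_default,
        )


def plot_report(report: EvaluationReport, path, checkpoint: str = "checkpoint3"):
    """Bar-chart summary of a report (optional; needs matplotlib).

    Three panels: ICC per pipeline for each NA-rate subset (with CI bars)
    and the PC1 adjusted p-values before/after batch correction.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agr = report.agreement[report.agreement.checkpoint == checkpoint]
    fig, axes = plt.subplots(3, 1, figsize=(10, 10), constrained_layout=True)
    for ax, rate, title in zip(
        axes[:2], (0.5, 0.0), ("imputed miRNAs (NA rate 0.5)", "measured miRNAs (NA rate 0)")
    ):
        sub = agr[agr.na_rate == rate].sort_values("pipeline_id")
        err = np.vstack(
            [sub.icc - sub.ci_low, sub.ci_high - sub.icc]
        ).clip(min=0)
        ax.bar(sub.pipeline_id.astype(str), sub.icc, yerr=err, color="0.5")
        ax.set_ylabel("ICC(2,1)")
        ax.set_title(f"Agreement, {title}")
        ax.axhline(0, color="k", lw=0.5)
    pc1 = report.batch[report.batch.component == "PC1"]
    width = 0.4
    for off, cp, color in ((-width / 2, "checkpoint2", "0.2"), (width / 2, "checkpoint3", "0.7")):
        sub = pc1[pc1.checkpoint == cp].sort_values("pipeline_id")
        axes[2].bar(
            sub.pipeline_id.to_numpy() + off, -np.log10(sub.adj_p_value.clip(lower=1e-16)),
            width=width, color=color, label=cp,
        )
    axes[2].axhline(-np.log10(0.05), color="k", ls="--", lw=0.8)
    axes[2].set_xlabel("pipeline")
    axes[2].set_ylabel("-log10 adjusted p (PC1)")
    axes[2].set_title("Batch effect before/after correction")
    axes[2].legend()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def evaluate_study(
    runs,
    common_pairs: list[tuple[str, str]],
    agreement_checkpoints: tuple[str, ...] = ("checkpoint3",),
    batch_checkpoints: tuple[str, ...] = ("checkpoint2", "checkpoint3"),
) -> EvaluationReport:
    """Score every pipeline run: agreement at NA rates 0.5 and 0, and PCA
    batch tests, with BH adjustment within each metric family.

    ICC p-values are adjusted across pipelines within each (checkpoint,
    NA-rate) family; PC p-values jointly across pipelines x components x
    checkpoints.  Failed runs are recorded, not fatal.
    """
    agreement_rows: list[dict] = []
    batch_rows: list[dict] = []
    failures: dict[int, str] = {}

    for run in runs:
        if not hasattr(run, "snapshots"):  # a recorded failure from run_all
            failures[getattr(run, "pipeline_id", -1)] = str(
                getattr(run, "error", "unknown failure")
            )
            continue
        pid = run.spec.pipeline_id
        sample_ids = run.sample_ids
        try:
            subsets = {
                rate: extract_pair_subsets(run.premask, sample_ids, common_pairs, rate)
                for rate in (0.5, 0.0)
            }
            for cp in agreement_checkpoints:
                snap = run.snapshots[cp]
                for rate in (0.5, 0.0):
                    paired = paired_from_matrix(snap, common_pairs, subsets[rate])
                    row = {
                        "pipeline_id": pid,
                        "checkpoint": cp,
                        "na_rate": rate,
                        "n_total": paired.n_total,
                    }
                    if paired.n_total < 2:
                        row.update(
                            status="not_applicable",
                            icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                            p_value=np.nan, rmse=np.nan, nrmse=np.nan,
                        )
                    else:
                        res, _ = agreement(paired)
                        row.update(
                            status="ok",
                            icc=res.icc, ci_low=res.ci_low, ci_high=res.ci_high,
                            p_value=res.p_value, rmse=res.rmse, nrmse=res.nrmse,
                        )
                    agreement_rows.append(row)
            for cp in batch_checkpoints:
                res = pca_batch_test(run.snapshots[cp], common_pairs, checkpoint=cp)
                for comp, p, ve in (
                    ("PC1", res.p_pc1, res.variance_explained[0]),
                    ("PC2", res.p_pc2, res.variance_explained[1]),
                ):
                    batch_rows.append(
                        {
                            "pipeline_id": pid,
                            "checkpoint": cp,
                            "component": comp,
                            "p_value": p,
                            "variance_explained": ve,
                        }
                    )
        except EvaluationError as exc:
            failures[pid] = str(exc)

    agreement_df = pd.DataFrame(agreement_rows)
    batch_df = pd.DataFrame(batch_rows)
    if not agreement_df.empty:
        agreement_df["adj_p_value"] = np.nan
        for (_, _), idx in agreement_df.groupby(["checkpoint", "na_rate"]).groups.items():
            ok = agreement_df.loc[idx, "p_value"].notna()
            rows = agreement_df.loc[idx][ok].index
            if len(rows):
                agreement_df.loc[rows, "adj_p_value"] = adjust_bh(
                    agreement_df.loc[rows, "p_value"].to_numpy()
                )
    if not batch_df.empty:
        batch_df["adj_p_value"] = adjust_bh(batch_df["p_value"].to_numpy())
    return EvaluationReport(agreement=agreement_df, batch=batch_df, failures=failures)
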