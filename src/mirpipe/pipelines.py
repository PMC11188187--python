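"""The 18 preprocessing pipelines as declarative stage sequences.

Each pipeline is an ordered list of stages over one of the two QC outputs
(the converted-value matrix, or the BG-subtraction matrix for the
smallest-positive replacement pair), always ending in batch correction.
Three checkpoints are recorded: after the imputation/replacement stage
(checkpoint 1), after the last pre-correction stage (checkpoint 2) and
after batch correction (checkpoint 3).  The pre-imputation missingness mask
(``premask``) is retained so evaluation can split (pair, miRNA) units by
their original NA rate.

Stage vocabulary: ``global_median``, ``constant``,
``replace_neg_smallest_pos``, ``log2``, ``pct75``, ``quantile``,
``sample_min``, ``rf_impute``, ``knn``, ``em``, ``combat``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import combat as combat_mod
from . import impute, normalize
from .errors import MirpipeError, PipelineError
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

SOURCE_CONVERTED = "converted"
SOURCE_BG_SUBTRACTION = "bg_subtraction"

IMPUTATION_KINDS = frozenset(
    {"constant", "replace_neg_smallest_pos", "sample_min", "rf_impute", "knn", "em"}
)
STOCHASTIC_KINDS = frozenset({"rf_impute", "em"})


@dataclass(frozen=True)
class Stage:
    kind: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineSpec:
    """One pipeline: a source matrix, ordered stages, checkpoint indices."""

    pipeline_id: int
    source: str
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.stages]
        if kinds.count("combat") != 1 or kinds[-1] != "combat":
            raise PipelineError(
                "a pipeline must contain exactly one batch-correction stage, last",
                pipeline_id=self.pipeline_id,
            )
        n_imp = sum(k in IMPUTATION_KINDS for k in kinds)
        if n_imp != 1:
            raise PipelineError(
                f"a pipeline must contain exactly one imputation/replacement stage, got {n_imp}",
                pipeline_id=self.pipeline_id,
            )
        if self.source not in (SOURCE_CONVERTED, SOURCE_BG_SUBTRACTION):
            raise PipelineError(
                f"unknown source {self.source!r}", pipeline_id=self.pipeline_id
            )

    @property
    def imputation_index(self) -> int:
        return next(
            i for i, s in enumerate(self.stages) if s.kind in IMPUTATION_KINDS
        )

    @property
    def checkpoint_after(self) -> dict[str, int]:
        return {
            "checkpoint1": self.imputation_index,
            "checkpoint2": len(self.stages) - 2,
            "checkpoint3": len(self.stages) - 1,
        }

    @property
    def stage_kinds(self) -> list[str]:
        return [s.kind for s in self.stages]


@dataclass
class PipelineRun:
    """Executed pipeline: checkpoint snapshots plus the pre-imputation mask."""

    spec: PipelineSpec
    snapshots: dict[str, ExpressionMatrix]
    premask: np.ndarray
    sample_ids: list[str]
    seed: int


@dataclass
class PipelineFailure:
    pipeline_id: int
    error: str


def builtin_pipelines(p34_global_median: bool = False) -> list[PipelineSpec]:
    """The 18 built-in pipelines.

    ``p34_global_median`` prepends the global median-to-25 scaling to
    pipelines 3 and 4 (an alternative reading of their step list; by default
    the forest imputation replaces that step entirely).
    """
    gm = Stage("global_median", {"target": 25.0})
    c1 = Stage("constant", {"value": 1.0})
    rf = Stage("rf_impute", {})
    neg = Stage("replace_neg_smallest_pos", {})
    lg = Stage("log2", {})
    p75 = Stage("pct75", {})
    qn = Stage("quantile", {})
    smin = Stage("sample_min", {})
    knn = Stage("knn", {"k": 10, "max_missing": 0.95})
    em = Stage("em", {"m": 1})
    cb = Stage("combat", {})

    p34_prefix = (gm,) if p34_global_median else ()
    layout: dict[int, tuple[str, tuple[Stage, ...]]] = {
        1: (SOURCE_CONVERTED, (gm, c1, lg, p75, cb)),
        2: (SOURCE_CONVERTED, (gm, c1, lg, qn, cb)),
        3: (SOURCE_CONVERTED, p34_prefix + (rf, lg, p75, cb)),
        4: (SOURCE_CONVERTED, p34_prefix + (rf, lg, qn, cb)),
        5: (SOURCE_BG_SUBTRACTION, (neg, lg, p75, cb)),
        6: (SOURCE_BG_SUBTRACTION, (neg, lg, qn, cb)),
        7: (SOURCE_CONVERTED, (lg, p75, smin, cb)),
        8: (SOURCE_CONVERTED, (lg, qn, smin, cb)),
        9: (SOURCE_CONVERTED, (lg, p75, rf, cb)),
        10: (SOURCE_CONVERTED, (lg, qn, rf, cb)),
        11: (SOURCE_CONVERTED, (lg, p75, knn, cb)),
        12: (SOURCE_CONVERTED, (lg, qn, knn, cb)),
        13: (SOURCE_CONVERTED, (lg, knn, p75, cb)),
        14: (SOURCE_CONVERTED, (lg, knn, qn, cb)),
        15: (SOURCE_CONVERTED, (lg, p75, em, cb)),
        16: (SOURCE_CONVERTED, (lg, qn, em, cb)),
        17: (SOURCE_CONVERTED, (lg, em, p75, cb)),
        18: (SOURCE_CONVERTED, (lg, em, qn, cb)),
    }
    return [
        PipelineSpec(pid, source, stages) for pid, (source, stages) in layout.items()
    ]


def _execute_stage(
    stage: Stage, matrix: ExpressionMatrix, seed: int
) -> ExpressionMatrix:
    p = stage.params
    if stage.kind == "global_median":
        return normalize.global_median_normalize(matrix, target=p.get("target", 25.0))
    if stage.kind == "constant":
        return impute.impute_constant(matrix, value=p.get("value", 1.0))
    if stage.kind == "replace_neg_smallest_pos":
        return impute.replace_negative_with_smallest_positive(matrix)
    if stage.kind == "log2":
        return normalize.log2_transform(matrix)
    if stage.kind == "pct75":
        return normalize.percentile75_normalize(matrix)
    if stage.kind == "quantile":
        return normalize.quantile_normalize(matrix)
    if stage.kind == "sample_min":
        return impute.impute_sample_minimum(matrix)
    if stage.kind == "rf_impute":
        params = impute.RfParams(
            n_trees=p.get("n_trees", 100),
            max_iter=p.get("max_iter", 10),
            seed=seed,
        )
        return impute.impute_rf_iterative(matrix, params)
    if stage.kind == "knn":
        params = impute.KnnParams(
            k=p.get("k", 10), max_missing=p.get("max_missing", 0.95)
        )
        return impute.impute_knn(matrix, params)
    if stage.kind == "em":
        params = impute.EmParams(
            m=p.get("m", 1),
            max_iter=p.get("max_iter", 100),
            tol=p.get("tol", 1e-4),
            ridge=p.get("ridge", 1e-6),
            seed=seed,
            draw_mode=p.get("draw_mode", "conditional_mean"),
        )
        return impute.impute_em(matrix, params)
    if stage.kind == "combat":
        corrected, _ = combat_mod.combat_fit_transform(
            matrix,
            max_iter=p.get("max_iter", 100),
            tol=p.get("tol", 1e-4),
        )
        return corrected
    raise PipelineError(f"unknown stage kind {stage.kind!r}")


def stage_seed(master_seed: int, pipeline_id: int, stage_index: int) -> int:
    """Deterministic per-(pipeline, stage) seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(pipeline_id, stage_index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    spec: PipelineSpec,
    converted: ExpressionMatrix,
    bg_subtraction: ExpressionMatrix,
    seed: int = 0,
) -> PipelineRun:
    """Execute one pipeline on the QC'd matrix pair; capture the three
    checkpoint snapshots and the pre-imputation mask."""
    matrix = (
        converted if spec.source == SOURCE_CONVERTED else bg_subtraction
    ).copy()
    premask = matrix.mask.copy()
    snapshots: dict[str, ExpressionMatrix] = {}
    for idx, stage in enumerate(spec.stages):
        try:
            matrix = _execute_stage(
                stage, matrix, stage_seed(seed, spec.pipeline_id, idx)
            )
        except MirpipeError as exc:
            raise PipelineError(
                f"pipeline {spec.pipeline_id} stage {idx} ({stage.kind}): {exc}",
                pipeline_id=spec.pipeline_id,
                stage_index=idx,
            ) from exc
        # one stage may carry several checkpoints (e.g. imputation last
        # before correction: checkpoint 1 == checkpoint 2)
        for cp, cp_idx in spec.checkpoint_after.items():
            if cp_idx == idx:
                snapshots[cp] = matrix.copy()
    return PipelineRun(
        spec=spec,
        snapshots=snapshots,
        premask=premask,
        sample_ids=list(matrix.sample_ids),
        seed=seed,
    )


def run_all(
    specs: list[PipelineSpec],
    converted: ExpressionMatrix,
    bg_subtraction: ExpressionMatrix,
    seed: int = 0,
) -> list[PipelineRun | PipelineFailure]:
    """Run every spec with per-pipeline derived seeds; collect failures
    without aborting the batch."""
    out: list[PipelineRun | PipelineFailure] = []
    for spec in specs:
        try:
            out.append(run_pipeline(spec, converted, bg_subtraction, seed))
        except MirpipeError as exc:
            log.warning("pipeline %d failed: %s", spec.pipeline_id, exc)
            out.append(PipelineFailure(pipeline_id=spec.pipeline_id, error=str(exc)))
    return out


# ---------------------------------------------------------------------------
# plain-text (de)serialization of pipeline specs
# ---------------------------------------------------------------------------


def specs_to_text(specs: list[PipelineSpec]) -> str:
    payload = {
        str(s.pipeline_id): {
            "source": s.source,
            "stages": [{"kind": st.kind, "params": st.params} for st in s.stages],
        }
        for s in specs
    }
    return json.dumps(payload, indent=2)


def specs_from_text(text: str) -> list[PipelineSpec]:
    payload = json.loads(text)
    specs = []
    for pid, entry in payload.items():
        stages = tuple(
            Stage(st["kind"], dict(st.get("params", {}))) for st in entry["stages"]
        )
        specs.append(PipelineSpec(int(pid), entry["source"], stages))
    return specs
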