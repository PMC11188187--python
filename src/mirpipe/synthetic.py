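"""Synthetic two-batch miRNA microarray studies with known ground truth.

The generator emulates the data shape of a two-cohort 3D-Gene-style study:
right-skewed per-sample signal distributions (log-normal latent abundances),
BLANK spots defining an optical background, detection-limit missingness
(signals at or below background mean + 2 SD are unreliable, so missingness
is MNAR and concentrates at low abundance), two batches sharing a set of
common samples, and a location/scale batch effect on the log signal — the
mechanism an empirical-Bayes location/scale correction can fully remove.

Model, per miRNA j and sample entity e:

    truth[j, e]   = a_j + s_e                      (noise-free log2 abundance)
    a_j ~ N(latent_log_mean, latent_log_sd^2)      shared between batches
    s_e ~ N(0, sample_scale_sd^2)                  per-entity scale factor
    x   = truth + batch2_shift·[batch 2] + eps     per-spot log2 signal
    eps ~ N(0, (noise_sd · batch2_scale^[batch 2])^2)
    signal = bg_level + 2^x                        raw fluorescence
    BLANK spots ~ N(bg_level, bg_sd^2) clipped at 0

Common samples appear once per batch but share one truth column.  "NG"
scanner flags are assigned independently of signal at rate ``ng_rate``;
detection-limit masking is the only MNAR mechanism.

Default sizes are desk scale: 300 miRNAs, 12 blanks, batches of 28 and 47
with 10 common samples.  The abundance/noise defaults are calibrated so the
per-common-pair fractions of miRNAs missing in exactly one batch (~0.19)
and observed in both (~0.33, both relative to all probes) match the study
conditions this package benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluate import PairedValues
from .qc import CLASS_BLANK, CLASS_PROBE, FLAG_NG, FLAG_PASS, RawArray, Spot


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the two-batch study generator (defaults = study conditions)."""

    n_mirnas: int = 300
    n_blank_spots: int = 12
    n_batch1: int = 28
    n_batch2: int = 47
    n_common: int = 10
    latent_log_mean: float = 3.7
    latent_log_sd: float = 4.0
    sample_scale_sd: float = 0.5
    batch2_shift: float = 2.0
    batch2_scale: float = 1.5
    noise_sd: float = 0.6
    bg_level: float = 100.0
    bg_sd: float = 20.0
    ng_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 2:
            raise ConfigurationError("n_mirnas must be >= 2")
        if self.n_blank_spots < 2:
            raise ConfigurationError("n_blank_spots must be >= 2")
        for name in ("n_batch1", "n_batch2"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_common < 0 or self.n_common > min(self.n_batch1, self.n_batch2):
            raise ConfigurationError(
                "n_common must satisfy 0 <= n_common <= min(n_batch1, n_batch2)"
            )
        for name in (
            "latent_log_sd",
            "sample_scale_sd",
            "batch2_scale",
            "noise_sd",
            "bg_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.ng_rate <= 1.0:
            raise ConfigurationError("ng_rate must be in [0, 1]")


@dataclass
class RawStudy:
    """A generated two-batch study plus its latent ground truth.

    ``truth`` holds noise-free log2 abundances over sample *entities*; common
    samples of the two batches map to the same entity column via
    ``entity_of``.
    """

    config: GeneratorConfig
    batch1_arrays: list[RawArray]
    batch2_arrays: list[RawArray]
    common_pairs: list[tuple[str, str]]
    truth: pd.DataFrame
    entity_of: dict[str, str] = field(default_factory=dict)

    @property
    def arrays(self) -> list[RawArray]:
        return self.batch1_arrays + self.batch2_arrays

    @property
    def batch_of(self) -> dict[str, str]:
        out = {a.sample_id: "1" for a in self.batch1_arrays}
        out.update({a.sample_id: "2" for a in self.batch2_arrays})
        return out


def _make_array(
    sample_id: str,
    mirna_ids: list[str],
    log_signal: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> RawArray:
    signal = cfg.bg_level + np.exp2(log_signal)
    ng = rng.random(len(mirna_ids)) < cfg.ng_rate
    spots = [
        Spot(mid, float(sig), FLAG_NG if bad else FLAG_PASS, CLASS_PROBE)
        for mid, sig, bad in zip(mirna_ids, signal, ng)
    ]
    blanks = np.clip(
        rng.normal(cfg.bg_level, cfg.bg_sd, cfg.n_blank_spots), 0.0, None
    )
    spots += [
        Spot(f"BLANK_{i + 1:03d}", float(b), FLAG_PASS, CLASS_BLANK)
        for i, b in enumerate(blanks)
    ]
    return RawArray(sample_id=sample_id, spots=spots)


def generate_two_batch_study(config: GeneratorConfig) -> RawStudy:
    """Draw one seeded two-batch raw study; identical config => identical output."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    # entities: common ones first, then batch-1-only, then batch-2-only
    n_entities = cfg.n_common + (cfg.n_batch1 - cfg.n_common) + (cfg.n_batch2 - cfg.n_common)
    entity_ids = [f"E{i + 1:03d}" for i in range(n_entities)]

    latent = rng.normal(cfg.latent_log_mean, cfg.latent_log_sd, cfg.n_mirnas)
    sample_factor = rng.normal(0.0, cfg.sample_scale_sd, n_entities)
    truth_values = latent[:, None] + sample_factor[None, :]
    truth = pd.DataFrame(truth_values, index=mirna_ids, columns=entity_ids)

    # entity assignment per physical sample
    b1_entities = entity_ids[: cfg.n_common] + entity_ids[
        cfg.n_common : cfg.n_batch1
    ]
    b2_entities = entity_ids[: cfg.n_common] + entity_ids[
        cfg.n_batch1 : cfg.n_batch1 + (cfg.n_batch2 - cfg.n_common)
    ]
    b1_ids = [f"B1_S{i + 1:03d}" for i in range(cfg.n_batch1)]
    b2_ids = [f"B2_S{i + 1:03d}" for i in range(cfg.n_batch2)]
    entity_of = dict(zip(b1_ids, b1_entities)) | dict(zip(b2_ids, b2_entities))

    batch1_arrays, batch2_arrays = [], []
    for sid, ent in zip(b1_ids, b1_entities):
        eps = rng.normal(0.0, cfg.noise_sd, cfg.n_mirnas)
        x = truth[ent].to_numpy() + eps
        batch1_arrays.append(_make_array(sid, mirna_ids, x, cfg, rng))
    for sid, ent in zip(b2_ids, b2_entities):
        eps = rng.normal(0.0, cfg.noise_sd * cfg.batch2_scale, cfg.n_mirnas)
        x = truth[ent].to_numpy() + cfg.batch2_shift + eps
        batch2_arrays.append(_make_array(sid, mirna_ids, x, cfg, rng))

    common_pairs = [(b1_ids[i], b2_ids[i]) for i in range(cfg.n_common)]
    return RawStudy(
        config=cfg,
        batch1_arrays=batch1_arrays,
        batch2_arrays=batch2_arrays,
        common_pairs=common_pairs,
        truth=truth,
        entity_of=entity_of,
    )


def truth_for_pairs(study: RawStudy) -> PairedValues:
    """Latent log2 abundances aligned over each common pair.

    Both batch copies of a common sample share one truth column, so the two
    vectors of every pair are identical — the noise-free oracle against which
    imputation accuracy is judged.
    """
    if not study.common_pairs:
        raise ConfigurationError("study has no common pairs")
    pairs = []
    for b1_id, b2_id in study.common_pairs:
        col = study.truth[study.entity_of[b1_id]].to_numpy()
        col2 = study.truth[study.entity_of[b2_id]].to_numpy()
        pairs.append((col.copy(), col2.copy()))
    return PairedValues(pairs=pairs)
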