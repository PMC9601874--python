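"""End-to-end heartbeat classification pipeline.

Given a designated standard normal beat T_s and a batch of beats, the
pipeline (1) embeds T_s, builds its SPD cloud and curvature sequence, and
fixes the histogram ceiling ``b = min(max curvature of T_s, 3 d (d-1) /
epsilon)`` once; then (2) for every beat runs embed -> kNN scatter cloud ->
scalar curvatures -> histogram -> dispersion -> domain classification.  A
failure in any stage flags that beat as unclassifiable with a reason and
never aborts the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify as _classify
from .embed import EmbedConfig, embed_beat
from .features import DispersionPoint, choose_b, dispersion, histogram, wsc_sequence
from .localstats import spd_cloud
from .preprocess import Beat

__all__ = ["PipelineConfig", "BeatResult", "PipelineResult", "run_wscec"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the classification pipeline (printed defaults)."""

    l: int = 10
    tau: int = 1
    d: int = 3
    k: int = 20
    m: float = 1.0
    s: int = 0
    epsilon: float = 0.09
    embed_scale: float | None = None   # None -> 2/l
    eig_floor: float | None = None     # None -> relative default
    knn_include_self: bool = False
    partition: _classify.DomainPartition | None = None

    def embed_config(self) -> EmbedConfig:
        return EmbedConfig(l=self.l, tau=self.tau, d=self.d, scale=self.embed_scale)


@dataclass(frozen=True)
class BeatResult:
    beat_id: int
    label: str | None
    dispersion: DispersionPoint
    diagnosis: _classify.Diagnosis
    n_points: int
    n_regularized: int
    n_excluded: int
    error: str = ""


@dataclass(frozen=True)
class PipelineResult:
    b: float
    config: PipelineConfig
    results: list[BeatResult]

    def feature_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "beat_id": r.beat_id,
                    "label": r.label,
                    "cur1": r.dispersion.cur1,
                    "cur2": r.dispersion.cur2,
                    "coarse": r.diagnosis.coarse,
                    "fine": r.diagnosis.fine,
                    "n_points": r.n_points,
                    "n_regularized": r.n_regularized,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)

    def counts(self) -> dict[str, int]:
        """Beats per coarse outcome; failed beats count as unclassified."""
        out = {c: 0 for c in _classify.COARSE_CLASSES}
        for r in self.results:
            out[r.diagnosis.coarse] += 1
        return out


def _beat_samples(beat) -> np.ndarray:
    return beat.samples if isinstance(beat, Beat) else np.asarray(beat, dtype=float)


def _beat_label(beat) -> str | None:
    return beat.label if isinstance(beat, Beat) else None


def beat_curvatures(samples: np.ndarray, config: PipelineConfig
                    ) -> tuple[np.ndarray, int]:
    """Curvature sequence of one beat plus the regularisation count."""
    cloud = embed_beat(samples, config.embed_config())
    spd = spd_cloud(cloud, k=config.k, eig_floor=config.eig_floor,
                    include_self=config.knn_include_self)
    return wsc_sequence(spd.matrices), spd.n_regularized


def run_wscec(beats, standard_beat, config: PipelineConfig | None = None
              ) -> PipelineResult:
    """Classify a batch of beats against a standard normal beat.

    ``beats`` is a sequence of :class:`~wscec.preprocess.Beat` or plain
    sample arrays; ``standard_beat`` likewise.  Returns per-beat dispersion
    points, diagnoses and bookkeeping counts.
    """
    config = config or PipelineConfig()
    partition = config.partition or _classify.DomainPartition.default()

    std_curv, _ = beat_curvatures(_beat_samples(standard_beat), config)
    b = choose_b(std_curv, config.epsilon, config.d)
    logger.info("histogram ceiling b = %.4g (from %d standard curvatures)",
                b, std_curv.size)

    results: list[BeatResult] = []
    for beat_id, beat in enumerate(beats):
        label = _beat_label(beat)
        try:
            curv, n_reg = beat_curvatures(_beat_samples(beat), config)
            H = histogram(curv, config.m, b)
            disp = dispersion(curv, H, config.s)
            if disp.valid:
                diag = _classify.classify_point((disp.cur1, disp.cur2), partition)
                err = ""
            else:
                diag = _classify.Diagnosis("unclassified")
                err = disp.reason
            results.append(
                BeatResult(beat_id, label, disp, diag, curv.size, n_reg,
                           H.n_excluded, err)
            )
        except Exception as exc:  # noqa: BLE001 - one bad beat must not kill the batch
            logger.warning("beat %d failed: %s", beat_id, exc)
            results.append(
                BeatResult(
                    beat_id, label,
                    DispersionPoint(np.nan, np.nan, valid=False, reason=str(exc)),
                    _classify.Diagnosis("unclassified"),
                    0, 0, 0, error=str(exc),
                )
            )
    return PipelineResult(b=float(b), config=config, results=results)
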