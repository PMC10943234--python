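"""Posterior thresholding, freezing bouts, motor activity, session summaries.

A frame qualifies as freezing-candidate when its posterior probability
of membership in the freezing component is at least 0.95 *and* its
similarity score is not anomalously low under a Tukey quartile
criterion.  Any run of 90 or more consecutive qualifying
frames (3 s at 30 fps) is a freezing bout; shorter stillness is not
freezing.  A 4-s freeze, movement, then a 10-s freeze therefore counts
as two bouts of 4 s and 10 s.

Two quantile-rule variants are provided and the configuration records
which one ran:

* ``"tukey_fence"`` (default): scores must stay above the trace's
  lower Tukey fence, ``Q1 - k * IQR`` (k = 1.5), with the quartiles
  taken from the denoised similarity scores themselves — the textbook
  application of Tukey's boxplot rule.  During sustained stillness
  virtually every frame passes, so the 90-frame rule can fire; the
  fence rejects anomalous dips (artifacts) the denoiser missed.
* ``"upper_quartile"``: scores must lie in the freezing component's
  rightmost quarter (``>= mu_f + z(0.75) * sd_f``).  This stricter cut
  flags only the stillest quarter of freezing-like frames, so with
  per-frame noise it essentially never yields a 90-frame run; it is
  kept as an explicit variant, not the default.

*Motor activity* is the sum over the session of each score's posterior
probability of membership in the motion component — an objective,
unitless measure of how much the animal moved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError, ConsistencyError, InputError
from .mixture import MixtureModel
from .trace import SimilarityTrace

__all__ = [
    "PosteriorTrace",
    "BoutConfig",
    "FreezingBout",
    "SessionSummary",
    "qualifying_frames",
    "detect_bouts",
    "motor_activity",
    "summarize_session",
    "bouts_to_mask",
    "bout_table",
]


@dataclass
class PosteriorTrace:
    """Per-score posterior probabilities for (motion, ambiguous, freezing)."""

    probs: np.ndarray  # (n, 3), columns in COMPONENT_LABELS order
    fps: float = 30.0
    source_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise InputError("probs must have shape (n, 3)")
        if np.any(~np.isfinite(self.probs)):
            raise InputError("posteriors must be finite")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise InputError("each posterior triple must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def motion(self) -> np.ndarray:
        return self.probs[:, 0]

    @property
    def ambiguous(self) -> np.ndarray:
        return self.probs[:, 1]

    @property
    def freezing(self) -> np.ndarray:
        return self.probs[:, 2]


@dataclass(frozen=True)
class BoutConfig:
    """Bout-detection parameters.

    min_bout_frames : minimum run length of qualifying frames
        (default 90 = 3 s at 30 fps).
    posterior_threshold : minimum freezing-membership posterior
        (default 0.95).
    freezing_quantile : quantile defining the freezing component's
        upper quartile Q3 (default 0.75); Q1 is its mirror.
    tukey_k : fence multiplier for the default anomaly cut
        (default 1.5).
    quantile_rule : "tukey_fence" (default) or "upper_quartile";
        recorded in every output sidecar.
    """

    min_bout_frames: int = 90
    posterior_threshold: float = 0.95
    freezing_quantile: float = 0.75
    tukey_k: float = 1.5
    quantile_rule: str = "tukey_fence"

    def __post_init__(self):
        if self.min_bout_frames < 1:
            raise ConfigError("min_bout_frames must be >= 1")
        for name in ("posterior_threshold", "freezing_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.quantile_rule not in ("tukey_fence", "upper_quartile"):
            raise ConfigError(
                f"unknown quantile_rule {self.quantile_rule!r}"
            )


@dataclass(frozen=True)
class FreezingBout:
    """One maximal freezing run, in score indices (end inclusive)."""

    start_index: int
    end_index: int
    fps: float = 30.0

    def __post_init__(self):
        if self.end_index < self.start_index:
            raise InputError("bout end must be >= start")

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def start_s(self) -> float:
        return self.start_index / self.fps


@dataclass(frozen=True)
class SessionSummary:
    """Per-session behavioral aggregates."""

    total_freezing_s: float
    n_bouts: int
    mean_bout_s: float
    motor_activity: float
    freezing_fraction: float
    source_id: str = ""


def score_cutoff(
    model: MixtureModel, cfg: BoutConfig, scores: np.ndarray | None = None
) -> float:
    """Similarity-score cut implied by the configured quantile rule.

    ``"tukey_fence"`` needs the denoised scores (fence from the data
    quartiles); ``"upper_quartile"`` needs only the fitted freezing
    component.
    """
    if cfg.quantile_rule == "upper_quartile":
        _, mu_f, sd_f = model.component("freezing")
        zq = float(norm.ppf(cfg.freezing_quantile))  # ~0.6745 at 0.75
        return mu_f + zq * sd_f
    if scores is None:
        raise InputError("the tukey_fence rule needs the trace scores")
    q3 = float(np.quantile(scores, cfg.freezing_quantile))
    q1 = float(np.quantile(scores, 1.0 - cfg.freezing_quantile))
    return q1 - cfg.tukey_k * (q3 - q1)


def qualifying_frames(
    post: PosteriorTrace,
    model: MixtureModel,
    trace: SimilarityTrace,
    cfg: BoutConfig | None = None,
) -> np.ndarray:
    """Boolean flag per score: freezing posterior >= threshold AND the
    score passes the configured freezing-component quantile cut."""
    cfg = cfg or BoutConfig()
    scores = trace.scores if isinstance(trace, SimilarityTrace) else np.asarray(trace)
    if len(post) != scores.size:
        raise InputError(
            f"posterior length {len(post)} != trace length {scores.size}"
        )
    cut = score_cutoff(model, cfg, scores)
    return (post.freezing >= cfg.posterior_threshold) & (scores >= cut)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop_exclusive)."""
    f = np.asarray(flags, dtype=bool).astype(np.int8)
    d = np.diff(np.concatenate([[0], f, [0]]))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_bouts(
    flags: Sequence[bool] | np.ndarray,
    fps: float,
    cfg: BoutConfig | None = None,
) -> list[FreezingBout]:
    """Turn qualifying-frame flags into freezing bouts.

    Each maximal run of True flags of length >= min_bout_frames becomes
    one bout; shorter runs are ignored; any False flag separates runs.
    """
    cfg = cfg or BoutConfig()
    if not fps > 0:
        raise InputError("fps must be positive")
    bouts = [
        FreezingBout(start, stop - 1, fps=fps)
        for start, stop in _runs(np.asarray(flags))
        if stop - start >= cfg.min_bout_frames
    ]
    return bouts


def motor_activity(post: PosteriorTrace) -> float:
    """Sum over scores of the motion-membership posterior."""
    return float(post.motion.sum())


def _check_disjoint(bouts: Sequence[FreezingBout], n_scores: int) -> None:
    prev_end = -1
    for b in sorted(bouts, key=lambda b: b.start_index):
        if b.start_index <= prev_end:
            raise ConsistencyError("bouts overlap")
        if b.start_index < 0 or b.end_index >= n_scores:
            raise ConsistencyError("bout extends beyond trace bounds")
        prev_end = b.end_index


def summarize_session(
    bouts: Sequence[FreezingBout],
    post: PosteriorTrace,
) -> SessionSummary:
    """Aggregate bouts + posteriors into the session summary."""
    n = len(post)
    _check_disjoint(bouts, n)
    total = float(sum(b.duration_s for b in bouts))
    n_bouts = len(bouts)
    inside = sum(b.n_frames for b in bouts)
    return SessionSummary(
        total_freezing_s=total,
        n_bouts=n_bouts,
        mean_bout_s=total / n_bouts if n_bouts else 0.0,
        motor_activity=motor_activity(post),
        freezing_fraction=inside / n if n else 0.0,
        source_id=post.source_id,
    )


def bouts_to_mask(bouts: Sequence[FreezingBout], n_scores: int) -> np.ndarray:
    """Boolean per-score mask: True inside any freezing bout."""
    mask = np.zeros(n_scores, dtype=bool)
    for b in bouts:
        mask[b.start_index : b.end_index + 1] = True
    return mask


def bout_table(bouts: Sequence[FreezingBout], source_id: str = ""):
    """Bouts as a pandas DataFrame in the package's CSV dialect."""
    import pandas as pd

    rows = [
        {
            "source_id": source_id,
            "bout_index": i,
            "start_frame": b.start_index,
            "end_frame": b.end_index,
            "start_s": b.start_s,
            "duration_s": b.duration_s,
        }
        for i, b in enumerate(bouts)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "bout_index",
            "start_frame",
            "end_frame",
            "start_s",
            "duration_s",
        ],
    )
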