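"""Ground-truthed synthetic sessions, at two levels of realism.

Every downstream module is testable without any recorded video thanks
to two seeded generators that share a common behavioral schedule:

* :func:`render_session` draws actual frames: a bright blob (the
  subject) over a static textured background with i.i.d. sensor noise.
  The blob barely moves while freezing (residual micro-motion — the
  behavioral definition of freezing permits slow head movements, and a
  perfectly static subject would produce a degenerate zero-width score
  pile no real recording shows), drifts at a slow sustained speed in
  the ambiguous state, and travels faster with a wandering heading
  while in motion, so the similarity trace computed from the frames is
  trimodal for the same physical reason real cage video is.
* :func:`simulate_trace` skips rendering and draws each score directly
  from a per-state truncated Gaussian, which makes 10^4–10^5-score
  statistical tests cheap while matching the distributional family the
  mixture model assumes.

The schedule is a semi-Markov alternation over the three behavioral
states with exponential dwell times (freezing dwells floored at 3 s so
every ground-truth freezing interval is detectable in principle).
Score ``i`` spans frames ``(i, i+1)`` and blob displacement is applied
on entering a frame, so a score's ground-truth state is the state of
the *later* frame of its pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .errors import InputError
from .trace import FrameSequence, SimilarityTrace

__all__ = [
    "STATES",
    "STATE_CODES",
    "GroundTruthSchedule",
    "SceneConfig",
    "sample_schedule",
    "render_session",
    "simulate_trace",
    "DEFAULT_STATE_PARAMS",
]

STATES = ("motion", "ambiguous", "freezing")
STATE_CODES = {s: i for i, s in enumerate(STATES)}

#: Per-state similarity-score (mean, sd) used by the direct-trace path.
#: Means are ordered motion < ambiguous < freezing and well separated
#: relative to their sds, mirroring a fixed-camera recording in which a
#: small subject occupies a minority of the frame.
DEFAULT_STATE_PARAMS = {
    "motion": (0.955, 0.004),
    "ambiguous": (0.975, 0.004),
    "freezing": (0.995, 0.002),
}


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic-scene parameters (intensities on the 8-bit scale).

    The defaults are calibrated so that rendered state-conditional
    similarity scores land near the direct-trace defaults
    (:data:`DEFAULT_STATE_PARAMS`): motion around 0.95, ambiguous
    around 0.975, freezing around 0.995.
    """

    frame_size: tuple[int, int] = (96, 96)
    background_base: float = 85.0
    background_texture_sd: float = 20.0
    background_noise_sd: float = 1.5
    blob_radius: float = 8.0
    blob_intensity: float = 100.0
    motion_step_sd: float = 4.5
    ambiguous_jitter_sd: float = 2.5
    freezing_jitter_sd: float = 0.4
    speed_cv: float = 0.1
    freezing_dwell_s: float = 6.0
    ambiguous_dwell_s: float = 3.5
    motion_dwell_s: float = 5.0
    min_freezing_s: float = 3.0
    min_other_s: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not (
            self.motion_step_sd
            > self.ambiguous_jitter_sd
            > self.freezing_jitter_sd
            >= 0
        ):
            raise InputError(
                "need motion_step_sd > ambiguous_jitter_sd > "
                "freezing_jitter_sd >= 0"
            )


@dataclass
class GroundTruthSchedule:
    """Per-frame behavioral state as ordered, partitioning intervals.

    ``intervals`` is a list of ``(state, start_frame, end_frame)`` with
    end exclusive; the intervals tile ``[0, total_frames)``.
    """

    intervals: list[tuple[str, int, int]]
    fps: float
    total_frames: int

    def __post_init__(self):
        cursor = 0
        for state, start, end in self.intervals:
            if state not in STATES:
                raise InputError(f"unknown state {state!r}")
            if start != cursor or end <= start:
                raise InputError("intervals must partition [0, total_frames)")
            cursor = end
        if cursor != self.total_frames:
            raise InputError("intervals must cover exactly total_frames")

    def states_per_frame(self) -> np.ndarray:
        """Integer state code per frame (see :data:`STATE_CODES`)."""
        out = np.empty(self.total_frames, dtype=np.int8)
        for state, start, end in self.intervals:
            out[start:end] = STATE_CODES[state]
        return out

    def score_states(self) -> np.ndarray:
        """State code per similarity score (state of the later frame)."""
        return self.states_per_frame()[1:]

    def freezing_score_mask(self) -> np.ndarray:
        """Ground-truth boolean freezing mask at score resolution."""
        return self.score_states() == STATE_CODES["freezing"]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        codes = self.states_per_frame()
        with open(path, "w") as fh:
            fh.write("frame,state\n")
            for i, c in enumerate(codes):
                fh.write(f"{i},{STATES[c]}\n")
        return path


def sample_schedule(
    cfg: SceneConfig, duration_s: float, fps: float = 30.0
) -> GroundTruthSchedule:
    """Draw a seeded alternating-state schedule.

    States never repeat back-to-back; dwell times are exponential with
    per-state means, floored at 3 s for freezing (so every freezing
    interval clears the bout criterion's duration floor) and at a short
    minimum for the other states.
    """
    if duration_s <= 0:
        raise InputError("duration must be positive")
    total = int(round(duration_s * fps))
    rng = np.random.default_rng(cfg.seed)
    means = {
        "freezing": cfg.freezing_dwell_s,
        "ambiguous": cfg.ambiguous_dwell_s,
        "motion": cfg.motion_dwell_s,
    }
    mins = {
        "freezing": cfg.min_freezing_s,
        "ambiguous": cfg.min_other_s,
        "motion": cfg.min_other_s,
    }
    intervals: list[tuple[str, int, int]] = []
    cursor = 0
    state = str(rng.choice(STATES))
    while cursor < total:
        dwell_s = max(mins[state], rng.exponential(means[state]))
        dwell = min(max(1, int(round(dwell_s * fps))), total - cursor)
        intervals.append((state, cursor, cursor + dwell))
        cursor += dwell
        others = [s for s in STATES if s != state]
        state = str(rng.choice(others))
    return GroundTruthSchedule(intervals=intervals, fps=fps, total_frames=total)


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.frame_size
    # i.i.d. pixel texture: gradients everywhere, so the displacement ->
    # decorrelation response is spatially homogeneous, and the blob-
    # texture covariance (which would make the stillness baseline
    # depend on where the subject parks) averages out
    tex = rng.normal(0.0, 1.0, size=(h, w))
    sd = tex.std()
    if sd > 0 and cfg.background_texture_sd > 0:
        tex *= cfg.background_texture_sd / sd
    return cfg.background_base + tex


def render_session(
    schedule: GroundTruthSchedule, cfg: SceneConfig, source_id: str = "synthetic"
) -> FrameSequence:
    """Render the schedule into grayscale frames.

    A Gaussian-profile blob moves according to the per-frame state over
    a fixed textured background; every frame receives fresh i.i.d.
    sensor noise and is quantized to the 8-bit grid.  Movement is a
    sustained speed with a wandering heading — per-frame displacement
    magnitude is drawn around the state's typical speed
    (``ambiguous_jitter_sd`` / ``motion_step_sd``, in pixels/frame) and
    the heading performs an angular random walk, which matches how
    animals actually move (continuous slow head motion vs. continuous
    faster locomotion) and keeps each state's similarity scores in a
    distinct band.  The blob reflects off frame boundaries so it never
    leaves the scene.
    """
    h, w = cfg.frame_size
    ss = np.random.SeedSequence(cfg.seed)
    rng_bg, rng_walk, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    bg = _background(cfg, rng_bg)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    states = schedule.states_per_frame()
    # keep the whole blob (and its freezing micro-motion ring) on
    # screen: a partially visible subject near the frame edge changes
    # fewer pixels per displacement and skews its state's score band
    margin = 2.5 * cfg.blob_radius
    pos = np.array([h / 2.0, w / 2.0])
    theta = float(rng_walk.uniform(0.0, 2.0 * np.pi))
    speed = {
        STATE_CODES["freezing"]: cfg.freezing_jitter_sd,
        STATE_CODES["ambiguous"]: cfg.ambiguous_jitter_sd,
        STATE_CODES["motion"]: cfg.motion_step_sd,
    }
    frames = np.empty((schedule.total_frames, h, w))
    two_r2 = 2.0 * cfg.blob_radius**2
    anchor = pos.copy()
    prev_code = -1
    for i, code in enumerate(states):
        code = int(code)
        v = speed[code]
        if code == STATE_CODES["freezing"]:
            # tethered micro-oscillation (breathing / slow head
            # movement) around the spot where the animal froze: the
            # blob circles the anchor at a steady small radius, so
            # the per-frame-pair displacement is nearly constant and
            # the freezing scores form a tight band with no slow
            # positional drift
            if prev_code != code:
                anchor = pos.copy()
                phi = float(rng_walk.uniform(0.0, 2.0 * np.pi))
            if v > 0.0:
                phi += rng_walk.normal(1.0, 0.1)
                pos = anchor + v * np.array([np.cos(phi), np.sin(phi)])
            else:
                pos = anchor.copy()
        elif v > 0.0:
            theta += rng_walk.normal(0.0, 0.5)
            mag = abs(rng_walk.normal(v, cfg.speed_cv * v))
            pos = pos + mag * np.array([np.cos(theta), np.sin(theta)])
            # reflect at boundaries (with a blob-radius margin)
            for d, limit in ((0, h), (1, w)):
                lo, hi = margin, limit - margin
                if pos[d] < lo:
                    pos[d] = lo + (lo - pos[d])
                if pos[d] > hi:
                    pos[d] = hi - (pos[d] - hi)
                pos[d] = float(np.clip(pos[d], lo, hi))
        prev_code = code
        blob = cfg.blob_intensity * np.exp(
            -((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / two_r2
        )
        frame = bg + blob
        if cfg.background_noise_sd > 0.0:
            frame = frame + rng_noise.normal(0.0, cfg.background_noise_sd, size=(h, w))
        frames[i] = np.clip(np.round(frame), 0.0, 255.0)
    return FrameSequence(frames, fps=schedule.fps, source_id=source_id)


def simulate_trace(
    schedule: GroundTruthSchedule,
    state_params: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    source_id: str = "synthetic",
) -> SimilarityTrace:
    """Draw a similarity trace directly from per-state Gaussians.

    ``score[i] ~ N(mean_state, sd_state)`` truncated to [0, 1] (a zero
    sd gives exactly the state mean).  Truncation rather than clipping
    keeps the mixture identifiable — no probability mass piles up at
    the boundaries.
    """
    params = dict(DEFAULT_STATE_PARAMS)
    if state_params:
        params.update(state_params)
    means = np.array([params[s][0] for s in STATES])
    sds = np.array([params[s][1] for s in STATES])
    if np.any(means <= 0.0) or np.any(means >= 1.0):
        raise InputError("state means must lie in (0, 1)")
    if not (params["motion"][0] < params["ambiguous"][0] < params["freezing"][0]):
        raise InputError("state means must be ordered motion < ambiguous < freezing")
    codes = schedule.score_states()
    m = means[codes]
    s = sds[codes]
    rng = np.random.default_rng(seed)
    scores = m.copy()
    nz = s > 0.0
    if nz.any():
        a = (0.0 - m[nz]) / s[nz]
        b = (1.0 - m[nz]) / s[nz]
        scores[nz] = truncnorm.rvs(
            a, b, loc=m[nz], scale=s[nz], random_state=rng
        )
    return SimilarityTrace(scores, fps=schedule.fps, source_id=source_id)
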