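"""Trace denoising: outlier substitution then median filtering.

Dropped video frames and lighting-induced aliasing produce isolated,
anomalously low similarity scores that do not reflect the animal's
behavior.  Denoising replaces every score at or below an outlier
threshold (default r² = 0.93) with the *modal* similarity score, then
passes the corrected vector through a short median filter (3-frame
kernel by default).  The order is fixed: substitute, then filter.

The mode of a continuous-valued trace is operationalized as the center
of the most populated histogram bin (bin width 0.001 over [0, 1]),
computed over non-outlier scores only, ties broken toward the higher
bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _ndi_median

from .errors import ConfigError, DegenerateTraceError
from .trace import SimilarityTrace

__all__ = [
    "DenoiseConfig",
    "modal_score",
    "substitute_outliers",
    "median_filter",
    "denoise",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising parameters.

    outlier_threshold : scores at or below this r² are treated as
        artifacts (default 0.93).
    median_kernel : odd window length, in frames, of the median filter
        (default 3; 1 disables filtering).
    mode_bin_width : histogram bin width used to locate the modal score
        (default 0.001 similarity units).
    """

    outlier_threshold: float = 0.93
    median_kernel: int = 3
    mode_bin_width: float = 0.001

    def __post_init__(self):
        if not 0.0 < self.outlier_threshold < 1.0:
            raise ConfigError(
                f"outlier_threshold must be in (0, 1), got {self.outlier_threshold}"
            )
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigError(
                f"median_kernel must be odd and >= 1, got {self.median_kernel}"
            )
        if not 0.0 < self.mode_bin_width < 1.0:
            raise ConfigError(
                f"mode_bin_width must be in (0, 1), got {self.mode_bin_width}"
            )


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, SimilarityTrace):
        return scores.scores
    return np.asarray(scores, dtype=float)


def modal_score(scores, cfg: DenoiseConfig | None = None) -> float:
    """Center of the most populated histogram bin among non-outlier scores.

    Bins of width ``cfg.mode_bin_width`` span [0, 1]; ties go to the
    higher bin.  Raises :class:`DegenerateTraceError` when every score
    is at or below the outlier threshold — such a session has no usable
    stillness signal and needs manual handling.
    """
    cfg = cfg or DenoiseConfig()
    x = _as_scores(scores)
    keep = x > cfg.outlier_threshold
    if not keep.any():
        raise DegenerateTraceError(
            "all scores are at or below the outlier threshold "
            f"({cfg.outlier_threshold}); the session needs manual review"
        )
    x = x[keep]
    n_bins = int(round(1.0 / cfg.mode_bin_width))
    # Guard against float representation pushing e.g. 0.97/0.001 to
    # 969.9999...: round to 9 decimals before flooring.
    idx = np.floor(np.round(x / cfg.mode_bin_width, 9)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mode_idx = (n_bins - 1) - int(np.argmax(counts[::-1]))  # ties -> higher bin
    return (mode_idx + 0.5) * cfg.mode_bin_width


def substitute_outliers(scores, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Replace every score <= outlier_threshold with the modal score."""
    cfg = cfg or DenoiseConfig()
    x = _as_scores(scores)
    mode = modal_score(x, cfg)
    out = x.copy()
    out[x <= cfg.outlier_threshold] = mode
    return out


def median_filter(scores, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Sliding-window median with reflect padding; length preserved."""
    cfg = cfg or DenoiseConfig()
    x = _as_scores(scores)
    if cfg.median_kernel > x.size:
        raise ConfigError(
            f"median kernel {cfg.median_kernel} exceeds trace length {x.size}"
        )
    if cfg.median_kernel == 1:
        return x.copy()
    return _ndi_median(x, size=cfg.median_kernel, mode="reflect")


def denoise(trace: SimilarityTrace, cfg: DenoiseConfig | None = None) -> SimilarityTrace:
    """Full denoising pass: outlier substitution, then median filter."""
    cfg = cfg or DenoiseConfig()
    cleaned = median_filter(substitute_outliers(trace.scores, cfg), cfg)
    return trace.replace(cleaned, denoised=True)
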