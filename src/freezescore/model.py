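"""Model/Results front end for single-session freezing analysis.

:class:`FreezingModel` is constructed from data (a similarity trace, a
frame sequence, or a video file) plus the three stage configurations;
``fit()`` runs denoising, the restarted-EM mixture fit, posterior
computation and bout detection, and returns a :class:`FreezingResults`
object carrying the estimates, diagnostics, and a ``summary()`` table.
Manual override of the component point estimates — the semi-automated
path for degenerate sessions — hangs off the results object and
recomputes everything downstream of the mixture.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import classify
from . import mixture as _mx
from .denoise import denoise as _run_denoise
from .classify import BoutConfig, FreezingBout, PosteriorTrace, SessionSummary
from .denoise import DenoiseConfig
from .errors import DegenerateModelError, InputError
from .mixture import COMPONENT_LABELS, MixtureConfig, MixtureModel
from .trace import FrameSequence, SimilarityTrace, compute_similarity_trace, read_video

__all__ = ["FreezingModel", "FreezingResults"]


class FreezingModel:
    """Freezing-behavior model for one video session.

    Parameters
    ----------
    trace : SimilarityTrace
        Raw (not yet denoised) per-frame-pair similarity scores.
    denoise : DenoiseConfig, optional
    mixture : MixtureConfig, optional
    bouts : BoutConfig, optional

    Examples
    --------
    >>> from freezescore import FreezingModel
    >>> from freezescore.synthetic import SceneConfig, sample_schedule, simulate_trace
    >>> sched = sample_schedule(SceneConfig(seed=7), duration_s=120.0)
    >>> res = FreezingModel(simulate_trace(sched, seed=7)).fit(seed=0)
    >>> res.session.n_bouts  # doctest: +SKIP
    """

    def __init__(
        self,
        trace: SimilarityTrace,
        denoise: DenoiseConfig | None = None,
        mixture: MixtureConfig | None = None,
        bouts: BoutConfig | None = None,
    ):
        if not isinstance(trace, SimilarityTrace):
            raise InputError("trace must be a SimilarityTrace; see from_scores")
        self.trace = trace
        self.denoise_config = denoise or DenoiseConfig()
        self.mixture_config = mixture or MixtureConfig()
        self.bout_config = bouts or BoutConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_scores(
        cls, scores, fps: float = 30.0, source_id: str = "", **configs
    ) -> "FreezingModel":
        return cls(SimilarityTrace(scores, fps=fps, source_id=source_id), **configs)

    @classmethod
    def from_frames(cls, seq: FrameSequence, **configs) -> "FreezingModel":
        return cls(compute_similarity_trace(seq), **configs)

    @classmethod
    def from_video(
        cls,
        path,
        fps_override: float | None = None,
        max_dim: int | None = None,
        crop: tuple[int, int, int, int] | None = None,
        **configs,
    ) -> "FreezingModel":
        seq = read_video(path, fps_override=fps_override, max_dim=max_dim, crop=crop)
        return cls.from_frames(seq, **configs)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        seed: int | None = None,
        override_means=None,
        override_sds=None,
        override_weights=None,
    ) -> "FreezingResults":
        """Run the full pipeline and return results.

        ``seed`` overrides the mixture config's seed for the EM
        restarts.  When ``override_means`` is given the fitted (or, for
        a degenerate trace, manually constructed) mixture is replaced
        by the supplied point estimates before classification.
        """
        cfg = self.mixture_config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        clean = _run_denoise(self.trace, self.denoise_config)
        try:
            mm = _mx.fit_mixture(clean, cfg)
        except DegenerateModelError:
            if override_means is None:
                raise
            mm = _mx.manual_model(
                clean, override_means, sds=override_sds, weights=override_weights
            )
        else:
            if override_means is not None:
                mm = _mx.override_components(
                    mm, override_means, sds=override_sds, weights=override_weights
                )
        return FreezingResults(self, clean, mm)


class FreezingResults:
    """Fitted results for one session.

    Attributes
    ----------
    mixture : MixtureModel
        Labeled 3-component mixture (motion / ambiguous / freezing by
        ascending mean).
    posteriors : PosteriorTrace
    flags : ndarray of bool
        Per-score qualifying-frame flags.
    bouts : list of FreezingBout
    session : SessionSummary
    """

    def __init__(self, model: FreezingModel, denoised: SimilarityTrace, mm: MixtureModel):
        self.model = model
        self.denoised_trace = denoised
        self.mixture = mm
        self.posteriors = _mx.posterior_trace(mm, denoised)
        self.flags = classify.qualifying_frames(
            self.posteriors, mm, denoised, model.bout_config
        )
        self.bouts = classify.detect_bouts(
            self.flags, denoised.fps, model.bout_config
        )
        self.session = classify.summarize_session(self.bouts, self.posteriors)

    # -- the semi-automated path -----------------------------------------
    @property
    def needs_review(self) -> bool:
        """True when the mixture tripped the edge-case gate and no
        manual override has been applied."""
        return self.mixture.edge_case and not self.mixture.manual_override

    def override(self, means, sds=None, weights=None) -> "FreezingResults":
        """Re-classify with human-supplied component point estimates."""
        mm = _mx.override_components(self.mixture, means, sds=sds, weights=weights)
        return FreezingResults(self.model, self.denoised_trace, mm)

    # -- convenience outputs ----------------------------------------------
    def bout_table(self):
        return classify.bout_table(self.bouts, source_id=self.denoised_trace.source_id)

    def minute_bins(self, bin_length_s: float = 60.0) -> np.ndarray:
        from .stats import minute_bins

        return minute_bins(
            self.bouts, len(self.denoised_trace), self.denoised_trace.fps, bin_length_s
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        mm = self.mixture
        s = self.session
        fit_kind = "manual override" if mm.manual_override else (
            "EM (converged)" if mm.converged else "EM (NOT converged)"
        )
        lines = [
            "Freezing session results",
            "=" * 60,
            f"source_id:         {self.denoised_trace.source_id or '-'}",
            f"scores:            {len(self.denoised_trace)}"
            f"  ({self.denoised_trace.duration_s:.1f} s at "
            f"{self.denoised_trace.fps:g} fps)",
            f"mixture fit:       {fit_kind}"
            + ("" if np.isnan(mm.log_likelihood) else f", logL = {mm.log_likelihood:.2f}"),
            "-" * 60,
            f"{'component':<12}{'weight':>10}{'mean':>10}{'sd':>12}",
        ]
        for i, lab in enumerate(COMPONENT_LABELS):
            lines.append(
                f"{lab:<12}{mm.weights[i]:>10.4f}{mm.means[i]:>10.4f}{mm.sds[i]:>12.6f}"
            )
        lines += [
            "-" * 60,
            f"freezing bouts:    {s.n_bouts}",
            f"total freezing:    {s.total_freezing_s:.2f} s",
            f"mean bout:         {s.mean_bout_s:.2f} s",
            f"freezing fraction: {s.freezing_fraction:.4f}",
            f"motor activity:    {s.motor_activity:.2f}",
        ]
        if mm.warnings:
            lines.append("-" * 60)
            lines.append("edge-case warnings (manual review required):")
            lines += [f"  * {w}" for w in mm.warnings]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_trace(self, ax=None):
        """Denoised trace with detected bouts shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = np.arange(len(self.denoised_trace)) / self.denoised_trace.fps
        ax.plot(t, self.denoised_trace.scores, lw=0.5, color="k")
        for b in self.bouts:
            ax.axvspan(b.start_s, b.start_s + b.duration_s, color="C0", alpha=0.3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("similarity score (r$^2$)")
        return ax

    def plot_mixture(self, ax=None, bins: int = 100):
        """Score histogram with the fitted component densities."""
        import matplotlib.pyplot as plt
        from scipy.stats import norm

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = self.denoised_trace.scores
        ax.hist(x, bins=bins, density=True, alpha=0.4, color="gray")
        grid = np.linspace(x.min(), x.max(), 1000)
        mm = self.mixture
        for i, lab in enumerate(COMPONENT_LABELS):
            ax.plot(
                grid,
                mm.weights[i] * norm.pdf(grid, mm.means[i], mm.sds[i]),
                label=lab,
            )
        ax.legend()
        ax.set_xlabel("similarity score (r$^2$)")
        ax.set_ylabel("density")
        return ax
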