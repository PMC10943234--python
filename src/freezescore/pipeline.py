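"""End-to-end orchestration: single sessions and cohorts.

``run_session`` executes video → trace → denoise → mixture → bouts →
summary, writing every artifact with a JSON sidecar carrying the config
hash, seed and package version so reruns are byte-reproducible.  The
semi-automated contract is enforced here: a session whose mixture fit
trips the edge-case gate and has no manual override exits with a
``review-required`` status and diagnostic frame ranges instead of a
bout table — degenerate sessions are never auto-scored.

``run_cohort`` scores many sessions, assembles the subject table, joins
optional covariates, and runs the cohort statistics (split-half t test,
per-minute freezing trend, covariate correlations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import BoutConfig, bout_table
from .denoise import DenoiseConfig
from .errors import InputError, UndefinedStatisticError
from .mixture import MixtureConfig
from .model import FreezingModel, FreezingResults
from .stats import correlate, grand_mean_trend, minute_bins, split_half_test
from .trace import SimilarityTrace, read_trace, read_video, write_trace

__all__ = ["RunConfig", "RunResult", "run_session", "run_cohort"]

logger = logging.getLogger("freezescore")

_TRACE_SUFFIXES = (".csv",)


@dataclass
class RunConfig:
    """Everything needed to score one session reproducibly."""

    input_path: str | Path | None = None
    trace: SimilarityTrace | None = None
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    output_dir: str | Path | None = None
    seed: int | None = None
    override_means: tuple[float, float, float] | None = None
    crop: tuple[int, int, int, int] | None = None
    fps_override: float | None = None
    source_id: str | None = None

    def config_dict(self) -> dict:
        return {
            "denoise": dataclasses.asdict(self.denoise),
            "mixture": dataclasses.asdict(self.mixture),
            "bouts": dataclasses.asdict(self.bouts),
            "seed": self.seed,
            "override_means": list(self.override_means)
            if self.override_means
            else None,
            "crop": list(self.crop) if self.crop else None,
            "fps_override": self.fps_override,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.config_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Outcome of one session run."""

    status: str  # "ok" | "review-required"
    results: FreezingResults | None
    source_id: str
    outputs: dict = field(default_factory=dict)


def _sidecar(cfg: RunConfig, extra: dict | None = None) -> dict:
    meta = {
        "config": cfg.config_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    if extra:
        meta.update(extra)
    return meta


def _write_json(path: Path, payload: dict) -> Path:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def _load_trace(cfg: RunConfig) -> SimilarityTrace:
    if cfg.trace is not None:
        return cfg.trace
    if cfg.input_path is None:
        raise InputError("RunConfig needs either a trace or an input_path")
    path = Path(cfg.input_path)
    if path.suffix.lower() in _TRACE_SUFFIXES:
        trace = read_trace(path, fps=cfg.fps_override)
    else:
        seq = read_video(
            path,
            fps_override=cfg.fps_override,
            crop=cfg.crop,
            source_id=cfg.source_id,
        )
        from .trace import compute_similarity_trace

        trace = compute_similarity_trace(seq)
    if cfg.source_id:
        trace = SimilarityTrace(
            trace.scores, fps=trace.fps, source_id=cfg.source_id,
            denoised=trace.denoised,
        )
    return trace


def _review_frame_ranges(res: FreezingResults, n_per_component: int = 2, span: int = 90) -> list[dict]:
    """Frame ranges a reviewer should watch: the scores closest to each
    component mean, one short clip per occurrence."""
    scores = res.denoised_trace.scores
    out = []
    for i, lab in enumerate(("motion", "ambiguous", "freezing")):
        order = np.argsort(np.abs(scores - res.mixture.means[i]))
        for j in order[:n_per_component]:
            start = max(0, int(j) - span // 2)
            out.append(
                {
                    "component": lab,
                    "start_frame": start,
                    "end_frame": min(scores.size - 1, start + span),
                }
            )
    return out


def run_session(cfg: RunConfig) -> RunResult:
    """Score one session; write artifacts when ``cfg.output_dir`` is set.

    Returns a :class:`RunResult` whose status is ``"review-required"``
    (with no bout table written) when the fitted mixture carries the
    edge-case warning and no manual override was supplied.
    """
    t0 = time.perf_counter()
    trace = _load_trace(cfg)
    sid = trace.source_id or "session"
    logger.info("[%s] trace loaded: %d scores", sid, len(trace))

    model = FreezingModel(
        trace, denoise=cfg.denoise, mixture=cfg.mixture, bouts=cfg.bouts
    )
    res = model.fit(seed=cfg.seed, override_means=cfg.override_means)
    logger.info(
        "[%s] mixture fit in %.2f s (means %s)",
        sid,
        time.perf_counter() - t0,
        np.round(res.mixture.means, 4).tolist(),
    )

    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    outputs: dict = {}
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if res.needs_review:
        logger.warning("[%s] edge case: manual review required", sid)
        if outdir:
            outputs["model"] = str(res.mixture.save(outdir / f"{sid}_model.json"))
            outputs["review"] = str(
                _write_json(
                    outdir / f"{sid}_review.json",
                    _sidecar(
                        cfg,
                        {
                            "status": "review-required",
                            "warnings": res.mixture.warnings,
                            "clips": _review_frame_ranges(res),
                        },
                    ),
                )
            )
        return RunResult("review-required", res, sid, outputs)

    if outdir:
        outputs["trace"] = str(
            write_trace(res.denoised_trace, outdir / f"{sid}_denoised.csv",
                        extra_meta={"config_hash": cfg.config_hash(),
                                    "seed": cfg.seed, "version": __version__})
        )
        outputs["model"] = str(res.mixture.save(outdir / f"{sid}_model.json"))
        bt = bout_table(res.bouts, source_id=sid)
        bt.to_csv(outdir / f"{sid}_bouts.csv", index=False)
        outputs["bouts"] = str(outdir / f"{sid}_bouts.csv")
        s = res.session
        pd.DataFrame(
            [
                {
                    "source_id": sid,
                    "total_freezing_s": s.total_freezing_s,
                    "n_bouts": s.n_bouts,
                    "mean_bout_s": s.mean_bout_s,
                    "motor_activity": s.motor_activity,
                    "freezing_fraction": s.freezing_fraction,
                }
            ]
        ).to_csv(outdir / f"{sid}_summary.csv", index=False)
        outputs["summary"] = str(outdir / f"{sid}_summary.csv")
        outputs["run"] = str(
            _write_json(outdir / f"{sid}_run.json", _sidecar(cfg, {"status": "ok"}))
        )
    logger.info("[%s] done in %.2f s", sid, time.perf_counter() - t0)
    return RunResult("ok", res, sid, outputs)


def run_cohort(
    configs: list[RunConfig],
    covariates: str | Path | pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
    bin_length_s: float = 60.0,
) -> tuple[pd.DataFrame, dict]:
    """Score a cohort and run the session-level statistics.

    Returns ``(subject_table, stats_report)``.  Sessions that come back
    review-required are recorded in the report and excluded from the
    statistics; covariate join failures are listed per subject.
    """
    if not configs:
        raise InputError("need at least 1 session")
    rows = []
    bouts_per_subject = []
    bin_matrix = []
    review = []
    session_len = None
    for cfg in configs:
        rr = run_session(cfg)
        if rr.status != "ok":
            review.append(rr.source_id)
            continue
        res = rr.results
        s = res.session
        rows.append(
            {
                "source_id": rr.source_id,
                "total_freezing_s": s.total_freezing_s,
                "n_bouts": s.n_bouts,
                "mean_bout_s": s.mean_bout_s,
                "motor_activity": s.motor_activity,
                "freezing_fraction": s.freezing_fraction,
            }
        )
        bouts_per_subject.append(res.bouts)
        session_len = res.denoised_trace.duration_s
        bin_matrix.append(
            minute_bins(
                res.bouts, len(res.denoised_trace), res.denoised_trace.fps,
                bin_length_s,
            )
        )
    table = pd.DataFrame(rows)

    join_failures = []
    if covariates is not None and len(table):
        cov = (
            covariates
            if isinstance(covariates, pd.DataFrame)
            else pd.read_csv(covariates)
        )
        if "source_id" not in cov.columns:
            raise InputError("covariates need a source_id column")
        cov["source_id"] = cov["source_id"].astype(str)
        table["source_id"] = table["source_id"].astype(str)
        merged = table.merge(cov, on="source_id", how="left", validate="1:1")
        cov_cols = [c for c in cov.columns if c != "source_id"]
        for _, row in merged.iterrows():
            if row[cov_cols].isna().any():
                join_failures.append(row["source_id"])
        table = merged

    report: dict = {
        "n_subjects": int(len(table)),
        "review_required": review,
        "covariate_join_failures": join_failures,
    }
    if len(table) >= 2 and session_len:
        try:
            t, df, p = split_half_test(bouts_per_subject, session_len)
            report["split_half"] = {"t": t, "df": df, "p": p}
        except UndefinedStatisticError as exc:
            report["split_half"] = {"error": str(exc)}
    if bin_matrix:
        M = np.vstack(bin_matrix)
        report["minute_bins"] = {"grand_mean": M.mean(axis=0).tolist()}
        try:
            r, p = grand_mean_trend(M)
            report["minute_bins"]["trend"] = {"r": r, "p": p}
        except (UndefinedStatisticError, InputError) as exc:
            report["minute_bins"]["trend"] = {"error": str(exc)}
    behavioral = [
        "total_freezing_s",
        "n_bouts",
        "mean_bout_s",
        "motor_activity",
    ]
    if covariates is not None and len(table) >= 3:
        corr = {}
        cov_cols = [
            c
            for c in table.columns
            if c not in behavioral + ["source_id", "freezing_fraction"]
        ]
        for xcol in cov_cols:
            for ycol in behavioral:
                try:
                    r, p, ci = correlate(table, xcol, ycol, log_transform_y=True)
                    corr[f"{xcol}~log({ycol}+1)"] = {
                        "r": r, "p": p, "ci95": list(ci), "n": int(len(table)),
                    }
                except (UndefinedStatisticError, InputError) as exc:
                    corr[f"{xcol}~log({ycol}+1)"] = {"error": str(exc)}
        report["correlations"] = corr

    if output_dir:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "subjects.csv", index=False)
        _write_json(outdir / "cohort_report.json", report)
    return table, report
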