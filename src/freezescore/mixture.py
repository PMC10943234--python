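"""Per-subject 3-component 1-D Gaussian mixture over similarity scores.

The denoised trace of each subject is modeled as a mixture of three
Gaussians.  Because lower similarity scores mean larger frame-to-frame
change, the components are labeled by ascending mean:

* lowest mean  → **motion**
* middle mean  → **ambiguous** (scores too ambiguous to classify,
  a buffer against spurious assignments)
* highest mean → **freezing**

Fitting runs many independent EM fits (300 by default) from seeded
random initializations and keeps the one with the highest final
log-likelihood, which makes the per-subject model highly stable.  EM
runs in log space throughout; a variance floor prevents singular
collapse, and collapsed or vanishing components mark the model with an
edge-case warning so the semi-automated pipeline can route the session
to manual review instead of silently accepting a bad fit.

Manual override: for degenerate sessions (an animal that essentially
never or always moves) a human supplies component point estimates; the
override only needs to be approximate because its job is to push every
frame's posterior toward the correct extreme class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigError, DegenerateModelError, InputError
from .trace import SimilarityTrace

__all__ = [
    "MixtureConfig",
    "MixtureModel",
    "COMPONENT_LABELS",
    "fit_mixture",
    "override_components",
    "manual_model",
    "posterior_trace",
]

#: Component labels in ascending-mean order.
COMPONENT_LABELS = ("motion", "ambiguous", "freezing")

_LOG_2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class MixtureConfig:
    """Mixture-fitting parameters.

    n_components is fixed at 3 by the published method.  n_restarts
    independent EM fits are run (default 300) and the best one kept.
    min_component_weight / min_mean_separation define the edge-case
    gate: a winning fit violating either carries a warning and the
    pipeline refuses to auto-score without a manual override.
    """

    n_components: int = 3
    n_restarts: int = 300
    seed: int | None = None
    min_component_weight: float = 0.01
    min_mean_separation: float = 0.005
    max_em_iters: int = 500
    em_tol: float = 1e-8

    def __post_init__(self):
        if self.n_components != 3:
            raise ConfigError("the published method fixes n_components = 3")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


@dataclass
class MixtureModel:
    """A fitted (or manually set) 3-component 1-D Gaussian mixture.

    Components are stored in ascending-mean order so that index 0 is
    the motion component, 1 ambiguous, 2 freezing (see
    :data:`COMPONENT_LABELS`).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float = float("nan")
    converged: bool = False
    manual_override: bool = False
    source_id: str = ""
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)
    trace_sd: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.weights.shape == self.means.shape == self.sds.shape == (3,)):
            raise InputError("weights, means and sds must each have shape (3,)")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InputError("component weights must sum to 1")
        if np.any(self.sds <= 0):
            raise InputError("component sds must be positive")
        order = np.argsort(self.means, kind="stable")
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]

    @property
    def labels(self) -> dict[int, str]:
        """Component index → behavioral label (ascending-mean order)."""
        return {i: lab for i, lab in enumerate(COMPONENT_LABELS)}

    @property
    def edge_case(self) -> bool:
        """True when the fit tripped the tiny-weight / collapsed-
        separation gate and the session needs human review."""
        return len(self.warnings) > 0

    def component(self, label: str) -> tuple[float, float, float]:
        """(weight, mean, sd) of the component with the given label."""
        i = COMPONENT_LABELS.index(label)
        return float(self.weights[i]), float(self.means[i]), float(self.sds[i])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "labels": {str(i): l for i, l in self.labels.items()},
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "manual_override": self.manual_override,
            "source_id": self.source_id,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MixtureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            log_likelihood=d.get("log_likelihood", float("nan")),
            converged=d.get("converged", False),
            manual_override=d.get("manual_override", False),
            source_id=d.get("source_id", ""),
            seed=d.get("seed"),
            warnings=list(d.get("warnings", [])),
        )


def _log_norm_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _em_chunk(x, mu, sd, w, cfg):
    """Run EM to convergence for a chunk of restarts simultaneously.

    Parameters are (C, 3) arrays; each restart evolves independently
    (all reductions run along the observation axis within a row), so
    chunking never changes any restart's trajectory.
    Returns final (mu, sd, w, total_ll, converged, n_iters).
    """
    n = x.size
    C = mu.shape[0]
    xg = x[None, :, None]  # (1, n, 1)
    ll = np.full(C, -np.inf)
    converged = np.zeros(C, dtype=bool)
    active = np.ones(C, dtype=bool)
    logw = np.log(w)
    for _ in range(cfg.max_em_iters):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        logp = logw[idx, None, :] + _log_norm_pdf(xg, mu[idx, None, :], sd[idx, None, :])
        # manual log-sum-exp over the 3 components (hot loop)
        mmax = logp.max(axis=2, keepdims=True)
        tot = mmax[..., 0] + np.log(
            np.exp(logp - mmax).sum(axis=2)
        )  # (c, n)
        new_ll = tot.sum(axis=1)
        resp = np.exp(logp - tot[:, :, None])  # (c, n, 3)
        Nk = resp.sum(axis=1)  # (c, 3)
        Nk_safe = np.maximum(Nk, 1e-300)
        w_new = Nk / n
        mu_new = np.einsum("cnk,n->ck", resp, x) / Nk_safe
        dev = xg - mu_new[:, None, :]
        var_new = np.einsum("cnk,cnk->ck", resp, dev * dev) / Nk_safe
        var_new = np.maximum(var_new, _VAR_FLOOR)
        mu[idx] = mu_new
        sd[idx] = np.sqrt(var_new)
        w[idx] = np.maximum(w_new, 1e-300)
        logw[idx] = np.log(w[idx])
        done = np.abs(new_ll - ll[idx]) <= cfg.em_tol * (1.0 + np.abs(new_ll))
        ll[idx] = new_ll
        converged[idx] = done
        active[idx] = ~done
    return mu, sd, w, ll, converged


def fit_mixture(trace: SimilarityTrace | np.ndarray, cfg: MixtureConfig | None = None) -> MixtureModel:
    """Fit the 3-component mixture by restarted EM.

    Runs ``cfg.n_restarts`` independent EM fits from random
    initializations (means at the trace's 10th/50th/90th quantiles plus
    seeded jitter, sds at the trace sd, uniform weights) and returns the
    fit with the highest final log-likelihood.

    Raises :class:`DegenerateModelError` when all scores are identical.
    A winning fit with a vanishing component weight or nearly merged
    means gets an edge-case warning attached (it does not raise): the
    pipeline uses that flag to demand manual review.
    """
    cfg = cfg or MixtureConfig()
    if isinstance(trace, SimilarityTrace):
        x = trace.scores.astype(np.float64)
        source_id = trace.source_id
    else:
        x = np.asarray(trace, dtype=np.float64)
        source_id = ""
    if x.ndim != 1 or x.size < 2:
        raise InputError("need a 1-D trace with at least 2 scores")
    x_sd = float(x.std())
    if np.ptp(x) == 0.0:
        raise DegenerateModelError(
            "all similarity scores are identical; fit is impossible — "
            "set component point estimates manually (manual_model)"
        )

    rng = np.random.default_rng(cfg.seed)
    R = cfg.n_restarts
    q = np.quantile(x, [0.10, 0.50, 0.90])
    jitter = rng.normal(0.0, 0.25 * x_sd, size=(R, 3))
    mu = q[None, :] + jitter
    sd = np.full((R, 3), max(x_sd, np.sqrt(_VAR_FLOOR)))
    w = np.full((R, 3), 1.0 / 3.0)

    chunk = 50
    ll_all = np.empty(R)
    conv_all = np.empty(R, dtype=bool)
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        mu_c, sd_c, w_c, ll_c, conv_c = _em_chunk(
            x, mu[lo:hi], sd[lo:hi], w[lo:hi], cfg
        )
        mu[lo:hi], sd[lo:hi], w[lo:hi] = mu_c, sd_c, w_c
        ll_all[lo:hi], conv_all[lo:hi] = ll_c, conv_c

    best = int(np.argmax(ll_all))
    model = MixtureModel(
        weights=w[best] / w[best].sum(),
        means=mu[best],
        sds=sd[best],
        log_likelihood=float(ll_all[best]),
        converged=bool(conv_all[best]),
        source_id=source_id,
        seed=cfg.seed,
        trace_sd=x_sd,
    )
    _attach_edge_case_warnings(model, cfg)
    return model


def _attach_edge_case_warnings(model: MixtureModel, cfg: MixtureConfig) -> None:
    tiny = np.nonzero(model.weights < cfg.min_component_weight)[0]
    for i in tiny:
        model.warnings.append(
            f"component '{COMPONENT_LABELS[i]}' has weight "
            f"{model.weights[i]:.4g} < {cfg.min_component_weight}"
        )
    seps = np.diff(model.means)
    for i, s in enumerate(seps):
        if s < cfg.min_mean_separation:
            model.warnings.append(
                f"means of '{COMPONENT_LABELS[i]}' and "
                f"'{COMPONENT_LABELS[i + 1]}' are separated by "
                f"{s:.4g} < {cfg.min_mean_separation}"
            )


def _check_means(means: np.ndarray) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    if means.shape != (3,):
        raise InputError("exactly 3 component means are required")
    if not np.all(np.isfinite(means)):
        raise InputError("means must be finite")
    if means.min() < 0.0 or means.max() > 1.0:
        raise InputError("means must lie in [0, 1]")
    means = np.sort(means)
    if np.any(np.diff(means) <= 0):
        raise InputError("means must be strictly increasing after sorting")
    return means


def override_components(
    model: MixtureModel,
    means,
    sds=None,
    weights=None,
) -> MixtureModel:
    """Manually set component point estimates on an existing model.

    Omitted sds/weights keep the fitted values; supplied values must be
    positive (sds) or sum to 1 (weights).  The returned model carries
    ``manual_override=True`` and labels reassigned by ascending mean.
    """
    means = _check_means(means)
    if sds is None:
        sds = model.sds.copy()
    else:
        sds = np.asarray(sds, dtype=float)
        if sds.shape != (3,) or np.any(sds <= 0):
            raise InputError("sds must be 3 positive values")
    if weights is None:
        weights = model.weights.copy()
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (3,) or abs(weights.sum() - 1.0) > 1e-9:
            raise InputError("weights must be 3 values summing to 1")
    return MixtureModel(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=model.log_likelihood,
        converged=model.converged,
        manual_override=True,
        source_id=model.source_id,
        seed=model.seed,
        trace_sd=model.trace_sd,
    )


def manual_model(
    trace: SimilarityTrace | np.ndarray,
    means,
    sds=None,
    weights=None,
    source_id: str = "",
) -> MixtureModel:
    """Build a mixture model purely from human-supplied point estimates.

    For degenerate sessions where no fit exists: missing sds default to
    the pooled sd of the trace (floored so a constant trace still
    yields a usable model), missing weights to uniform.
    """
    means = _check_means(means)
    if isinstance(trace, SimilarityTrace):
        x = trace.scores
        source_id = source_id or trace.source_id
    else:
        x = np.asarray(trace, dtype=float)
    if sds is None:
        pooled = max(float(x.std()), 1e-4)
        sds = np.full(3, pooled)
    if weights is None:
        weights = np.full(3, 1.0 / 3.0)
    return MixtureModel(
        weights=np.asarray(weights, dtype=float),
        means=means,
        sds=np.asarray(sds, dtype=float),
        manual_override=True,
        source_id=source_id,
        trace_sd=float(x.std()),
    )


def posterior_trace(model: MixtureModel, trace: SimilarityTrace | np.ndarray):
    """Posterior component-membership probabilities for every score.

    For score ``s``, the posterior for component ``k`` is
    ``w_k N(s; mu_k, sd_k) / sum_j w_j N(s; mu_j, sd_j)``, computed in
    log space so extreme scores never underflow to NaN.  Returns a
    :class:`~freezescore.classify.PosteriorTrace` whose columns follow
    :data:`COMPONENT_LABELS` order (motion, ambiguous, freezing).
    """
    from .classify import PosteriorTrace

    if isinstance(trace, SimilarityTrace):
        x = trace.scores
        fps = trace.fps
        source_id = trace.source_id
    else:
        x = np.asarray(trace, dtype=float)
        fps = 30.0
        source_id = model.source_id
    logp = np.log(model.weights)[None, :] + _log_norm_pdf(
        x[:, None], model.means[None, :], model.sds[None, :]
    )
    logp -= logsumexp(logp, axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    return PosteriorTrace(probs=probs, fps=fps, source_id=source_id)
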