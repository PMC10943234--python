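"""Rater-validation protocol: segment sampling, consensus, Cohen's kappa,
round-robin interrater reliability, and sensitivity/specificity.

The automated classifier is validated against human raters on short
(3 s) video segments: equal numbers of classifier-freezing and
classifier-non-freezing segments are sampled from a session, raters
label each segment freezing / non-freezing in isolation, the per-segment
consensus (modal label, ties broken toward non-freezing) stands in for
ground truth, and agreement is quantified with Cohen's kappa,
sensitivity (true-positive rate) and specificity (true-negative rate).
Human-vs-human reliability is the unweighted mean kappa over all rater
pairs (round robin).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import FreezingBout
from .errors import InputError, SamplingError, UndefinedStatisticError

__all__ = [
    "RaterLabelSet",
    "Segment",
    "ValidationReport",
    "sample_segments",
    "consensus",
    "cohen_kappa",
    "kappa_permutation_p",
    "sensitivity_specificity",
    "round_robin",
    "validation_report",
]


@dataclass
class RaterLabelSet:
    """Binary freezing labels (1 = freezing) from several raters over a
    common, ordered set of segments."""

    segment_ids: list
    labels: np.ndarray  # (n_raters, n_segments)
    rater_ids: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InputError("labels must be (n_raters, n_segments)")
        if self.labels.shape != (len(self.rater_ids), len(self.segment_ids)):
            raise InputError("labels shape inconsistent with ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise InputError("labels must be binary (0/1)")

    @property
    def n_raters(self) -> int:
        return self.labels.shape[0]

    @property
    def n_segments(self) -> int:
        return self.labels.shape[1]

    @classmethod
    def from_csv(cls, path) -> "RaterLabelSet":
        """Read long-format CSV with columns segment_id, rater_id, label."""
        df = pd.read_csv(path)
        wide = df.pivot(index="rater_id", columns="segment_id", values="label")
        if wide.isna().any().any():
            raise InputError("every rater must label every segment")
        return cls(
            segment_ids=list(wide.columns),
            labels=wide.to_numpy(dtype=int),
            rater_ids=list(wide.index),
        )


@dataclass(frozen=True)
class Segment:
    """A sampled validation segment, in score indices (end inclusive)."""

    start_index: int
    end_index: int
    predicted_freezing: bool
    fps: float = 30.0

    @property
    def segment_id(self) -> str:
        return f"seg_{self.start_index}_{self.end_index}"


def sample_segments(
    bouts: Sequence[FreezingBout],
    n_scores: int,
    fps: float,
    n_per_class: int,
    segment_s: float = 3.0,
    seed: int | None = None,
) -> list[Segment]:
    """Sample non-overlapping segments, ``n_per_class`` fully inside
    freezing bouts and ``n_per_class`` fully outside them.

    Raises :class:`SamplingError` naming the deficient class when a
    session cannot supply the request.
    """
    L = int(round(segment_s * fps))
    if L < 1 or n_per_class < 1:
        raise InputError("segment length and n_per_class must be >= 1")
    inside = np.zeros(n_scores, dtype=bool)
    for b in bouts:
        inside[b.start_index : b.end_index + 1] = True

    def candidate_starts(mask: np.ndarray) -> np.ndarray:
        # starts s where mask[s : s+L] is all True
        if n_scores < L:
            return np.array([], dtype=int)
        csum = np.concatenate([[0], np.cumsum(mask.astype(int))])
        full = csum[L:] - csum[:-L] == L
        return np.nonzero(full)[0]

    rng = np.random.default_rng(seed)
    taken: list[tuple[int, int]] = []
    out: list[Segment] = []
    for cls_name, mask, predicted in (
        ("freezing", inside, True),
        ("non-freezing", ~inside, False),
    ):
        cands = candidate_starts(mask)
        order = rng.permutation(cands.size)
        picked = 0
        for j in order:
            s = int(cands[j])
            e = s + L - 1
            if any(not (e < ts or s > te) for ts, te in taken):
                continue
            taken.append((s, e))
            out.append(Segment(s, e, predicted, fps=fps))
            picked += 1
            if picked == n_per_class:
                break
        if picked < n_per_class:
            raise SamplingError(
                f"could only place {picked}/{n_per_class} disjoint "
                f"{cls_name} segments of {segment_s:g} s",
                deficient_class=cls_name,
            )
    return out


def consensus(labels: RaterLabelSet | np.ndarray) -> np.ndarray:
    """Per-segment majority label; exact ties resolve to non-freezing."""
    arr = labels.labels if isinstance(labels, RaterLabelSet) else np.asarray(labels)
    if arr.shape[0] < 2:
        raise InputError("consensus needs at least 2 raters")
    return (arr.mean(axis=0) > 0.5).astype(int)


def cohen_kappa(a, b) -> float:
    """Chance-corrected agreement between two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    and p_e the chance agreement implied by the raters' marginal label
    frequencies.  The degenerate case p_e = 1 (both raters constant and
    identical) is defined as 1.0 when agreement is perfect and raises
    otherwise.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise InputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 1:
        raise InputError("need at least one label")
    n = a.size
    p_o = float(np.mean(a == b))
    pa1 = float(np.mean(a == 1))
    pb1 = float(np.mean(b == 1))
    p_e = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise UndefinedStatisticError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_permutation_p(
    a, b, n_permutations: int = 10000, seed: int | None = None
) -> float:
    """One-sided permutation p value for kappa(a, b) > chance.

    The reference distribution permutes one rater's labels, breaking
    any true association while preserving both marginals.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    obs = cohen_kappa(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(b)
        try:
            k = cohen_kappa(a, perm)
        except UndefinedStatisticError:
            k = -np.inf
        if k >= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def sensitivity_specificity(pred, truth) -> tuple[float, float]:
    """True-positive and true-negative rates of binary predictions."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size != truth.size:
        raise InputError("length mismatch")
    pos = truth == 1
    neg = truth == 0
    if not pos.any() or not neg.any():
        raise UndefinedStatisticError(
            "sensitivity/specificity undefined: truth contains one class"
        )
    sens = float(np.mean(pred[pos] == 1))
    spec = float(np.mean(pred[neg] == 0))
    return sens, spec


def round_robin(labels: RaterLabelSet) -> float:
    """Unweighted mean Cohen's kappa over all unordered rater pairs."""
    if labels.n_raters < 2:
        raise InputError("round robin needs at least 2 raters")
    kappas = [
        cohen_kappa(labels.labels[i], labels.labels[j])
        for i, j in itertools.combinations(range(labels.n_raters), 2)
    ]
    return float(np.mean(kappas))


@dataclass
class ValidationReport:
    """Agreement metrics for one classifier against a rater panel."""

    pairwise_kappas: dict
    mean_pairwise_kappa: float
    kappa_vs_consensus: float
    kappa_vs_raters: dict
    sensitivity: float
    specificity: float
    n_segments: int
    tie_segments: int = 0

    def to_dict(self) -> dict:
        return {
            "pairwise_kappas": {
                "|".join(map(str, k)): v for k, v in self.pairwise_kappas.items()
            },
            "mean_pairwise_kappa": self.mean_pairwise_kappa,
            "kappa_vs_consensus": self.kappa_vs_consensus,
            "kappa_vs_raters": {str(k): v for k, v in self.kappa_vs_raters.items()},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_segments": self.n_segments,
            "tie_segments": self.tie_segments,
        }


def validation_report(labels: RaterLabelSet, classifier: np.ndarray) -> ValidationReport:
    """Full validation of a classifier's per-segment labels against a
    rater panel: kappa per rater and vs consensus, round-robin human
    reliability, and sensitivity/specificity with the consensus as the
    proxy for true outcomes."""
    classifier = np.asarray(classifier).ravel().astype(int)
    if classifier.size != labels.n_segments:
        raise InputError("classifier labels must cover every segment")
    cons = consensus(labels)
    ties = int(np.sum(np.isclose(labels.labels.mean(axis=0), 0.5)))
    pairwise = {
        (labels.rater_ids[i], labels.rater_ids[j]): cohen_kappa(
            labels.labels[i], labels.labels[j]
        )
        for i, j in itertools.combinations(range(labels.n_raters), 2)
    }
    sens, spec = sensitivity_specificity(classifier, cons)
    return ValidationReport(
        pairwise_kappas=pairwise,
        mean_pairwise_kappa=float(np.mean(list(pairwise.values()))),
        kappa_vs_consensus=cohen_kappa(classifier, cons),
        kappa_vs_raters={
            labels.rater_ids[i]: cohen_kappa(classifier, labels.labels[i])
            for i in range(labels.n_raters)
        },
        sensitivity=sens,
        specificity=spec,
        n_segments=labels.n_segments,
        tie_segments=ties,
    )
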