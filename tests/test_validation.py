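"""Rater validation: kappa, consensus, segment sampling, sens/spec."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freezescore.classify import FreezingBout
from freezescore.errors import InputError, SamplingError, UndefinedStatisticError
from freezescore.validation import (
    RaterLabelSet,
    cohen_kappa,
    consensus,
    kappa_permutation_p,
    round_robin,
    sample_segments,
    sensitivity_specificity,
    validation_report,
)


def _labelset(arrays, rater_ids=None):
    arr = np.asarray(arrays)
    return RaterLabelSet(
        segment_ids=list(range(arr.shape[1])),
        labels=arr,
        rater_ids=rater_ids or [f"r{i}" for i in range(arr.shape[0])],
    )


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_chance_level_contingency(self):
        # p_o = 0.5, p_e = 0.5 from the 2x2 table -> kappa = 0
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_maximal_disagreement(self):
        assert cohen_kappa([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(-1.0)

    def test_degenerate_identical_constant_raters(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            cohen_kappa([1, 0], [1])

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 60))
    def test_symmetric_relabel_invariant_and_bounded_by_agreement(self, seed, n):
        r = np.random.default_rng(seed)
        a, b = r.integers(0, 2, n), r.integers(0, 2, n)
        try:
            k = cohen_kappa(a, b)
        except UndefinedStatisticError:
            return
        assert k == pytest.approx(cohen_kappa(b, a), abs=1e-12)
        assert k == pytest.approx(cohen_kappa(1 - a, 1 - b), abs=1e-12)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        p_o = np.mean(a == b)
        pa, pb = a.mean(), b.mean()
        if pa * pb + (1 - pa) * (1 - pb) > 0:
            assert k <= p_o + 1e-12

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 2, 80), rng.integers(0, 2, 80)
        assert cohen_kappa(a, b) == pytest.approx(
            sk.cohen_kappa_score(a, b), abs=1e-12
        )

    def test_permutation_p_small_for_strong_agreement(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 80)
        b = a.copy()
        flip = rng.choice(80, 8, replace=False)
        b[flip] = 1 - b[flip]
        p = kappa_permutation_p(a, b, n_permutations=500, seed=0)
        assert p < 0.01


class TestConsensus:
    def test_majority_rules(self):
        assert consensus(_labelset([[1, 1], [0, 1], [0, 1]])).tolist() == [0, 1]

    def test_unanimous(self):
        assert consensus(_labelset([[1], [1], [1]])).tolist() == [1]

    def test_two_rater_tie_resolves_to_non_freezing(self):
        assert consensus(_labelset([[1, 0], [0, 0]])).tolist() == [0, 0]

    def test_single_rater_rejected(self):
        with pytest.raises(InputError):
            consensus(_labelset([[1, 0]]))


class TestSensitivitySpecificity:
    def test_perfect_prediction(self):
        assert sensitivity_specificity([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_inverted_prediction(self):
        assert sensitivity_specificity([0, 1, 0], [1, 0, 1]) == (0.0, 0.0)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 80)
        pred = rng.integers(0, 2, 80)
        sens, spec = sensitivity_specificity(pred, truth)
        tp = np.sum((pred == 1) & (truth == 1))
        fn = np.sum((pred == 0) & (truth == 1))
        tn = np.sum((pred == 0) & (truth == 0))
        fp = np.sum((pred == 1) & (truth == 0))
        assert sens == pytest.approx(tp / (tp + fn), abs=1e-12)
        assert spec == pytest.approx(tn / (tn + fp), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity_specificity([1, 0], [1, 1])


class TestRoundRobin:
    def test_identical_raters(self):
        assert round_robin(_labelset([[1, 0, 1]] * 3)) == pytest.approx(1.0)

    def test_two_raters_equals_their_kappa(self):
        ls = _labelset([[1, 0, 1, 1], [1, 1, 0, 1]])
        assert round_robin(ls) == pytest.approx(
            cohen_kappa(ls.labels[0], ls.labels[1])
        )

    def test_mean_over_all_pairs_matches_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, 40)
        labels = np.vstack([base, base, rng.integers(0, 2, 40)])
        ls = _labelset(labels)
        expected = np.mean(
            [
                cohen_kappa(labels[i], labels[j])
                for i, j in itertools.combinations(range(3), 2)
            ]
        )
        assert round_robin(ls) == pytest.approx(expected, abs=1e-12)


class TestSampleSegments:
    def _bouts(self):
        return [FreezingBout(100, 999, 30.0)]  # one 30-s bout

    def test_classes_disjoint_and_correctly_placed(self):
        segs = sample_segments(self._bouts(), 3000, 30.0, 2, 3.0, seed=0)
        assert len(segs) == 4
        assert sum(s.predicted_freezing for s in segs) == 2
        for s in segs:
            if s.predicted_freezing:
                assert 100 <= s.start_index and s.end_index <= 999
            else:
                assert s.end_index < 100 or s.start_index > 999
        for s1, s2 in itertools.combinations(segs, 2):
            assert s1.end_index < s2.start_index or s2.end_index < s1.start_index

    def test_request_exceeding_bout_time_errors_naming_class(self):
        with pytest.raises(SamplingError) as exc:
            sample_segments(self._bouts(), 3000, 30.0, 20, 3.0, seed=0)
        assert exc.value.deficient_class == "freezing"

    def test_fixed_seed_reproducible(self):
        a = sample_segments(self._bouts(), 3000, 30.0, 3, 3.0, seed=42)
        b = sample_segments(self._bouts(), 3000, 30.0, 3, 3.0, seed=42)
        assert a == b


class TestValidationReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 2, 80)
        raters = []
        for rs in (1, 2, 3):
            r = np.random.default_rng(rs)
            lab = truth.copy()
            flip = r.choice(80, 6, replace=False)
            lab[flip] = 1 - lab[flip]
            raters.append(lab)
        ls = _labelset(np.vstack(raters))
        rep = validation_report(ls, truth)
        assert rep.n_segments == 80
        assert -1 <= rep.kappa_vs_consensus <= 1
        assert rep.mean_pairwise_kappa == pytest.approx(round_robin(ls))
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1
        assert len(rep.pairwise_kappas) == 3

    def test_classifier_beats_shuffled_ground_truth(self, sim_session, sim_results):
        # agreement with the real schedule must exceed agreement with a
        # label-shuffled schedule, for every permutation seed tried
        sched, _ = sim_session
        truth = sched.freezing_score_mask()
        pred = np.zeros(len(sim_results.denoised_trace), bool)
        for b in sim_results.bouts:
            pred[b.start_index : b.end_index + 1] = True
        k_true = cohen_kappa(pred.astype(int), truth.astype(int))
        for seed in range(5):
            r = np.random.default_rng(seed)
            k_shuf = cohen_kappa(pred.astype(int), r.permutation(truth).astype(int))
            assert k_true > k_shuf

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rows = []
        for rater in ("r1", "r2"):
            for seg in ("s1", "s2", "s3"):
                rows.append(
                    {"segment_id": seg, "rater_id": rater, "label": int(seg == "s2")}
                )
        p = tmp_path / "labels.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        ls = RaterLabelSet.from_csv(p)
        assert ls.n_raters == 2 and ls.n_segments == 3
        assert consensus(ls).tolist() == [0, 1, 0]
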