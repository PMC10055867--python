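"""Threshold selection, open-set metrics, confusion matrices, score plot."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tocsynd as t
from tocsynd.novelty import (
    NOVEL,
    NoveltyMetrics,
    NoveltyThreshold,
    OpenSetPrediction,
    compute_metrics,
    confusion_matrix,
    plot_novelty_scores,
    round_half_away,
    select_threshold,
)
from tocsynd.peak_tables import CrossPeak, LabeledPeakSet


def make_prediction(true, predicted, scores=None, direction="above", value=1.0):
    n = len(true)
    return OpenSetPrediction(
        true_labels=np.array(true, dtype=object),
        predicted_labels=np.array(predicted, dtype=object),
        scores=np.array(scores if scores is not None else [0.0] * n, dtype=float),
        threshold=NoveltyThreshold(value=value, direction=direction),
        sample="test",
    )


class TestSelectThreshold:
    def test_min_error_separable_picks_gap_midpoint(self):
        th = select_threshold([1.0, 2.0, 3.0], [10.0, 11.0], direction="above")
        assert th.value == pytest.approx(6.5)
        assert th.provenance["validation_error"] == 0

    def test_quantile_max_accepts_all_knowns(self):
        th = select_threshold([1.0, 2.0, 3.0], None, direction="above",
                              strategy="quantile", q=100.0)
        assert th.value == pytest.approx(3.0)
        assert not th.is_novel(np.array([1.0, 2.0, 3.0])).any()

    def test_interleaved_scores_min_error_is_one(self):
        th = select_threshold([1.0, 3.0], [2.0], direction="above")
        assert th.provenance["validation_error"] == 1

    def test_density_direction_flips_sides(self):
        th = select_threshold([10.0, 11.0, 12.0], [1.0, 2.0], direction="below")
        assert th.provenance["validation_error"] == 0
        assert th.is_novel(np.array([1.5]))[0]
        assert not th.is_novel(np.array([11.0]))[0]

    def test_quantile_fallback_without_pseudo_novel(self):
        th = select_threshold([5.0, 6.0, 7.0], None, direction="below")
        assert th.provenance["strategy"] == "quantile"
        assert th.provenance["q"] == 1.0

    def test_empty_known_scores_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [1.0], direction="above")

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        known = rng.uniform(0, 1, 50).tolist()
        pseudo = rng.uniform(0.5, 2, 50).tolist()
        a = select_threshold(known, pseudo, direction="above")
        b = select_threshold(known, pseudo, direction="above")
        assert a.value == b.value


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "Fe,Nn,N,expected",
        [(2, 16, 76, 2.6), (3, 16, 83, 3.6), (1, 16, 83, 1.2), (1, 6, 58, 1.7)],
    )
    def test_total_error_rounding_matches_convention(self, Fe, Nn, N, expected):
        m = NoveltyMetrics(Fn=0, Fp=0, Fe=Fe, Nn=Nn, N=N)
        assert m.rounded()["total_error"] == expected
        assert m.rounded()["fnr"] == 0.0
        assert m.rounded()["fpr"] == 0.0

    def test_all_correct_gives_zero_rates(self):
        pred = make_prediction(["a", "b", "x"], ["a", "b", NOVEL])
        m = compute_metrics(pred, {"a", "b"})
        assert (m.fnr, m.fpr, m.total_error) == (0.0, 0.0, 0.0)

    def test_counts_from_prediction(self):
        pred = make_prediction(
            ["a", "a", "b", "x", "y"],
            ["a", NOVEL, "a", NOVEL, "b"],
        )
        m = compute_metrics(pred, {"a", "b"})
        assert (m.Fn, m.Fp, m.Fe, m.Nn, m.N) == (1, 1, 1, 2, 5)
        assert m.fnr == pytest.approx(50.0)
        assert m.fpr == pytest.approx(100.0 / 3.0)
        assert m.total_error == pytest.approx(60.0)

    def test_no_novel_instances_flags_undefined_fnr(self):
        pred = make_prediction(["a"], ["a"])
        m = compute_metrics(pred, {"a"})
        assert m.fnr == 0.0
        assert m.fnr_undefined

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.65) == 2.7
        assert round_half_away(2.64) == 2.6
        assert round_half_away(0.05) == 0.1


class TestInvariants:
    @given(
        st.lists(
            st.tuples(st.sampled_from(["a", "b", "x"]), st.floats(0, 10)),
            min_size=1,
            max_size=40,
        ),
        st.floats(0.5, 9.5),
        st.floats(0.5, 9.5),
    )
    def test_threshold_monotonicity_distance_direction(self, rows, t1, t2):
        """Raising a distance threshold never decreases Fn, never
        increases Fp."""
        lo, hi = sorted((t1, t2))
        known = {"a", "b"}

        def metrics_at(value):
            th = NoveltyThreshold(value=value, direction="above")
            true = np.array([r[0] for r in rows], dtype=object)
            scores = np.array([r[1] for r in rows])
            predicted = np.where(th.is_novel(scores), NOVEL, "a").astype(object)
            pred = OpenSetPrediction(true, predicted, scores, th)
            return compute_metrics(pred, known)

        m_lo, m_hi = metrics_at(lo), metrics_at(hi)
        assert m_hi.Fn >= m_lo.Fn
        assert m_hi.Fp <= m_lo.Fp

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["a", "b", "x", "y"]),
                st.sampled_from(["a", "b", NOVEL]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_conservation_and_confusion_closure(self, pairs):
        """Fn + detected-novel = Nn; Fp + Fe + correct-known = N - Nn;
        rates recomputed from the confusion matrix equal direct counts."""
        known = {"a", "b"}
        pred = make_prediction(
            [p[0] for p in pairs], [p[1] for p in pairs]
        )
        m = compute_metrics(pred, known)
        detected = sum(
            1 for t_, p_ in pairs if t_ not in known and p_ == NOVEL
        )
        correct_known = sum(
            1 for t_, p_ in pairs if t_ in known and p_ == t_
        )
        assert m.Fn + detected == m.Nn
        assert m.Fp + m.Fe + correct_known == m.N - m.Nn

        cm = confusion_matrix(pred)
        assert int(cm.to_numpy().sum()) == m.N
        fn_cm = int(
            cm.loc[[r for r in cm.index if r not in known],
                   [c for c in cm.columns if c != NOVEL]].to_numpy().sum()
        ) if any(r not in known for r in cm.index) else 0
        assert fn_cm == m.Fn


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        pred = make_prediction(["a", "b", "c"], ["a", "b", "c"])
        cm = confusion_matrix(pred)
        off = cm.to_numpy() - np.diag([1, 1, 1, 0])[:3, :]
        assert np.all(cm.to_numpy().sum(axis=1) == 1)
        for r in cm.index:
            assert cm.loc[r, r] == 1

    def test_row_sums_equal_true_counts(self):
        pred = make_prediction(
            ["a", "a", "b", "x"], ["a", NOVEL, "b", NOVEL]
        )
        cm = confusion_matrix(pred)
        assert cm.loc["a"].sum() == 2
        assert cm.loc["b"].sum() == 1
        assert cm.loc["x", NOVEL] == 1


class TestPlot:
    def _pred_with_groups(self):
        return make_prediction(
            ["a", "a", "b", "x", "y"],
            ["a", "b", NOVEL, NOVEL, "a"],
            scores=[0.1, 0.2, 2.0, 3.0, 0.4],
        )

    def test_plot_writes_file(self, tmp_path):
        pred = self._pred_with_groups()
        out = plot_novelty_scores(
            pred, [0.05, 0.1], pred.threshold, tmp_path / "scores.png",
            known_label_set={"a", "b"},
        )
        assert out.exists() and out.stat().st_size > 0

    def test_empty_test_set_still_renders(self, tmp_path):
        pred = make_prediction([], [], scores=[])
        out = plot_novelty_scores(
            pred, [0.1, 0.2, 0.3], pred.threshold, tmp_path / "empty.png",
            known_label_set={"a"},
        )
        assert out.exists()

    def test_group_counts(self):
        from tocsynd.novelty import score_groups

        groups = score_groups(self._pred_with_groups(), {"a", "b"})
        assert len(groups["known-test correct"]) == 1
        assert len(groups["known-test misclassified"]) == 1
        assert len(groups["known-rejected"]) == 1
        assert len(groups["novel detected"]) == 1
        assert len(groups["novel missed"]) == 1
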