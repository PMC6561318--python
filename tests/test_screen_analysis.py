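"""Hit calling, trigger summaries, responder classes, differentials, ROC."""

import numpy as np
import pytest

from htms.odds_ratio import ContingencyTable, NullSpec, ORResult, Status
from htms.screen_analysis import (
    NOT_EVALUABLE,
    MouseDesign,
    ScreenTable,
    call_hit,
    classify_in_vivo_responder,
    differential_response,
    rank_differential,
    render_heatmap_table,
    roc_calibrate,
    summaries_frame,
    summarize_trigger,
)

NULL = NullSpec()
_TABLE = ContingencyTable(1, 10, 10, 10)


def _res(or_=None, p=None, status=Status.VALID):
    return ORResult("t", or_, p, status, _TABLE)


def _blank():
    return ORResult("t", None, None, Status.INSUFFICIENT_COVERAGE, _TABLE)


class TestCallHit:
    @pytest.mark.parametrize(
        "or_, p, expected",
        [
            (0.5, 0.001, True),
            (0.02, 0.04, True),    # cutoff inclusive
            (0.019, 0.001, False),
            (0.5, 0.05, False),    # alpha strict
            (0.5, 0.2, False),
        ],
    )
    def test_conjunctive_criterion(self, or_, p, expected):
        assert call_hit(_res(or_, p), NULL) is expected

    def test_non_valid_is_not_evaluable(self):
        assert call_hit(_blank(), NULL) is NOT_EVALUABLE
        assert (
            call_hit(_res(status=Status.PNS_FAILURE), NULL) is NOT_EVALUABLE
        )

    def test_sentinel_has_no_truth_value(self):
        with pytest.raises(TypeError):
            bool(NOT_EVALUABLE)


def _screen(entries_spec, design=None, gavage=0.0):
    """entries_spec: {(trigger, mouse, tp): ORResult-or-(or_, p)}"""
    entries = {}
    for key, val in entries_spec.items():
        if isinstance(val, ORResult):
            entries[key] = ORResult(key[0], val.odds_ratio, val.p_value, val.status, val.table)
        else:
            or_, p = val
            entries[key] = ORResult(key[0], or_, p, Status.VALID, _TABLE)
    if design is None:
        mice = {}
        for (_, mouse, tp) in entries:
            mice.setdefault(mouse, set()).add(tp)
        design = [
            MouseDesign(m, "treated" if m.startswith("t") else "control", tuple(sorted(tps)))
            for m, tps in sorted(mice.items())
        ]
    return ScreenTable(entries, design, gavage_timepoint=gavage)


class TestSummarizeTrigger:
    def test_fraction_over_evaluable_only(self):
        spec = {("x", "c1", 0.0): (0.0, 1.0)}
        # 10 evaluable post-gavage cells, 9 hits, plus 2 blanks
        for i in range(9):
            spec[("x", "c1", float(i + 1))] = (0.5, 0.001)
        spec[("x", "c1", 10.0)] = (0.001, 0.9)
        spec[("x", "c1", 11.0)] = _blank()
        spec[("x", "c1", 12.0)] = _blank()
        s = summarize_trigger(_screen(spec), "x", NULL)
        assert s.n_evaluable == 10
        assert s.n_positive == 9
        assert s.fraction_positive == pytest.approx(0.9)

    def test_all_blank_gives_undefined_fraction(self):
        spec = {
            ("x", "c1", 0.0): (0.0, 1.0),
            ("x", "c1", 1.0): _blank(),
            ("x", "c1", 2.0): _blank(),
        }
        s = summarize_trigger(_screen(spec), "x", NULL)
        assert s.n_evaluable == 0 and s.fraction_positive is None

    def test_n_mice_positive_counts_mice_not_cells(self):
        spec = {("x", "c1", 0.0): (0.0, 1.0), ("x", "c2", 0.0): (0.0, 1.0)}
        for tp in (1.0, 2.0, 3.0):
            spec[("x", "c1", tp)] = (0.5, 0.001)
            spec[("x", "c2", tp)] = (0.001, 0.9)
        s = summarize_trigger(_screen(spec), "x", NULL)
        assert s.n_mice_positive == 1

    def test_pooling_is_order_invariant(self):
        rng = np.random.default_rng(0)
        spec = {}
        for mouse in ("c1", "c2", "t1"):
            spec[("x", mouse, 0.0)] = (0.0, 1.0)
            for tp in (1.0, 2.0, 3.0):
                hit = rng.random() < 0.5
                spec[("x", mouse, tp)] = (0.5, 0.001) if hit else (0.0, 0.9)
        table = _screen(spec)
        frac = summarize_trigger(table, "x", NULL).fraction_positive
        shuffled = dict(reversed(list(spec.items())))
        frac2 = summarize_trigger(_screen(shuffled), "x", NULL).fraction_positive
        assert frac == frac2


class TestClassifyInVivoResponder:
    def _base(self, gavage_or, hits):
        spec = {("x", "c1", 0.0): (gavage_or, 1.0)}
        for i, h in enumerate(hits):
            spec[("x", "c1", float(i + 1))] = (0.5, 0.001) if h else (0.0, 0.9)
        return _screen(spec)

    def test_off_at_gavage_with_later_hit(self):
        assert classify_in_vivo_responder(self._base(0.001, [False, True]), "x", NULL) is True

    def test_on_before_gut_is_not_a_responder(self):
        assert classify_in_vivo_responder(self._base(0.5, [True, True]), "x", NULL) is False

    def test_no_later_hits(self):
        assert classify_in_vivo_responder(self._base(0.001, [False, False]), "x", NULL) is False

    def test_invalid_gavage_not_evaluable(self):
        spec = {("x", "c1", 0.0): _blank(), ("x", "c1", 1.0): (0.5, 0.001)}
        assert classify_in_vivo_responder(_screen(spec), "x", NULL) is NOT_EVALUABLE


class TestDifferentialResponse:
    def _spec(self, treated_hits, control_hits):
        spec = {}
        for prefix, hits in (("t", treated_hits), ("c", control_hits)):
            for i, h in enumerate(hits):
                mouse = f"{prefix}{i % 3 + 1}"
                tp = float(i // 3 + 1)
                spec[("x", mouse, tp)] = (0.5, 0.001) if h else (0.0, 0.9)
        return spec

    def test_disease_specific_trigger(self):
        spec = self._spec([True] * 14 + [False], [False] * 15)
        d = differential_response(_screen(spec), "x", NULL)
        assert d == pytest.approx(14 / 15)

    def test_identical_patterns_give_zero(self):
        spec = self._spec([True, False, True], [True, False, True])
        assert differential_response(_screen(spec), "x", NULL) == 0.0

    def test_control_only_response_is_negative(self):
        spec = self._spec([False] * 10, [True] * 5 + [False] * 5)
        assert differential_response(_screen(spec), "x", NULL) == pytest.approx(-0.5)

    def test_antisymmetric_under_group_swap(self):
        spec = self._spec([True, True, False], [False, False, False])
        d1 = differential_response(_screen(spec), "x", NULL)
        swapped = {("x", ("c" if m.startswith("t") else "t") + m[1:], tp): v
                   for (t, m, tp), v in spec.items()}
        d2 = differential_response(_screen(swapped), "x", NULL)
        assert d1 == pytest.approx(-d2)

    def test_empty_group_not_evaluable(self):
        spec = {("x", "t1", 1.0): (0.5, 0.001), ("x", "c1", 1.0): _blank()}
        assert differential_response(_screen(spec), "x", NULL) is NOT_EVALUABLE

    def test_ranking_sorts_by_difference(self):
        spec = self._spec([True] * 6, [False] * 6)
        spec.update({("y", m, tp): (0.0, 0.9) for (t, m, tp) in list(spec)})
        df = rank_differential(_screen(spec), NULL)
        assert list(df["trigger_id"]) == ["x", "y"]


class TestROC:
    def test_perfect_separation(self):
        ors = {f"on{i}": 0.1 + 0.1 * i for i in range(5)}
        ors.update({f"off{i}": 0.001 * (i + 1) for i in range(5)})
        labels = {t: t.startswith("on") for t in ors}
        res = roc_calibrate(ors, labels)
        assert res.auc == pytest.approx(1.0)
        assert 0.005 < res.youden_threshold <= 0.1

    def test_auc_equals_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(5)
        ors = {f"t{i}": float(rng.lognormal(-3, 2)) for i in range(20)}
        labels = {t: bool(rng.integers(0, 2)) for t in ors}
        labels["t0"], labels["t1"] = True, False  # ensure both classes
        res = roc_calibrate(ors, labels)
        pos = [ors[t] for t in ors if labels[t]]
        neg = [ors[t] for t in ors if not labels[t]]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(6)
        n = 1000
        ors = {f"t{i}": float(rng.lognormal(-3, 2)) for i in range(n)}
        labels = {f"t{i}": bool(rng.integers(0, 2)) for i in range(n)}
        res = roc_calibrate(ors, labels)
        n_pos = sum(labels.values())
        n_neg = n - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(res.auc - 0.5) < 3 * se

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        ors = {f"t{i}": float(rng.lognormal(-3, 1)) for i in range(50)}
        labels = {t: bool(rng.integers(0, 2)) for t in ors}
        labels["t0"], labels["t1"] = True, False
        auc1 = roc_calibrate(ors, labels).auc
        auc2 = roc_calibrate({t: np.log(v + 1e-12) for t, v in ors.items()}, labels).auc
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="on and one off"):
            roc_calibrate({"a": 0.1, "b": 0.2}, {"a": True, "b": True})

    def test_unlabeled_or_missing_or_rejected(self):
        with pytest.raises(ValueError, match="no odds ratio"):
            roc_calibrate({"a": 0.1}, {"a": True, "b": False})


class TestHeatmapExport:
    def _table(self):
        spec = {}
        for trig, strength in (("hi", 0.5), ("lo", 0.001)):
            for mouse in ("c1", "t1"):
                spec[(trig, mouse, 0.0)] = (0.0, 1.0)
                for tp in (1.0, 2.0):
                    spec[(trig, mouse, tp)] = (strength, 0.001)
        spec[("hi", "c1", 2.0)] = _blank()
        return _screen(spec)

    def test_structure_sorting_and_blanks(self):
        df = render_heatmap_table(self._table(), NULL)
        assert list(df.index) == ["hi", "lo"]  # hit fraction sorts first
        assert df.shape == (2, 6)  # 2 mice x 3 timepoints
        assert df.loc["hi", "c1_t2"] == ""  # insufficient coverage blank

    def test_byte_identical_rerun(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        render_heatmap_table(self._table(), NULL).to_csv(p1, sep="\t")
        render_heatmap_table(self._table(), NULL).to_csv(p2, sep="\t")
        assert p1.read_bytes() == p2.read_bytes()

    def test_top_k_limits_rows(self):
        df = render_heatmap_table(self._table(), NULL, top_k=1)
        assert list(df.index) == ["hi"]

    def test_summaries_rank_deterministically(self):
        df = summaries_frame(self._table(), NULL)
        assert list(df["trigger_id"]) == ["hi", "lo"]
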