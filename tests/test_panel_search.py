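import itertools

import numpy as np
import pytest

from panelstrat.panel_search import (
    PanelRule,
    PerfReport,
    SearchConfig,
    ThresholdCondition,
    apply_panel,
    candidate_thresholds,
    confusion,
    exhaustive_search,
    panel_performance,
    refit_thresholds,
)
from panelstrat.roc_analysis import cutoff_at_min_sensitivity, roc_curve
from tests.conftest import make_frame, random_frame


def _validation_high_se_panel():
    return PanelRule(
        conditions=(
            ThresholdCondition("wbc", ">", 10.0),
            ThresholdCondition("saa", ">", 10.6),
            ThresholdCondition("nihss", ">", 6.5),
        ),
        min_votes=1,
    )


class TestApplyPanel:
    def test_no_votes_non_infected(self):
        votes, pred = apply_panel(
            _validation_high_se_panel(), {"wbc": 8, "saa": 5, "nihss": 4}
        )
        assert votes == 0 and not pred

    def test_one_vote_fires_k1(self):
        votes, pred = apply_panel(
            _validation_high_se_panel(), {"wbc": 13, "saa": 5, "nihss": 4}
        )
        assert votes == 1 and pred

    def test_high_sp_panel_two_of_three(self):
        panel = PanelRule(
            conditions=(
                ThresholdCondition("wbc", ">", 13.33),
                ThresholdCondition("saa", ">", 41.0),
                ThresholdCondition("nihss", ">", 17.5),
            ),
            min_votes=2,
        )
        votes, pred = apply_panel(panel, {"wbc": 14, "saa": 50, "nihss": 10})
        assert votes == 2 and pred

    def test_missing_marker_raises(self):
        with pytest.raises(ValueError, match="missing panel marker"):
            apply_panel(_validation_high_se_panel(), {"wbc": 13})

    def test_invalid_min_votes_rejected(self):
        with pytest.raises(ValueError):
            PanelRule(conditions=(ThresholdCondition("x", ">", 1.0),), min_votes=2)

    def test_less_than_operator(self):
        cond = ThresholdCondition("x", "<", 5.0)
        assert cond.holds(4.0) and not cond.holds(5.0)


class TestPanelPerformance:
    def test_always_fires(self):
        frame = make_frame({"x": [1.0, 2.0, 3.0, 4.0]}, [0, 0, 1, 1])
        panel = PanelRule((ThresholdCondition("x", ">", float("-inf")),), 1)
        perf = panel_performance(panel, frame)
        assert perf.sensitivity == 1.0 and perf.specificity == 0.0

    def test_never_fires(self):
        frame = make_frame({"x": [1.0, 2.0, 3.0, 4.0]}, [0, 0, 1, 1])
        panel = PanelRule((ThresholdCondition("x", ">", float("inf")),), 1)
        perf = panel_performance(panel, frame)
        assert perf.sensitivity == 0.0 and perf.specificity == 1.0

    def test_self_consistent_with_apply_panel(self, validation_frame):
        panel = _validation_high_se_panel()
        perf = panel_performance(panel, validation_frame)
        preds = [
            apply_panel(panel, row)[1] for _, row in validation_frame.iterrows()
        ]
        recount = confusion(preds, validation_frame["infected"])
        assert perf == recount

    def test_counts_sum_to_cohort_size(self, validation_frame):
        perf = panel_performance(_validation_high_se_panel(), validation_frame)
        assert perf.tp + perf.fp + perf.tn + perf.fn == len(validation_frame)


class TestCandidateThresholds:
    def test_simple_midpoints(self):
        assert candidate_thresholds([1, 2, 3]) == [1.5, 2.5]

    def test_constant_column_empty(self):
        assert candidate_thresholds([4, 4, 4]) == []

    def test_thinning_monotone_subset(self):
        values = list(range(1, 102))
        full = candidate_thresholds(values, cap=1000)
        thin = candidate_thresholds(values, cap=10)
        assert len(thin) == 10
        assert thin == sorted(thin)
        assert set(thin) <= set(full)
        assert thin[0] == full[0] and thin[-1] == full[-1]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            candidate_thresholds([])


def _naive_search(frame, config: SearchConfig):
    """Quadruple-loop reference implementation with the same tie-break."""
    infected = frame["infected"].to_numpy(dtype=bool)
    n_pos, n_neg = infected.sum(), (~infected).sum()
    names = sorted(config.markers)
    grids = {}
    for m in names:
        op = config.directions.get(m, ">")
        cuts = candidate_thresholds(frame[m].to_numpy(dtype=float), cap=config.grid_cap)
        grids[m] = ([float("-inf")] + cuts) if op == ">" else (cuts + [float("inf")])
    if config.fix_marker_set:
        subsets = [tuple(names)]
    else:
        subsets = [
            s
            for size in range(1, min(config.max_panel_size, len(names)) + 1)
            for s in itertools.combinations(names, size)
        ]
    best_key, best = None, None
    feasible_found = False
    for subset in subsets:
        if any(len(grids[m]) == 0 for m in subset):
            continue
        for cutoffs in itertools.product(*(grids[m] for m in subset)):
            ks = range(1, len(subset) + 1) if config.free_k else [config.fixed_k]
            for k in ks:
                if k > len(subset):
                    continue
                votes = np.zeros(len(frame))
                for m, c in zip(subset, cutoffs):
                    vals = frame[m].to_numpy(dtype=float)
                    op = config.directions.get(m, ">")
                    votes += (vals > c) if op == ">" else (vals < c)
                pred = votes >= k
                se = (pred & infected).sum() / n_pos
                sp = (~pred & ~infected).sum() / n_neg
                constrained, objective = (se, sp) if config.objective == "high-se" else (sp, se)
                ok = constrained >= config.constraint - 1e-12
                if ok and not feasible_found:
                    feasible_found = True
                    best_key, best = None, None
                if feasible_found and not ok:
                    continue
                if feasible_found:
                    key = (-objective, -constrained, len(subset), subset, cutoffs, k)
                else:
                    key = (-constrained, -objective, len(subset), subset, cutoffs, k)
                if best_key is None or key < best_key:
                    best_key, best = key, (subset, cutoffs, k)
    subset, cutoffs, k = best
    panel = PanelRule(
        tuple(
            ThresholdCondition(m, config.directions.get(m, ">"), c)
            for m, c in zip(subset, cutoffs)
        ),
        k,
    )
    return panel, panel_performance(panel, frame), feasible_found


class TestExhaustiveSearch:
    def test_perfect_single_marker(self):
        frame = make_frame(
            {"a": [1, 2, 3, 10, 11, 12], "b": [5, 3, 1, 2, 6, 4]},
            [0, 0, 0, 1, 1, 1],
        )
        config = SearchConfig(markers=("a", "b"), constraint=0.9)
        panel, perf, log = exhaustive_search(frame, config)
        assert log["feasible"]
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0
        assert panel.markers() == ["a"]

    def test_single_marker_matches_roc_cutoff(self, validation_frame):
        # cross-module oracle: 1-marker k=1 search == constrained ROC point
        config = SearchConfig(markers=("saa",), constraint=0.9, grid_cap=10_000)
        panel, perf, log = exhaustive_search(validation_frame, config)
        curve = roc_curve(validation_frame["saa"], validation_frame["infected"])
        choice = cutoff_at_min_sensitivity(curve, 0.9)
        assert perf.sensitivity == pytest.approx(choice.sensitivity)
        assert perf.specificity == pytest.approx(choice.specificity)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_naive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 30))
        frame = random_frame(r, n, markers=("a", "b", "c"), discrete=True)
        config = SearchConfig(
            markers=("a", "b", "c"),
            objective="high-se" if seed % 2 == 0 else "high-sp",
            constraint=float(r.choice([0.6, 0.8, 0.95])),
            max_panel_size=3,
            grid_cap=8,
        )
        panel, perf, log = exhaustive_search(frame, config)
        naive_panel, naive_perf, naive_feasible = _naive_search(frame, config)
        assert log["feasible"] == naive_feasible
        assert panel == naive_panel
        assert perf == naive_perf

    def test_infeasible_constraint_flagged(self):
        frame = make_frame({"a": [1.0, 1.0, 1.0, 1.0]}, [0, 1, 0, 1])
        config = SearchConfig(markers=("a",), objective="high-sp", constraint=0.95)
        panel, perf, log = exhaustive_search(frame, config)
        assert not log["feasible"]

    def test_monotone_feasibility(self, validation_frame):
        sps_ = []
        for s in (0.7, 0.85, 0.95, 1.0):
            config = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=s)
            _, perf, log = exhaustive_search(validation_frame, config)
            if log["feasible"]:
                sps_.append(perf.specificity)
        assert all(a >= b - 1e-12 for a, b in zip(sps_, sps_[1:]))

    def test_deterministic(self, discovery_frame):
        config = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=0.95)
        first = exhaustive_search(discovery_frame, config)
        second = exhaustive_search(discovery_frame, config)
        assert first[0] == second[0]
        assert first[1] == second[1]

    def test_single_class_raises(self):
        frame = make_frame({"a": [1.0, 2.0]}, [1, 1])
        with pytest.raises(ValueError):
            exhaustive_search(frame, SearchConfig(markers=("a",)))


class TestRefitThresholds:
    def test_equals_full_search_on_fixed_set(self, validation_frame):
        config = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=0.95,
                              grid_cap=12)
        full_cfg = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=0.95,
                                grid_cap=12, fix_marker_set=True)
        refit = refit_thresholds(["saa", "wbc", "nihss"], validation_frame, config)
        full = exhaustive_search(validation_frame, full_cfg)
        assert refit[0] == full[0]

    def test_constraint_satisfied_when_feasible(self, validation_frame):
        config = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=0.95)
        panel, perf, log = refit_thresholds(
            ["saa", "wbc", "nihss"], validation_frame, config
        )
        if log["feasible"]:
            assert perf.sensitivity >= 0.95 - 1e-12

    def test_refit_objective_at_least_selection_objective(self, discovery_frame):
        config = SearchConfig(markers=("saa", "wbc", "nihss"), constraint=0.95,
                              max_panel_size=2)
        sel_panel, sel_perf, sel_log = exhaustive_search(discovery_frame, config)
        re_panel, re_perf, re_log = refit_thresholds(
            ["saa", "wbc", "nihss"], discovery_frame, config
        )
        if sel_log["feasible"] and re_log["feasible"]:
            assert re_perf.specificity >= sel_perf.specificity - 1e-12


class TestPerfReport:
    def test_se_sp_formulas(self):
        rep = PerfReport(tp=9, fp=3, tn=17, fn=1)
        assert rep.sensitivity == 0.9
        assert rep.specificity == 0.85
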