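"""End-to-end study orchestration: discovery -> validation protocol.

Each white-box method (association rules, decision tree, threshold panel)
selects a marker set on the discovery cohort; rules, cutoffs and trees are
then re-estimated on the validation cohort restricted to those markers, and
sensitivity/specificity are reported for both subgroups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time

import pandas as pd

from . import calibration, decision_tree, rule_mining, roc_analysis
from .panel_search import SearchConfig, confusion, exhaustive_search, refit_thresholds
from .synthetic_cohort import cohort_to_frame, generate_cohort, read_cohort_csv

logger = logging.getLogger("panelstrat")

__all__ = ["StudyConfig", "run_study", "compare_methods", "load_subgroups"]

DEFAULT_MARKERS = calibration.MARKERS


class StudyConfig(dict):
    """Plain dict subclass; exists so configs serialise/round-trip trivially."""


def _frame_hash(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def _log_stage(stage: str, frame: pd.DataFrame, seed, t0: float) -> None:
    logger.info(
        "stage=%s input_hash=%s seed=%s runtime=%.3fs",
        stage, _frame_hash(frame), seed, time.perf_counter() - t0,
    )


def load_subgroups(config: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(discovery frame, validation frame, provenance) from a study config.

    The config either names a cohort CSV (``cohort_csv``) containing both
    subgroups, or requests synthetic cohorts from the built-in calibration
    (``synthetic: true`` with ``seed``).
    """
    if "cohort_csv" in config:
        cohort = read_cohort_csv(config["cohort_csv"])
        frame = cohort_to_frame(cohort)
        prov = {"source": config["cohort_csv"]}
    else:
        seed = int(config.get("seed", 0))
        disc_spec, valid_spec = calibration.default_specs(seed)
        frame = pd.concat(
            [cohort_to_frame(generate_cohort(disc_spec)),
             cohort_to_frame(generate_cohort(valid_spec))],
            ignore_index=True,
        )
        prov = {"source": "synthetic", "seed": seed}
    disc = frame[frame["subgroup"] == "discovery"].reset_index(drop=True)
    valid = frame[frame["subgroup"] == "validation"].reset_index(drop=True)
    for name, sub in (("discovery", disc), ("validation", valid)):
        labels = sub["infected"].to_numpy(dtype=bool)
        if len(sub) == 0 or labels.all() or not labels.any():
            raise ValueError(f"subgroup {name!r} is missing a class")
    return disc, valid, prov


def _roc_table(disc: pd.DataFrame, valid: pd.DataFrame, markers, se_min: float) -> list[dict]:
    rows = []
    for marker in markers:
        row = {"marker": marker}
        for name, sub in (("discovery", disc), ("validation", valid)):
            curve = roc_analysis.roc_curve(
                sub[marker], sub["infected"], direction="higher", marker=marker
            )
            choice = roc_analysis.cutoff_at_min_sensitivity(curve, se_min)
            row[name] = {
                "auc": curve.auc,
                "sensitivity": choice.sensitivity,
                "specificity": choice.specificity,
                "cutoff": None if choice.low_information else choice.cutoff,
            }
        rows.append(row)
    return rows


def _rules_section(disc, valid, markers, cfg) -> dict:
    max_bins = int(cfg.get("max_bins", 4))
    max_lhs = int(cfg.get("max_lhs_size", 2))

    def fit(frame, marker_subset, min_conf):
        bins = {
            m: rule_mining.bin_numeric(frame[m], frame["infected"], max_bins=max_bins)
            for m in marker_subset
        }
        rules = rule_mining.mine_rules(
            frame, bins, min_confidence=min_conf, max_lhs_size=max_lhs
        )
        return rule_mining.build_classifier(rules, frame)

    def perf(classifier, frame):
        preds = [
            rule_mining.classify_with_rules(classifier, row)
            for _, row in frame.iterrows()
        ]
        return confusion(preds, frame["infected"].to_numpy(dtype=bool))

    # discovery: confidence-1 rules select the markers
    disc_clf = fit(disc, markers, float(cfg.get("min_confidence_discovery", 1.0)))
    selected = sorted({m for r in disc_clf.rules for m, _ in r.lhs}) or list(markers)
    # validation: re-mine restricted to the selected markers, relaxed confidence
    valid_clf = fit(valid, selected, float(cfg.get("min_confidence_validation", 0.5)))
    return {
        "method": "association-rules",
        "selected_markers": selected,
        "discovery": perf(disc_clf, disc).to_dict(),
        "validation": perf(valid_clf, valid).to_dict(),
        "rules": {
            "discovery": [
                {"display": r.display(), "support": r.support,
                 "confidence": r.confidence, "lift": r.lift}
                for r in disc_clf.rules
            ],
            "validation": [
                {"display": r.display(), "support": r.support,
                 "confidence": r.confidence, "lift": r.lift}
                for r in valid_clf.rules
            ],
        },
    }


def _tree_section(disc, valid, markers, cfg) -> dict:
    min_leaf_disc = int(cfg.get("min_leaf_discovery", 4))
    min_leaf_valid = int(cfg.get("min_leaf_validation", 9))
    disc_tree = decision_tree.grow_tree(disc, markers, min_leaf=min_leaf_disc)
    selected = decision_tree.tree_markers(disc_tree) or list(markers)
    valid_tree = decision_tree.grow_tree(valid, selected, min_leaf=min_leaf_valid)
    return {
        "method": "decision-tree",
        "selected_markers": selected,
        "discovery": decision_tree.tree_performance(disc_tree, disc).to_dict(),
        "validation": decision_tree.tree_performance(valid_tree, valid).to_dict(),
        "trees": {
            "discovery": decision_tree.tree_to_dict(disc_tree),
            "validation": decision_tree.tree_to_dict(valid_tree),
        },
    }


def _panel_section(disc, valid, markers, cfg, objective: str) -> dict:
    config = SearchConfig(
        markers=tuple(markers),
        objective=objective,
        constraint=float(cfg.get("constraint", 0.95)),
        max_panel_size=int(cfg.get("max_panel_size", 3)),
        grid_cap=int(cfg.get("grid_cap", 25)),
    )
    disc_panel, disc_perf, disc_log = exhaustive_search(disc, config)
    selected = sorted(disc_panel.markers())
    valid_panel, valid_perf, valid_log = refit_thresholds(selected, valid, config)
    return {
        "method": f"threshold-panel-{objective}",
        "selected_markers": selected,
        "discovery": disc_perf.to_dict(),
        "validation": valid_perf.to_dict(),
        "panels": {
            "discovery": {**disc_panel.to_dict(), "display": disc_panel.display(),
                          "feasible": disc_log["feasible"]},
            "validation": {**valid_panel.to_dict(), "display": valid_panel.display(),
                           "feasible": valid_log["feasible"]},
        },
    }


def run_study(config: dict) -> dict:
    """Run the full discovery -> validation protocol and return a StudyReport.

    The report is a JSON-serialisable dict with a per-marker ROC table, one
    section per method (selected markers + SE/SP on both subgroups), the
    fitted panels, a method ranking, and a provenance block sufficient to
    re-run the study.
    """
    t0 = time.perf_counter()
    disc, valid, prov = load_subgroups(config)
    markers = list(config.get("markers", DEFAULT_MARKERS))
    se_min = float(config.get("se_min", 0.9))
    _log_stage("load", pd.concat([disc, valid]), config.get("seed"), t0)

    sections = []
    for name, builder in (
        ("rules", lambda: _rules_section(disc, valid, markers, config.get("rules", {}))),
        ("tree", lambda: _tree_section(disc, valid, markers, config.get("tree", {}))),
        ("panel-high-se", lambda: _panel_section(disc, valid, markers,
                                                 config.get("panel", {}), "high-se")),
        ("panel-high-sp", lambda: _panel_section(disc, valid, markers,
                                                 config.get("panel", {}), "high-sp")),
    ):
        t_stage = time.perf_counter()
        sections.append(builder())
        _log_stage(name, disc, config.get("seed"), t_stage)

    report = {
        "roc": _roc_table(disc, valid, markers, se_min),
        "methods": sections,
        "ranking": compare_methods({"methods": sections}),
        "provenance": {
            **prov,
            "config": {k: v for k, v in config.items()},
            "n_discovery": int(len(disc)),
            "n_validation": int(len(valid)),
        },
    }
    # guarantee JSON round-trip
    return json.loads(json.dumps(report))


def compare_methods(report: dict) -> list[dict]:
    """Rank methods by cross-subgroup stability (smaller drift is stabler).

    stability = |SE_disc - SE_valid| + |SP_disc - SP_valid|; ties and the
    final ordering fall back to method name for determinism.
    """
    rows = []
    for section in report["methods"]:
        d, v = section["discovery"], section["validation"]
        drift = abs(d["sensitivity"] - v["sensitivity"]) + abs(
            d["specificity"] - v["specificity"]
        )
        rows.append({"method": section["method"], "stability": drift})
    rows.sort(key=lambda r: (r["stability"], r["method"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
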