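"""Class-association-rule mining and a rule-set classifier.

Numeric markers are discretised into contiguous intervals by recursive
entropy-minimising binary splits; rules are conjunctions of per-marker
interval conditions targeting one of the two outcome classes, scored with
support, confidence and lift (confidence / consequent prevalence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Interval",
    "AssociationRule",
    "RuleClassifier",
    "bin_numeric",
    "assign_bins",
    "rule_metrics",
    "mine_rules",
    "classify_with_rules",
]


@dataclass(frozen=True, order=True)
class Interval:
    """Closed-open interval [lo, hi); lo may be -inf and hi may be +inf."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"interval requires lo < hi, got [{self.lo}, {self.hi})")

    def __contains__(self, x: float) -> bool:
        return self.lo <= x < self.hi

    def display(self) -> str:
        lo = "-Inf" if self.lo == -math.inf else f"{self.lo:g}"
        hi = "Inf" if self.hi == math.inf else f"{self.hi:g}"
        return f"[{lo},{hi})"


@dataclass(frozen=True)
class AssociationRule:
    lhs: tuple[tuple[str, Interval], ...]  # sorted by marker name
    rhs_class: bool  # True = infected
    support: float
    confidence: float
    lift: float

    def display(self) -> str:
        conds = ", ".join(f"{{{m} = {iv.display()}}}" for m, iv in self.lhs)
        rhs = "yes" if self.rhs_class else "no"
        return f"{conds} => {{infection = {rhs}}}"


@dataclass(frozen=True)
class RuleClassifier:
    rules: tuple[AssociationRule, ...]
    default_class: bool


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _split_entropy(values: np.ndarray, labels: np.ndarray, cut: float) -> float:
    left = values < cut
    n = len(values)
    e = 0.0
    for mask in (left, ~left):
        sub = labels[mask]
        counts = np.array([(~sub).sum(), sub.sum()], dtype=float)
        e += mask.sum() / n * _entropy(counts)
    return e


def bin_numeric(values, labels, max_bins: int = 4) -> list[Interval]:
    """Supervised discretisation into at most ``max_bins`` contiguous intervals.

    Cut points are midpoints between adjacent distinct values, chosen by
    recursive entropy-minimising binary splits; splitting stops when no cut
    reduces class entropy or ``max_bins`` is reached.  Degenerate
    supervision (single class, or no entropy-reducing cut on non-constant
    data) falls back to equal-frequency quartile cuts.  The returned
    intervals always partition the whole real line.
    """
    if max_bins < 2:
        raise ValueError("max_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if np.unique(values).size <= 1:
        return [Interval(-math.inf, math.inf)]
    if labels.all() or not labels.any():
        cuts = _quartile_cuts(values)
    else:
        cuts = sorted(_entropy_cuts(values, labels, max_bins))
        if not cuts:
            cuts = _quartile_cuts(values)
    bounds = [-math.inf] + cuts + [math.inf]
    return [Interval(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])]


def _quartile_cuts(values: np.ndarray) -> list[float]:
    qs = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return sorted(set(float(q) for q in qs if values.min() < q < values.max()))


def _entropy_cuts(values: np.ndarray, labels: np.ndarray, max_bins: int) -> list[float]:
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        if len(cuts) + 1 >= max_bins:
            return
        vals, labs = values[mask], labels[mask]
        distinct = np.unique(vals)
        if distinct.size <= 1:
            return
        base = _entropy(np.array([(~labs).sum(), labs.sum()], dtype=float))
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
        best_cut, best_e = None, base - 1e-12
        for c in candidates:
            e = _split_entropy(vals, labs, c)
            if e < best_e:
                best_cut, best_e = float(c), e
        if best_cut is None:
            return
        cuts.append(best_cut)
        # larger (more impure) side first is irrelevant for determinism:
        # recursion order is fixed left-then-right
        recurse(mask & (values < best_cut))
        recurse(mask & (values >= best_cut))

    recurse(np.ones_like(labels, dtype=bool))
    return cuts


def assign_bins(frame, bins: dict[str, list[Interval]]):
    """Map each patient's marker values onto interval indices (dict of arrays)."""
    out = {}
    for marker, intervals in bins.items():
        vals = frame[marker].to_numpy(dtype=float)
        idx = np.zeros(len(vals), dtype=int)
        for i, iv in enumerate(intervals):
            idx[(vals >= iv.lo) & (vals < iv.hi)] = i
        out[marker] = idx
    return out


def _lhs_mask(frame, lhs) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for marker, iv in lhs:
        vals = frame[marker].to_numpy(dtype=float)
        mask &= (vals >= iv.lo) & (vals < iv.hi)
    return mask


def rule_metrics(lhs, rhs_class: bool, frame) -> tuple[float, float, float]:
    """(support, confidence, lift) of a rule on a cohort frame.

    support = n(A and B)/N, confidence = n(A and B)/n(A) and
    lift = confidence / prevalence(B); lift equals 1 exactly when the
    antecedent and the consequent are statistically independent.
    """
    n = len(frame)
    if n == 0:
        raise ValueError("rule_metrics: empty cohort")
    infected = frame["infected"].to_numpy(dtype=bool)
    a = _lhs_mask(frame, lhs)
    b = infected if rhs_class else ~infected
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("rule_metrics: no patient satisfies the rule antecedent")
    support = int((a & b).sum()) / n
    confidence = int((a & b).sum()) / n_a
    prevalence = int(b.sum()) / n
    lift = confidence / prevalence
    return support, confidence, lift


def _rule_sort_key(rule: AssociationRule):
    return (
        -rule.confidence,
        -rule.support,
        -rule.lift,
        tuple((m, iv.lo, iv.hi) for m, iv in rule.lhs),
        rule.rhs_class,
    )


def mine_rules(
    frame,
    bins: dict[str, list[Interval]],
    min_support: float = 0.0,
    min_confidence: float = 1.0,
    max_lhs_size: int = 2,
) -> list[AssociationRule]:
    """Exhaustively enumerate interval-conjunction rules meeting the constraints.

    All conjunctions of at most ``max_lhs_size`` conditions over distinct
    markers are scored against both consequent classes; rules passing the
    support/confidence thresholds are returned sorted by (confidence desc,
    support desc, lift desc, lexicographic LHS).
    """
    from itertools import combinations, product

    if len(frame) == 0:
        raise ValueError("mine_rules: empty cohort")
    markers = sorted(bins)
    infected = frame["infected"].to_numpy(dtype=bool)
    n = len(frame)
    prevalence = {True: infected.sum() / n, False: (~infected).sum() / n}

    # precompute per-condition masks
    cond_masks = {
        (m, iv): _lhs_mask(frame, [(m, iv)]) for m in markers for iv in bins[m]
    }

    rules: list[AssociationRule] = []
    for size in range(1, max_lhs_size + 1):
        for marker_set in combinations(markers, size):
            for ivs in product(*(bins[m] for m in marker_set)):
                lhs = tuple(zip(marker_set, ivs))
                mask = np.ones(n, dtype=bool)
                for cond in lhs:
                    mask &= cond_masks[cond]
                n_a = int(mask.sum())
                if n_a == 0:
                    continue
                for rhs in (False, True):
                    b = infected if rhs else ~infected
                    n_ab = int((mask & b).sum())
                    support = n_ab / n
                    confidence = n_ab / n_a
                    if support < min_support or confidence < min_confidence:
                        continue
                    if prevalence[rhs] == 0:
                        continue
                    rules.append(
                        AssociationRule(
                            lhs=lhs,
                            rhs_class=rhs,
                            support=support,
                            confidence=confidence,
                            lift=confidence / prevalence[rhs],
                        )
                    )
    rules.sort(key=_rule_sort_key)
    return rules


def classify_with_rules(classifier: RuleClassifier, patient) -> bool:
    """Predict a patient's class: first matching rule fires, else the default.

    ``patient`` is a mapping from marker name to value.  A marker required
    by a rule but absent from the patient skips that rule; if every rule is
    skipped for that reason an error is raised.
    """
    if not classifier.rules:
        return classifier.default_class
    any_evaluable = False
    for rule in classifier.rules:
        try:
            values = [float(patient[m]) for m, _ in rule.lhs]
        except (KeyError, TypeError):
            continue
        any_evaluable = True
        if all(v in iv for v, (_, iv) in zip(values, rule.lhs)):
            return rule.rhs_class
    if not any_evaluable:
        raise ValueError("patient is missing every marker used by the rule set")
    return classifier.default_class


def build_classifier(rules, frame) -> RuleClassifier:
    """Rule classifier with the training majority class as default."""
    infected = frame["infected"].to_numpy(dtype=bool)
    # ties resolve to non-infected, the triage-safe default
    default = infected.sum() > (~infected).sum()
    return RuleClassifier(rules=tuple(rules), default_class=bool(default))
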