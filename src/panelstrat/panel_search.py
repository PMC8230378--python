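"""Exhaustive k-of-n threshold-panel search.

A panel is a set of per-marker threshold conditions plus a vote count k:
a patient is called infected when at least k conditions hold.  The search
enumerates marker subsets, per-marker cutoff grids and k, and optimises
specificity at a fixed minimum sensitivity (high-SE mode) or sensitivity at
a fixed minimum specificity (high-SP mode).  Enumeration over the cutoff
grids is vectorised with boolean condition matrices so that paper-scale
searches (7 candidate markers, panels of up to 3, grids of ~25 cutoffs)
finish in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "ThresholdCondition",
    "PanelRule",
    "SearchConfig",
    "PerfReport",
    "confusion",
    "apply_panel",
    "panel_performance",
    "candidate_thresholds",
    "exhaustive_search",
    "refit_thresholds",
]


@dataclass(frozen=True)
class ThresholdCondition:
    marker: str
    op: str  # ">" or "<"
    cutoff: float

    def __post_init__(self) -> None:
        if self.op not in (">", "<"):
            raise ValueError(f"unknown operator {self.op!r}")

    def holds(self, value: float) -> bool:
        return value > self.cutoff if self.op == ">" else value < self.cutoff

    def display(self) -> str:
        return f"{self.marker.upper()} {self.op} {self.cutoff:g}"


@dataclass(frozen=True)
class PanelRule:
    conditions: tuple[ThresholdCondition, ...]
    min_votes: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_votes <= len(self.conditions)):
            raise ValueError(
                f"min_votes {self.min_votes} outside [1, {len(self.conditions)}]"
            )

    def markers(self) -> list[str]:
        return [c.marker for c in self.conditions]

    def display(self) -> str:
        conds = " and ".join(c.display() for c in self.conditions)
        return f"{conds} (infection when >={self.min_votes})"

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"marker": c.marker, "op": c.op, "cutoff": c.cutoff}
                for c in self.conditions
            ],
            "min_votes": self.min_votes,
        }


@dataclass(frozen=True)
class SearchConfig:
    markers: tuple[str, ...]
    objective: str = "high-se"  # "high-se": max SP s.t. SE >= s; "high-sp": max SE s.t. SP >= s
    constraint: float = 0.95
    max_panel_size: int = 3
    grid_cap: int = 25
    directions: dict = field(default_factory=dict)  # marker -> ">" (default) or "<"
    fix_marker_set: bool = False  # use exactly `markers` (threshold refit mode)
    free_k: bool = True  # enumerate k; when False k is fixed to fixed_k
    fixed_k: int = 1

    def __post_init__(self) -> None:
        if self.objective not in ("high-se", "high-sp"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if not (0.0 < self.constraint <= 1.0):
            raise ValueError("constraint must lie in (0, 1]")
        if self.max_panel_size < 1 or self.grid_cap < 1:
            raise ValueError("max_panel_size and grid_cap must be >= 1")


@dataclass(frozen=True)
class PerfReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def confusion(predicted, infected) -> PerfReport:
    predicted = np.asarray(predicted, dtype=bool)
    infected = np.asarray(infected, dtype=bool)
    return PerfReport(
        tp=int((predicted & infected).sum()),
        fp=int((predicted & ~infected).sum()),
        tn=int((~predicted & ~infected).sum()),
        fn=int((~predicted & infected).sum()),
    )


def apply_panel(panel: PanelRule, patient) -> tuple[int, bool]:
    """(votes, predicted class) for one patient (mapping marker -> value)."""
    votes = 0
    for cond in panel.conditions:
        try:
            value = float(patient[cond.marker])
        except (KeyError, TypeError):
            raise ValueError(f"patient is missing panel marker {cond.marker!r}") from None
        votes += cond.holds(value)
    return votes, votes >= panel.min_votes


def panel_performance(panel: PanelRule, frame) -> PerfReport:
    """Exact confusion counts of a panel applied to every cohort patient."""
    infected = frame["infected"].to_numpy(dtype=bool)
    votes = np.zeros(len(frame), dtype=int)
    for cond in panel.conditions:
        vals = frame[cond.marker].to_numpy(dtype=float)
        votes += (vals > cond.cutoff) if cond.op == ">" else (vals < cond.cutoff)
    return confusion(votes >= panel.min_votes, infected)


def candidate_thresholds(values, cap: int = 25) -> list[float]:
    """Midpoints between consecutive distinct values, thinned to ``cap``.

    Thinning keeps the two extreme midpoints and spaces the rest evenly by
    rank, so the result is always a monotone subset of the full midpoint
    grid.  Constant input yields an empty grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("candidate_thresholds: empty input")
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    if mids.size <= cap:
        return [float(m) for m in mids]
    idx = np.unique(np.round(np.linspace(0, mids.size - 1, cap)).astype(int))
    return [float(m) for m in mids[idx]]


def _condition_matrix(vals: np.ndarray, cutoffs: list[float], op: str) -> np.ndarray:
    grid = np.asarray(cutoffs)
    if op == ">":
        return vals[:, None] > grid[None, :]
    return vals[:, None] < grid[None, :]


def _better(a: tuple, b: tuple | None) -> bool:
    """Candidate ordering; ``a``/``b`` are comparison keys (see _key)."""
    return b is None or a < b


def _key(primary: float, secondary: float, n_markers: int, markers: tuple,
         cutoffs: tuple, k: int) -> tuple:
    # maximise primary then secondary; prefer fewer markers; then lexicographic
    return (-primary, -secondary, n_markers, markers, cutoffs, k)


def exhaustive_search(frame, config: SearchConfig):
    """Optimal panel over all subsets x cutoff grids x vote counts.

    Returns ``(panel, perf, log)`` where ``log`` records feasibility, the
    number of panels evaluated and the constraint.  When no panel meets the
    constraint the best-effort panel maximising the constrained metric is
    returned with ``log['feasible'] = False``.
    """
    infected = frame["infected"].to_numpy(dtype=bool)
    n_pos = int(infected.sum())
    n_neg = int((~infected).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("exhaustive_search: both classes must be present")

    grids: dict[str, list[float]] = {}
    mats: dict[str, np.ndarray] = {}
    for marker in config.markers:
        vals = frame[marker].to_numpy(dtype=float)
        op = config.directions.get(marker, ">")
        cuts = candidate_thresholds(vals, cap=config.grid_cap)
        # a -inf sentinel makes the always-true condition available, so the
        # trivial SE=1/SP=0 panel is in the search space (mirrors the ROC
        # curve's trivial endpoint)
        cuts = [float("-inf")] + cuts if op == ">" else cuts + [float("inf")]
        grids[marker] = cuts
        mats[marker] = _condition_matrix(vals, cuts, op)
    if all(len(g) == 0 for g in grids.values()):
        raise ValueError("exhaustive_search: empty cutoff grid for every marker")

    if config.fix_marker_set:
        subsets = [tuple(sorted(config.markers))]
    else:
        names = sorted(config.markers)
        subsets = [
            s
            for size in range(1, min(config.max_panel_size, len(names)) + 1)
            for s in combinations(names, size)
        ]

    best_key = None
    best = None  # (markers, cutoff tuple, k)
    best_feasible = False
    n_evaluated = 0

    for subset in subsets:
        sub_mats = [mats[m] for m in subset]
        if any(m.shape[1] == 0 for m in sub_mats):
            continue
        # votes tensor: patients x grid1 x grid2 x ...
        votes = None
        for axis, mat in enumerate(sub_mats):
            shape = [len(frame)] + [1] * len(sub_mats)
            shape[axis + 1] = mat.shape[1]
            term = mat.reshape(shape).astype(np.int8)
            votes = term if votes is None else votes + term
        ks = range(1, len(subset) + 1) if config.free_k else [config.fixed_k]
        for k in ks:
            if not config.free_k and k > len(subset):
                continue
            pred = votes >= k  # patients x grids...
            tp = np.tensordot(infected.astype(np.int64), pred, axes=(0, 0))
            fp = np.tensordot((~infected).astype(np.int64), pred, axes=(0, 0))
            se = tp / n_pos
            sp = (n_neg - fp) / n_neg
            n_evaluated += se.size
            if config.objective == "high-se":
                constrained, objective = se, sp
            else:
                constrained, objective = sp, se
            feasible = constrained >= config.constraint - 1e-12

            def consider(mask: np.ndarray, primary: np.ndarray, secondary: np.ndarray) -> None:
                nonlocal best_key, best
                if not mask.any():
                    return
                pbest = primary[mask].max()
                at = mask & (primary >= pbest - 1e-15)
                sbest = secondary[at].max()
                at &= secondary >= sbest - 1e-15
                idxs = np.argwhere(at)
                # lexicographically smallest cutoff index tuple
                idx = tuple(idxs[0]) if len(idxs) == 1 else tuple(
                    min(map(tuple, idxs))
                )
                cutoffs = tuple(grids[m][i] for m, i in zip(subset, idx))
                key = _key(pbest, sbest, len(subset), subset, cutoffs, k)
                if _better(key, best_key):
                    best_key = key
                    best = (subset, cutoffs, k)

            if feasible.any():
                if not best_feasible:
                    best_key, best = None, None  # drop best-effort candidates
                    best_feasible = True
                consider(feasible, objective, constrained)
            elif not best_feasible:
                # best effort: maximise the constrained metric itself
                consider(np.ones_like(feasible, dtype=bool), constrained, objective)

    assert best is not None
    subset, cutoffs, k = best
    panel = PanelRule(
        conditions=tuple(
            ThresholdCondition(marker=m, op=config.directions.get(m, ">"), cutoff=c)
            for m, c in zip(subset, cutoffs)
        ),
        min_votes=k,
    )
    perf = panel_performance(panel, frame)
    log = {
        "feasible": best_feasible,
        "objective": config.objective,
        "constraint": config.constraint,
        "n_panels_evaluated": int(n_evaluated),
    }
    return panel, perf, log


def refit_thresholds(markers, frame, config: SearchConfig):
    """Re-estimate cutoffs (and k) for a fixed marker set on a new cohort."""
    cfg = SearchConfig(
        markers=tuple(sorted(markers)),
        objective=config.objective,
        constraint=config.constraint,
        max_panel_size=len(markers),
        grid_cap=config.grid_cap,
        directions=config.directions,
        fix_marker_set=True,
        free_k=config.free_k,
        fixed_k=config.fixed_k,
    )
    return exhaustive_search(frame, cfg)
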