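"""Built-in cohort calibrations from the published demographic tables.

Each marker carries its class-conditional ``(median, q1, q3)`` for the
discovery subgroup (40 patients: 19 non-infected / 21 infected) and the
validation subgroup (243 patients: 204 non-infected / 39 infected).
These numbers are inputs to the generator, not fitted quantities.
"""

from __future__ import annotations

from .synthetic_cohort import CohortSpec, MarkerDistSpec

__all__ = ["discovery_spec", "validation_spec", "default_specs", "MARKERS"]

#: numeric candidate predictors used throughout the analyses
MARKERS = ["saa", "crp", "pct", "wbc", "monocytes", "nihss", "temperature"]

# (family, non-infected (median, q1, q3), infected (median, q1, q3))
_DISCOVERY = {
    "age":         ("normal",                (78.26, 74.5, 80.5),    (80.4, 69.5, 83.0)),
    "nihss":       ("discretized-lognormal", (3.0, 2.0, 7.0),        (12.0, 4.0, 14.0)),
    "temperature": ("normal",                (37.1, 36.9, 37.3),     (36.8, 36.2, 37.2)),
    "wbc":         ("lognormal",             (7.66, 6.3, 9.2),       (9.3, 7.4, 11.2)),
    "crp":         ("lognormal",             (3.6, 3.0, 6.65),       (4.8, 3.0, 17.4)),
    "monocytes":   ("lognormal",             (0.38, 0.32, 0.51),     (0.44, 0.32, 0.52)),
    "pct":         ("lognormal",             (0.013, 0.012, 0.02),   (0.017, 0.012, 0.028)),
    "saa":         ("lognormal",             (4.27, 2.32, 8.39),     (16.8, 7.1, 81.4)),
}

_VALIDATION = {
    "age":         ("normal",                (74.0, 60.3, 81.6),     (76.07, 68.7, 81.9)),
    "nihss":       ("discretized-lognormal", (4.0, 2.0, 8.0),        (9.0, 5.5, 18.5)),
    "temperature": ("normal",                (37.0, 36.6, 37.5),     (37.1, 36.8, 37.3)),
    "wbc":         ("lognormal",             (7.8, 6.4, 9.4),        (9.77, 7.75, 11.7)),
    "crp":         ("lognormal",             (3.0, 3.0, 5.7),        (5.6, 3.0, 15.8)),
    "monocytes":   ("lognormal",             (0.38, 0.29, 0.48),     (0.38, 0.31, 0.51)),
    "pct":         ("lognormal",             (0.02, 0.012, 0.02),    (0.02, 0.01, 0.03)),
    "saa":         ("lognormal",             (4.97, 2.52, 12.7),     (16.7, 4.7, 89.2)),
}

# CVRF flag prevalence per class, derived from the printed "n (%)" rows.
# Discovery: hypertension 12/19 non-infected, 19/21 infected; etc.
_DISCOVERY_CVRF = {
    "hypertension":       (12 / 19, 19 / 21),
    "atrial_fibrillation": (3 / 19, 6 / 21),
    "smoking":            (5 / 19, 6 / 21),
    "diabetes":           (4 / 19, 3 / 21),
    "coronary_disease":   (4 / 19, 6 / 21),
}

_VALIDATION_CVRF = {
    "hypertension":       (147 / 204, 35 / 39),
    "atrial_fibrillation": (35 / 204, 13 / 39),
    "smoking":            (75 / 204, 18 / 39),
    "diabetes":           (39 / 204, 9 / 39),
    "coronary_disease":   (46 / 204, 5 / 39),
}


def _markers(table: dict) -> tuple[MarkerDistSpec, ...]:
    return tuple(
        MarkerDistSpec(marker_name=name, family=family, non_infected=no, infected=yes)
        for name, (family, no, yes) in table.items()
    )


def discovery_spec(seed: int = 0) -> CohortSpec:
    """Discovery subgroup: 40 patients, 19 non-infected / 21 infected."""
    return CohortSpec(
        subgroup="discovery",
        n_total=40,
        n_infected=21,
        markers=_markers(_DISCOVERY),
        female_fraction=(9 / 19, 9 / 21),
        cvrf=_DISCOVERY_CVRF,
        seed=seed,
    )


def validation_spec(seed: int = 0) -> CohortSpec:
    """Validation subgroup: 243 patients, 204 non-infected / 39 infected."""
    return CohortSpec(
        subgroup="validation",
        n_total=243,
        n_infected=39,
        markers=_markers(_VALIDATION),
        female_fraction=(72 / 204, 25 / 39),
        cvrf=_VALIDATION_CVRF,
        seed=seed,
    )


def default_specs(seed: int = 0) -> tuple[CohortSpec, CohortSpec]:
    """(discovery, validation) specs with decorrelated per-subgroup seeds."""
    return discovery_spec(seed), validation_spec(seed + 1_000_003)
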