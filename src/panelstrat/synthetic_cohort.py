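"""Synthetic patient cohorts calibrated to published summary statistics.

Patient-level data for the study cohorts are not deposited; only per-class
median/IQR summaries and class counts are available.  This module fits
two-parameter distributions to those summaries (lognormal for right-skewed
labs, normal for temperature and age, discretized lognormal for the NIHSS
score) and draws reproducible cohorts with exact class counts, so that every
downstream analysis stage can be exercised without external data.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import stats as sps

__all__ = [
    "MarkerDistSpec",
    "CohortSpec",
    "PatientRecord",
    "Cohort",
    "CalibrationError",
    "CohortConfigError",
    "CohortParseError",
    "fit_lognormal_from_quantiles",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "cohort_to_frame",
]

#: z-score of the 75th percentile of the standard normal; 2*Z75 converts an
#: IQR on the log scale into a lognormal sigma.
Z75 = float(sps.norm.ppf(0.75))

#: canonical CSV column order (extra columns are appended after these)
CSV_COLUMNS = [
    "id", "subgroup", "infected", "age", "sex", "nihss", "temperature",
    "saa", "crp", "pct", "wbc", "monocytes",
]

#: numeric markers in generation order (fixed for seed determinism)
NUMERIC_MARKERS = [
    "age", "nihss", "temperature", "saa", "crp", "pct", "wbc", "monocytes",
]

FAMILIES = ("lognormal", "normal", "discretized-lognormal")

NIHSS_MAX = 42
CRP_FLOOR = 3.0


class CalibrationError(ValueError):
    """Summary statistics cannot be turned into distribution parameters."""


class CohortConfigError(ValueError):
    """A CohortSpec is incomplete or inconsistent."""


class CohortParseError(ValueError):
    """A cohort CSV cell cannot be parsed; message names row and column."""


def fit_lognormal_from_quantiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit (mu, sigma) of a lognormal from its median and quartiles.

    ``mu = ln(median)`` and ``sigma = (ln q3 - ln q1) / (2 * Z75)``: the
    fitted distribution reproduces the requested median exactly and the
    requested quartile ratio ``q3/q1`` exactly.  When the printed quartiles
    are not symmetric around the median on the log scale a two-parameter
    lognormal cannot match all three values; the median and IQR width in
    log space are prioritised.

    Returns ``(mu, 0.0)`` for the degenerate point-mass case
    ``q1 == median == q3``.
    """
    if median <= 0 or q1 <= 0 or q3 <= 0:
        raise CalibrationError(
            f"lognormal fit requires positive quantiles, got ({median}, {q1}, {q3})"
        )
    if not (q1 <= median <= q3):
        raise CalibrationError(
            f"quantiles must satisfy q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    if q1 == q3:
        if q1 != median:
            raise CalibrationError(
                f"inconsistent quantiles: q1 == q3 == {q1} but median == {median}"
            )
        return float(np.log(median)), 0.0
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * Z75))
    return mu, sigma


def normal_params_from_quantiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Normal (mean, sd) with mean = median and sd matched to the IQR."""
    if not (q1 <= median <= q3):
        raise CalibrationError(
            f"quantiles must satisfy q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    return float(median), float((q3 - q1) / (2.0 * Z75))


@dataclass(frozen=True)
class MarkerDistSpec:
    """Class-conditional summary of one marker: (median, q1, q3) per class."""

    marker_name: str
    family: str
    infected: tuple[float, float, float]      # (median, q1, q3)
    non_infected: tuple[float, float, float]  # (median, q1, q3)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CohortConfigError(
                f"{self.marker_name}: unknown family {self.family!r}"
            )
        for label, (med, q1, q3) in (
            ("infected", self.infected),
            ("non_infected", self.non_infected),
        ):
            if not (q1 <= med <= q3):
                raise CalibrationError(
                    f"{self.marker_name}/{label}: need q1 <= median <= q3, "
                    f"got ({med}, {q1}, {q3})"
                )
            if self.family in ("lognormal", "discretized-lognormal") and min(med, q1, q3) <= 0:
                raise CalibrationError(
                    f"{self.marker_name}/{label}: lognormal summaries must be positive"
                )

    def params(self, infected: bool) -> tuple[float, float]:
        med, q1, q3 = self.infected if infected else self.non_infected
        if self.family == "normal":
            return normal_params_from_quantiles(med, q1, q3)
        return fit_lognormal_from_quantiles(med, q1, q3)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one subgroup-shaped cohort."""

    subgroup: str
    n_total: int
    n_infected: int
    markers: tuple[MarkerDistSpec, ...]
    female_fraction: tuple[float, float] = (0.5, 0.5)  # (non-infected, infected)
    cvrf: dict[str, tuple[float, float]] = field(default_factory=dict)
    toast: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subgroup not in ("discovery", "validation"):
            raise CohortConfigError(f"unknown subgroup {self.subgroup!r}")
        if not (0 <= self.n_infected <= self.n_total):
            raise CohortConfigError(
                f"need 0 <= n_infected <= n_total, got {self.n_infected}/{self.n_total}"
            )
        for name, pair in [("female_fraction", self.female_fraction)] + list(self.cvrf.items()):
            for p in pair:
                if not (0.0 <= p <= 1.0):
                    raise CohortConfigError(f"{name}: proportion {p} outside [0, 1]")

    def marker(self, name: str) -> MarkerDistSpec:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise CohortConfigError(f"no MarkerDistSpec for required marker {name!r}")


@dataclass
class PatientRecord:
    id: str
    subgroup: str
    infected: bool
    age: float
    sex: str
    nihss: int
    temperature: float
    saa: float
    crp: float
    pct: float
    wbc: float
    monocytes: float
    cvrf: dict[str, bool] = field(default_factory=dict)
    toast: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.nihss, (int, np.integer)):
            raise CohortParseError(f"patient {self.id}: nihss must be an integer")
        if not (0 <= self.nihss <= NIHSS_MAX):
            raise ValueError(f"patient {self.id}: nihss {self.nihss} outside [0, {NIHSS_MAX}]")
        for name in ("age", "temperature", "saa", "crp", "pct", "wbc", "monocytes"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"patient {self.id}: {name}={v} not finite and >= 0")


@dataclass
class Cohort:
    records: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self.records == other.records


def _draw_marker(spec: MarkerDistSpec, n: int, infected: bool, rng: np.random.Generator) -> np.ndarray:
    loc, scale = spec.params(infected)
    if spec.family == "normal":
        values = rng.normal(loc, scale, size=n)
    else:
        values = np.exp(rng.normal(loc, scale, size=n))
    if spec.family == "discretized-lognormal":
        values = np.clip(np.rint(values), 0, NIHSS_MAX)
    if spec.marker_name == "crp":
        values = np.maximum(values, CRP_FLOOR)
    return np.maximum(values, 0.0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort with exactly the spec's class counts.

    Markers are drawn independently within class (the summaries carry no
    correlation structure), in a fixed class/marker order so that identical
    (spec, seed) pairs produce identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = "D" if spec.subgroup == "discovery" else "V"
    records: list[PatientRecord] = []
    counter = 0
    for infected, n_class in (
        (False, spec.n_total - spec.n_infected),
        (True, spec.n_infected),
    ):
        if n_class == 0:
            continue
        draws = {
            name: _draw_marker(spec.marker(name), n_class, infected, rng)
            for name in NUMERIC_MARKERS
        }
        p_female = spec.female_fraction[1 if infected else 0]
        female = rng.random(n_class) < p_female
        flags = {
            name: rng.random(n_class) < props[1 if infected else 0]
            for name, props in spec.cvrf.items()
        }
        for i in range(n_class):
            counter += 1
            records.append(
                PatientRecord(
                    id=f"{prefix}{counter:04d}",
                    subgroup=spec.subgroup,
                    infected=infected,
                    age=float(draws["age"][i]),
                    sex="female" if female[i] else "male",
                    nihss=int(draws["nihss"][i]),
                    temperature=float(draws["temperature"][i]),
                    saa=float(draws["saa"][i]),
                    crp=float(draws["crp"][i]),
                    pct=float(draws["pct"][i]),
                    wbc=float(draws["wbc"][i]),
                    monocytes=float(draws["monocytes"][i]),
                    cvrf={k: bool(v[i]) for k, v in flags.items()},
                )
            )
    return Cohort(records, provenance={"subgroup": spec.subgroup, "seed": spec.seed})


# ---------------------------------------------------------------------------
# CSV round trip


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # full precision: guarantees round-trip identity
    return str(value)


def write_cohort_csv(cohort: Cohort, path_or_buf) -> None:
    """Write a cohort as UTF-8 CSV with the canonical header."""
    extra = sorted({k for r in cohort for k in r.cvrf})
    has_toast = any(r.toast is not None for r in cohort)
    header = CSV_COLUMNS + [f"cvrf_{k}" for k in extra] + (["toast"] if has_toast else [])

    def _write(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for r in cohort:
            row = [
                r.id, r.subgroup, _format_cell(r.infected), _format_cell(r.age),
                r.sex, str(r.nihss), _format_cell(r.temperature),
                _format_cell(r.saa), _format_cell(r.crp), _format_cell(r.pct),
                _format_cell(r.wbc), _format_cell(r.monocytes),
            ]
            row += [_format_cell(r.cvrf.get(k)) for k in extra]
            if has_toast:
                row.append(r.toast or "")
            writer.writerow(row)

    if hasattr(path_or_buf, "write"):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def _parse_float(cell: str, row: int, col: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise CohortParseError(f"row {row}, column {col!r}: cannot parse {cell!r} as a number") from None


def read_cohort_csv(path_or_buf) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Unknown columns trigger a warning; malformed numeric cells raise
    :class:`CohortParseError` naming the row and column.
    """
    if hasattr(path_or_buf, "read"):
        fh = path_or_buf
        close = False
    else:
        fh = open(path_or_buf, "r", encoding="utf-8", newline="")
        close = True
    try:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[: len(CSV_COLUMNS)] != CSV_COLUMNS:
            raise CohortParseError(f"malformed header: expected {CSV_COLUMNS}, got {header}")
        cvrf_cols = [c for c in header if c.startswith("cvrf_")]
        known = set(CSV_COLUMNS) | set(cvrf_cols) | {"toast"}
        for col in header:
            if col not in known:
                warnings.warn(f"unknown cohort column {col!r} ignored", stacklevel=2)
        idx = {c: i for i, c in enumerate(header)}
        records = []
        for rownum, row in enumerate(reader, start=2):
            cell = lambda c: row[idx[c]] if idx[c] < len(row) else ""
            nihss_raw = cell("nihss")
            try:
                nihss = int(nihss_raw)
            except ValueError:
                raise CohortParseError(
                    f"row {rownum}, column 'nihss': {nihss_raw!r} is not an integer"
                ) from None
            records.append(
                PatientRecord(
                    id=cell("id"),
                    subgroup=cell("subgroup"),
                    infected=cell("infected") == "1",
                    age=_parse_float(cell("age"), rownum, "age"),
                    sex=cell("sex"),
                    nihss=nihss,
                    temperature=_parse_float(cell("temperature"), rownum, "temperature"),
                    saa=_parse_float(cell("saa"), rownum, "saa"),
                    crp=_parse_float(cell("crp"), rownum, "crp"),
                    pct=_parse_float(cell("pct"), rownum, "pct"),
                    wbc=_parse_float(cell("wbc"), rownum, "wbc"),
                    monocytes=_parse_float(cell("monocytes"), rownum, "monocytes"),
                    cvrf={c[5:]: cell(c) == "1" for c in cvrf_cols},
                    toast=(cell("toast") or None) if "toast" in idx else None,
                )
            )
        return Cohort(records)
    finally:
        if close:
            fh.close()


def cohort_to_frame(cohort: Cohort):
    """Cohort as a pandas DataFrame (one row per patient)."""
    import pandas as pd

    rows = []
    for r in cohort:
        d = {
            "id": r.id, "subgroup": r.subgroup, "infected": r.infected,
            "age": r.age, "sex": r.sex, "nihss": r.nihss,
            "temperature": r.temperature, "saa": r.saa, "crp": r.crp,
            "pct": r.pct, "wbc": r.wbc, "monocytes": r.monocytes,
        }
        for k, v in r.cvrf.items():
            d[f"cvrf_{k}"] = v
        rows.append(d)
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.DataFrame(rows)
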