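"""Reading, validating and writing registry tables and median pairs.

Two input dialects are supported: age-binned tables (one row per unit, sex
and quinquennial age group, with incident cases and resident population)
and pre-aggregated median pairs (one row per unit and sex carrying the two
medians directly). Both reduce to :class:`MedianPair`, the point on the
standard-curve scatter plot.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: canonical column names of the binned-table CSV dialect
BINNED_COLUMNS = ("unit_id", "sex", "age_group", "cases", "population")
#: canonical column names of the median-pair CSV dialect
PAIR_COLUMNS = (
    "unit_id",
    "sex",
    "median_population_age",
    "median_onset_age",
    "n_cases",
    "n_population",
)


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class AgeBinScheme:
    """Age grouping: closed bins of equal width plus one open top bin.

    The canonical scheme is quinquennial: [0,5), [5,10), ... [80,85), [85, inf),
    labelled ``0-4`` ... ``80-84``, ``85+``.
    """

    edges: tuple[float, ...] = tuple(float(a) for a in range(0, 90, 5))
    width: float = 5.0
    open_top: bool = True

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2:
            raise ValueError("need at least two bin edges")
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin lower edges must be strictly increasing")
        if not np.allclose(np.diff(e), self.width):
            raise ValueError("all closed bins must share the same width")
        if not self.open_top:
            raise ValueError("the scheme requires exactly one open top bin")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def open_top_index(self) -> int:
        return len(self.edges) - 1

    def lower_edge(self, i: int) -> float:
        return self.edges[i]

    def labels(self) -> list[str]:
        labs = [
            f"{int(lo)}-{int(lo + self.width) - 1}" for lo in self.edges[:-1]
        ]
        labs.append(f"{int(self.edges[-1])}+")
        return labs

    def index_of_label(self, label: str) -> int:
        """Map an age-group label to its bin index; raises on unknown labels."""
        norm = str(label).strip().replace("–", "-").replace("—", "-")
        try:
            return self.labels().index(norm)
        except ValueError:
            # tolerate CI5-style "85" open-top shorthand and "85 +" spacing
            squeezed = norm.replace(" ", "")
            labs = [lab.replace(" ", "") for lab in self.labels()]
            if squeezed in labs:
                return labs.index(squeezed)
            raise ValidationError(f"unrecognized age-group label: {label!r}") from None

    def bin_containing(self, age: float) -> int:
        """Index of the bin whose half-open interval contains ``age``."""
        if age < self.edges[0]:
            raise ValueError(f"age {age} below the lowest bin edge")
        return min(
            int(np.searchsorted(np.asarray(self.edges), age, side="right")) - 1,
            self.open_top_index,
        )


#: module-wide default scheme
QUINQUENNIAL = AgeBinScheme()


def _check_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "men", "male"):
        return "male"
    if s in ("f", "w", "women", "female"):
        return "female"
    raise ValidationError(f"unrecognized sex label: {sex!r}")


@dataclass
class AgeBinnedTable:
    """Per-unit, per-sex incident cases and resident population by age bin."""

    unit_id: str
    sex: str
    cases: np.ndarray
    population: np.ndarray
    scheme: AgeBinScheme = field(default_factory=AgeBinScheme)

    def __post_init__(self) -> None:
        self.sex = _check_sex(self.sex)
        self.cases = np.asarray(self.cases, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        n = self.scheme.n_bins
        if self.cases.shape != (n,) or self.population.shape != (n,):
            raise ValidationError(
                f"{self.unit_id}/{self.sex}: expected {n} bins, got "
                f"{self.cases.shape} cases / {self.population.shape} population"
            )
        if np.any(self.cases < 0) or np.any(self.population < 0):
            raise ValidationError(f"{self.unit_id}/{self.sex}: negative counts")
        if np.any(~np.isfinite(self.cases)) or np.any(~np.isfinite(self.population)):
            raise ValidationError(f"{self.unit_id}/{self.sex}: non-finite counts")
        if np.any(self.cases != np.round(self.cases)):
            logger.warning(
                "%s/%s: non-integer case counts accepted as-is", self.unit_id, self.sex
            )

    @property
    def n_cases(self) -> float:
        return float(self.cases.sum())

    @property
    def n_population(self) -> float:
        return float(self.population.sum())


@dataclass
class MedianPair:
    """One unit reduced to its two medians.

    ``x`` is the median age of the resident population (the predictor);
    ``y`` is the median age at cancer onset (the response), ``None`` when it
    cannot be estimated (no or too few cases, or the case median falls in
    the open top bin).
    """

    unit_id: str
    sex: str
    x: float
    y: float | None
    n_cases: float
    n_population: float

    def __post_init__(self) -> None:
        self.sex = _check_sex(self.sex)
        self.x = float(self.x)
        if self.x < 0 or not math.isfinite(self.x):
            raise ValidationError(
                f"{self.unit_id}/{self.sex}: population median must be finite and >= 0"
            )
        if self.y is not None:
            self.y = float(self.y)
            if not math.isfinite(self.y):
                raise ValidationError(f"{self.unit_id}/{self.sex}: non-finite onset median")


def _apply_layout(df: pd.DataFrame, layout: Mapping[str, str] | None,
                  required: Sequence[str]) -> pd.DataFrame:
    """Rename file columns to canonical names via a {canonical: file} mapping."""
    if layout:
        rename = {v: k for k, v in layout.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    return df


def read_binned_tables(
    path,
    layout: Mapping[str, str] | None = None,
    scheme: AgeBinScheme = QUINQUENNIAL,
) -> list[AgeBinnedTable]:
    """Read an age-binned CSV into one :class:`AgeBinnedTable` per (unit, sex).

    ``layout`` maps canonical column names (``unit_id``, ``sex``,
    ``age_group``, ``cases``, ``population``) to the file's column headers,
    for CI5-style exports. Missing bins are filled with zero and logged;
    duplicate (unit, sex, bin) rows and negative counts are rejected.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    df = _apply_layout(df, layout, BINNED_COLUMNS)

    for col in ("cases", "population"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # header is line 1
            raise ValidationError(f"{path}: non-numeric {col} at line {row}")
        if (vals < 0).any():
            row = int(df.index[vals < 0][0]) + 2
            raise ValidationError(f"{path}: negative {col} at line {row}")
        df[col] = vals

    df["sex"] = df["sex"].map(_check_sex)
    df["_bin"] = df["age_group"].map(scheme.index_of_label)

    dup = df.duplicated(subset=["unit_id", "sex", "_bin"])
    if dup.any():
        bad = df.loc[dup, ["unit_id", "sex", "age_group"]].iloc[0]
        raise ValidationError(
            f"duplicate rows for ({bad.unit_id}, {bad.sex}, {bad.age_group})"
        )

    tables: list[AgeBinnedTable] = []
    for (unit, sex), grp in df.groupby(["unit_id", "sex"], sort=True):
        cases = np.zeros(scheme.n_bins)
        pop = np.zeros(scheme.n_bins)
        idx = grp["_bin"].to_numpy()
        cases[idx] = grp["cases"].to_numpy()
        pop[idx] = grp["population"].to_numpy()
        if len(idx) < scheme.n_bins:
            missing = sorted(set(range(scheme.n_bins)) - set(idx.tolist()))
            logger.warning(
                "%s/%s: %d missing age bins treated as zero (%s)",
                unit, sex, len(missing),
                ", ".join(scheme.labels()[i] for i in missing),
            )
        tables.append(AgeBinnedTable(str(unit), sex, cases, pop, scheme))
    return tables


def write_binned_tables(tables: Iterable[AgeBinnedTable], path) -> None:
    """Write tables in the canonical binned CSV dialect."""
    rows = []
    for t in tables:
        for lab, c, p in zip(t.scheme.labels(), t.cases, t.population):
            rows.append(
                {"unit_id": t.unit_id, "sex": t.sex, "age_group": lab,
                 "cases": c, "population": p}
            )
    pd.DataFrame(rows, columns=list(BINNED_COLUMNS)).to_csv(path, index=False)


def read_median_pairs(path, layout: Mapping[str, str] | None = None) -> list[MedianPair]:
    """Read pre-aggregated median pairs; an empty onset median means undefined y."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    df = _apply_layout(df, layout, PAIR_COLUMNS)

    pairs: list[MedianPair] = []
    for i, row in df.iterrows():
        x = row["median_population_age"]
        if pd.isna(x):
            raise ValidationError(
                f"{path}: missing median_population_age at line {int(i) + 2} "
                "(the predictor is mandatory)"
            )
        y = row["median_onset_age"]
        pairs.append(
            MedianPair(
                unit_id=str(row["unit_id"]),
                sex=row["sex"],
                x=float(x),
                y=None if pd.isna(y) else float(y),
                n_cases=float(row["n_cases"]),
                n_population=float(row["n_population"]),
            )
        )
    return pairs


def write_median_pairs(pairs: Iterable[MedianPair], path) -> None:
    """Write pairs in the canonical pair CSV dialect (full precision)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PAIR_COLUMNS)
        for p in pairs:
            w.writerow(
                [p.unit_id, p.sex, repr(p.x), "" if p.y is None else repr(p.y),
                 repr(p.n_cases), repr(p.n_population)]
            )


# --- report output -----------------------------------------------------------

REPORT_COLUMNS = (
    "unit_id", "sex", "n_cases", "n_population", "x", "y_observed", "expected",
    "residual", "ci_low", "ci_high", "pp", "pp_parameter", "ci_parameter_low",
    "ci_parameter_high", "eligible", "significant_early", "significant_late",
    "category", "status",
)


def _result_record(r) -> dict:
    """Flatten a DivergenceResult into a plain record."""
    defined = r.y_observed is not None and r.residual is not None
    rec = {
        "unit_id": r.unit_id,
        "sex": r.sex,
        "n_cases": r.n_cases,
        "n_population": r.n_population,
        "x": r.x,
        "y_observed": r.y_observed if defined else None,
        "expected": r.expected,
        "residual": r.residual if defined else None,
        "ci_low": r.residual_ci[0] if defined else None,
        "ci_high": r.residual_ci[1] if defined else None,
        "pp": r.pp if defined else None,
        "pp_parameter": r.pp_parameter if defined else None,
        "ci_parameter_low": r.residual_ci_parameter[0] if defined and r.residual_ci_parameter else None,
        "ci_parameter_high": r.residual_ci_parameter[1] if defined and r.residual_ci_parameter else None,
        "eligible": r.eligible,
        "significant_early": r.significant_early,
        "significant_late": r.significant_late,
        "category": r.category,
        "status": "ok" if r.eligible else "insufficient cases",
    }
    return rec


def write_report(results: Sequence, path, format: str = "csv",
                 polygons=None) -> None:
    """Write divergence results as CSV, JSON, or GeoJSON attribute join.

    ``geojson-attributes`` mode reads ``polygons`` (a GeoJSON
    FeatureCollection whose features carry a ``unit_id`` property, or a path
    to one), extends each matched feature's properties with the divergence
    attributes, and warns about unmatched unit ids on either side.
    """
    results = list(results)
    if not results:
        raise ValueError("results must be nonempty")
    records = [_result_record(r) for r in results]

    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
            w.writeheader()
            for rec in records:
                w.writerow(
                    {k: ("" if v is None else repr(v) if isinstance(v, float) else v)
                     for k, v in rec.items()}
                )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    elif format == "geojson-attributes":
        if polygons is None:
            raise ValueError("geojson-attributes mode requires polygons")
        if isinstance(polygons, (str, bytes)) or hasattr(polygons, "__fspath__"):
            with open(polygons) as fh:
                fc = json.load(fh)
        else:
            fc = polygons
        if fc.get("type") != "FeatureCollection":
            raise ValidationError("polygons must be a GeoJSON FeatureCollection")
        by_key = {(rec["unit_id"], rec["sex"]): rec for rec in records}
        by_unit: dict[str, list[dict]] = {}
        for rec in records:
            by_unit.setdefault(rec["unit_id"], []).append(rec)
        matched_units: set[str] = set()
        out_features = []
        for feat in fc.get("features", []):
            props = dict(feat.get("properties") or {})
            uid = str(props.get("unit_id"))
            recs = by_unit.get(uid)
            if recs is None:
                logger.warning("polygon feature %r has no divergence result", uid)
                continue
            matched_units.add(uid)
            for rec in recs:
                suffix = f"_{rec['sex']}" if len(recs) > 1 else ""
                for key in ("residual", "pp", "category", "significant_early",
                            "significant_late", "eligible"):
                    props[f"{key}{suffix}"] = rec[key]
            out = dict(feat)
            out["properties"] = props
            out_features.append(out)
        orphans = sorted(set(by_unit) - matched_units)
        if orphans:
            logger.warning("results without matching polygon: %s", ", ".join(orphans))
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": out_features}, fh, indent=1)
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report`."""
    return pd.read_csv(path, float_precision="round_trip")
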