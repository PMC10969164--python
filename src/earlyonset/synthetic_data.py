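"""Synthetic reference registries and sparse study areas.

The generator emulates the statistical structure the method assumes: a set
of large reference registries whose (population median, onset median)
points scatter around a straight line, and a set of small study areas
whose onset medians are sample medians of a handful of individual ages —
so eligibility rules and small-sample noise are exercised exactly as in
real sparse census sections. Injected per-area shifts (negative = earlier
onset) play the role of a localized exposure.

All generators are deterministic given the scenario seed and return a
truth table alongside the pairs, so tests can assert against the generative
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from earlyonset.registry_io import AgeBinScheme, AgeBinnedTable, MedianPair, QUINQUENNIAL
from earlyonset.medians import grouped_median

# Sample medians of n normal draws have asymptotic sd  sigma * MEDIAN_SD_FACTOR / sqrt(n)
MEDIAN_SD_FACTOR = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth of one synthetic scenario.

    Defaults mirror the study design the method targets: 36 reference
    registries, 41 sparse study areas, onset-vs-population line with
    intercept 56 years, slope 0.4 and 1.5 years of registry-level scatter,
    population medians in the 40–50 year range typical of Italian
    municipalities. ``sd_onset`` is the spread of individual ages at onset
    around an area's target median (9 years by default).
    """

    n_reference: int = 36
    x_range: tuple[float, float] = (40.0, 50.0)
    true_alpha: float = 56.0
    true_beta: float = 0.4
    true_sigma: float = 1.5
    n_study: int = 41
    shifts: tuple[float, ...] | None = None
    study_case_counts: tuple[int, ...] | None = None
    sd_onset: float = 9.0
    sex: str = "male"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_range[0] >= self.x_range[1]:
            raise ValueError("x_range low must be below high")
        if self.true_sigma < 0 or self.sd_onset < 0:
            raise ValueError("spread parameters must be nonnegative")
        if self.shifts is not None and len(self.shifts) != self.n_study:
            raise ValueError("shifts length must equal n_study")
        if self.study_case_counts is not None and len(self.study_case_counts) != self.n_study:
            raise ValueError("study_case_counts length must equal n_study")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)

    def resolved_shifts(self) -> np.ndarray:
        if self.shifts is None:
            return np.zeros(self.n_study)
        return np.asarray(self.shifts, dtype=float)

    def resolved_case_counts(self, rng: np.random.Generator) -> np.ndarray:
        """Per-area case counts; by default right-skewed sparse counts (0–300)."""
        if self.study_case_counts is not None:
            return np.asarray(self.study_case_counts, dtype=int)
        counts = np.round(rng.lognormal(np.log(20.0), 1.2, size=self.n_study))
        return np.clip(counts, 0, 300).astype(int)


@dataclass
class SyntheticTruth:
    """Per-unit generative ground truth emitted next to the pairs."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _line(config: ScenarioConfig, x: np.ndarray) -> np.ndarray:
    return config.true_alpha + config.true_beta * x


def generate_reference_pairs(config: ScenarioConfig) -> tuple[list[MedianPair], SyntheticTruth]:
    """Reference registries: onset medians scatter around the line with sd true_sigma.

    Registries are large, so their medians carry no appreciable sampling
    noise beyond the registry-level scatter; case and population totals are
    drawn at realistic registry magnitudes and only matter for bookkeeping.
    """
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(*config.x_range, size=config.n_reference)
    expected = _line(config, x)
    noise = rng.normal(0.0, config.true_sigma, size=config.n_reference)
    y = expected + noise
    n_cases = rng.integers(1_000, 30_000, size=config.n_reference)
    n_pop = rng.integers(60_000, 1_300_000, size=config.n_reference)
    pairs = [
        MedianPair(f"REF{i:02d}", config.sex, float(x[i]), float(y[i]),
                   int(n_cases[i]), int(n_pop[i]))
        for i in range(config.n_reference)
    ]
    truth = SyntheticTruth(pd.DataFrame({
        "unit_id": [p.unit_id for p in pairs],
        "sex": config.sex,
        "x": x,
        "expected": expected,
        "shift": 0.0,
        "y": y,
    }))
    return pairs, truth


def generate_study_pairs(config: ScenarioConfig) -> tuple[list[MedianPair], SyntheticTruth]:
    """Sparse study areas: onset median = sample median of simulated cases.

    Each area draws a population median x, a target onset median
    y* = line(x) + shift, then n_cases individual onset ages
    ~ Normal(y*, sd_onset²); the reported onset median is their sample
    median (undefined for areas with no cases). This keeps the
    small-sample noise of real census sections in the pipeline.
    """
    rng = np.random.default_rng(config.seed + 1)
    shifts = config.resolved_shifts()
    counts = config.resolved_case_counts(rng)
    x = rng.uniform(*config.x_range, size=config.n_study)
    target = _line(config, x) + shifts
    pairs: list[MedianPair] = []
    realized: list[float | None] = []
    n_pop = rng.integers(50, 12_000, size=config.n_study)
    for i in range(config.n_study):
        n = int(counts[i])
        if n >= 1:
            ages = rng.normal(target[i], config.sd_onset, size=n)
            y: float | None = float(np.median(ages))
        else:
            y = None
        realized.append(y)
        pairs.append(
            MedianPair(f"AREA{i:02d}", config.sex, float(x[i]), y, n, int(n_pop[i]))
        )
    truth = SyntheticTruth(pd.DataFrame({
        "unit_id": [p.unit_id for p in pairs],
        "sex": config.sex,
        "x": x,
        "expected": _line(config, x),
        "shift": shifts,
        "target": target,
        "n_cases": counts,
        "y": [np.nan if y is None else y for y in realized],
    }))
    return pairs, truth


def generate_null_study_pairs(config: ScenarioConfig) -> tuple[list[MedianPair], SyntheticTruth]:
    """Null study areas exchangeable with the reference registries.

    Onset medians are drawn directly from the reference generative law
    y ~ Normal(line(x), true_sigma²) — the model's own null — rather than
    through individual-age sampling, which adds sparse-median noise the
    model does not represent. This is the null under which the divergence
    PP is uniform and per-tail flag rates are calibrated; case counts are
    attached only for eligibility bookkeeping.
    """
    rng = np.random.default_rng(config.seed + 2)
    counts = config.resolved_case_counts(rng)
    x = rng.uniform(*config.x_range, size=config.n_study)
    expected = _line(config, x)
    y = expected + rng.normal(0.0, config.true_sigma, size=config.n_study)
    n_pop = rng.integers(50, 12_000, size=config.n_study)
    pairs = [
        MedianPair(f"AREA{i:02d}", config.sex, float(x[i]),
                   float(y[i]) if counts[i] >= 1 else None,
                   int(counts[i]), int(n_pop[i]))
        for i in range(config.n_study)
    ]
    truth = SyntheticTruth(pd.DataFrame({
        "unit_id": [p.unit_id for p in pairs],
        "sex": config.sex,
        "x": x,
        "expected": expected,
        "shift": 0.0,
        "n_cases": counts,
        "y": np.where(counts >= 1, y, np.nan),
    }))
    return pairs, truth


def binned_counts_for_median(
    target_median: float,
    n: float,
    scheme: AgeBinScheme = QUINQUENNIAL,
    seed: int | None = None,
) -> np.ndarray:
    """Counts whose grouped median equals ``target_median`` (exact inverse).

    Places half the mass in the bin containing the target and splits the
    rest between the neighbouring bins so the interpolation lands exactly
    on the target. Counts are real-valued; ``seed`` is accepted for
    interface symmetry but the construction is deterministic. Raises when
    the target lies in the open top bin or is not representable (the lower
    half of the lowest bin).
    """
    t = float(target_median)
    k = scheme.bin_containing(t)
    if k == scheme.open_top_index:
        raise ValueError(f"target {t} lies in the open top bin")
    g = (t - scheme.lower_edge(k)) / scheme.width  # position within the bin, [0, 1)
    counts = np.zeros(scheme.n_bins)
    if n <= 0:
        raise ValueError("n must be positive")
    below = (n / 2.0) * (1.0 - g)
    above = (n / 2.0) * g
    if k == 0 and below > 0:
        raise ValueError(
            f"target {t} in the lower half of the lowest bin is not representable"
        )
    counts[k] = n / 2.0
    if below > 0:
        counts[k - 1] = below
    if above > 0:
        counts[k + 1] = above  # may be the open top bin; the median bin stays closed
    est = grouped_median(counts, scheme)
    assert est.value is not None and abs(est.value - t) < 1e-6
    return counts


def binned_table_for_pair(pair: MedianPair, scheme: AgeBinScheme = QUINQUENNIAL) -> AgeBinnedTable:
    """Binned table whose grouped medians reproduce the pair's medians.

    Used by the simulate workflow to emit the binned CSV dialect. A pair
    with no cases yields an all-zero case vector; a pair whose onset median
    falls in the open top bin gets all case mass there, so the binned route
    reports the median as undefined — exactly what a real registry table
    with the same structure would do.
    """
    population = binned_counts_for_median(pair.x, max(pair.n_population, 2.0), scheme)
    if pair.y is None:
        if pair.n_cases > 0:
            raise ValueError(
                f"{pair.unit_id}/{pair.sex}: cannot bin an undefined onset median with cases"
            )
        cases = np.zeros(scheme.n_bins)
    elif scheme.bin_containing(pair.y) == scheme.open_top_index:
        cases = np.zeros(scheme.n_bins)
        cases[scheme.open_top_index] = max(pair.n_cases, 1.0)
    else:
        cases = binned_counts_for_median(pair.y, max(pair.n_cases, 1.0), scheme)
    return AgeBinnedTable(pair.unit_id, pair.sex, cases, population, scheme)


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML-style mapping."""
    kwargs = dict(d)
    for key in ("shifts", "study_case_counts"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    if "x_range" in kwargs:
        kwargs["x_range"] = tuple(kwargs["x_range"])
    return ScenarioConfig(**kwargs)
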