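"""Grouped medians by linear interpolation within age bins.

The median of an age-binned count vector is estimated by treating each
bin's count as uniformly spread over the bin and interpolating within the
bin that contains the N/2 point:

    median = L + ((N/2 - CF) / f) * h

where L is the lower edge of the median bin, CF the cumulative count below
it, f its count and h the bin width. A median falling in the open top bin
(85+) has no upper edge and is reported as undefined rather than
extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from earlyonset.registry_io import AgeBinScheme, AgeBinnedTable, MedianPair


@dataclass(frozen=True)
class GroupedMedianEstimate:
    """Interpolated grouped median; ``value`` is None when the median bin is open."""

    value: float | None
    bin_index: int
    n: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def grouped_median(counts, scheme: AgeBinScheme) -> GroupedMedianEstimate:
    """Linear-interpolation median of per-bin counts under ``scheme``.

    Equals the exact median of the continuum density that is uniform within
    each bin. When the N/2 point coincides with a bin edge the value is
    that edge (the formula is continuous there). Raises on zero total
    count; returns an undefined estimate when the median bin is the open
    top bin.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (scheme.n_bins,):
        raise ValueError(f"expected {scheme.n_bins} per-bin counts, got shape {c.shape}")
    if np.any(c < 0) or np.any(~np.isfinite(c)):
        raise ValueError("counts must be finite and nonnegative")
    n = float(c.sum())
    if n <= 0:
        raise ValueError("no observations")

    cum = np.cumsum(c)
    half = n / 2.0
    k = int(np.searchsorted(cum, half, side="left"))
    if k == scheme.open_top_index:
        return GroupedMedianEstimate(value=None, bin_index=k, n=n)
    cf = float(cum[k - 1]) if k > 0 else 0.0
    f = float(c[k])
    value = scheme.lower_edge(k) + (half - cf) / f * scheme.width
    return GroupedMedianEstimate(value=value, bin_index=k, n=n)


def median_pair_from_table(table: AgeBinnedTable) -> MedianPair:
    """Reduce a binned table to its (population median, onset median) pair.

    The onset median is undefined (None) when the unit has no cases or the
    case median falls in the open top bin; the population median is
    mandatory, so a zero total population is an error.
    """
    if table.n_population <= 0:
        raise ValueError(f"{table.unit_id}/{table.sex}: zero total population")
    x_est = grouped_median(table.population, table.scheme)
    if not x_est.defined:
        raise ValueError(
            f"{table.unit_id}/{table.sex}: population median falls in the open top bin"
        )
    if table.n_cases > 0:
        y_est = grouped_median(table.cases, table.scheme)
        y = y_est.value  # None when the case median sits in the open bin
    else:
        y = None
    return MedianPair(
        unit_id=table.unit_id,
        sex=table.sex,
        x=x_est.value,
        y=y,
        n_cases=table.n_cases,
        n_population=table.n_population,
    )
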