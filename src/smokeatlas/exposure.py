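"""Population exposure mapping: SFAP flags and the four exposure metrics.

A substantial fire-sourced air pollution (SFAP) day at a grid cell is a
day on which all-source PM2.5 exceeds the WHO 2021 daily guideline
(15 µg/m³) with fire contributing at least 50%, and/or all-source daily
maximum 8-h ozone exceeds its guideline (100 µg/m³) with fire contributing
at least 50%.  Exposure is summarized per region-year by person-days
(person × SFAP day), days per person, people exposed to at least one SFAP
day, and population-weighted mean concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fields import DailyField, PopulationRaster
from .grids import GridSpec

CATEGORIES = ("none", "pm_only", "o3_only", "both")


@dataclass(frozen=True)
class SfapThresholds:
    """Guideline values (µg/m³) and the minimum fire share of a SFAP day."""

    pm_guideline: float = 15.0
    o3_guideline: float = 100.0
    fire_share: float = 0.5


@dataclass
class SfapFlags:
    """Per cell-date SFAP flag with its PM/O3 category decomposition.

    ``category`` codes index :data:`CATEGORIES`; ``n_missing`` counts
    cell-dates where a needed field was NaN (treated as not flagged).
    """

    grid: GridSpec
    dates: pd.DatetimeIndex
    category: np.ndarray          # int8, (date, lat, lon)
    thresholds: SfapThresholds
    n_missing: int = 0

    @property
    def flag(self) -> np.ndarray:
        return self.category != 0

    def year_slice(self, year: int) -> "SfapFlags":
        sel = self.dates.year == year
        return replace(self, dates=self.dates[sel], category=self.category[sel])


def flag_sfap(pm_total: DailyField, pm_fire: DailyField,
              o3_total: DailyField, o3_fire: DailyField,
              thresholds: SfapThresholds | None = None) -> SfapFlags:
    """Flag SFAP days from estimated total and fire-sourced fields.

    "Exceeded" is read as strictly greater than the guideline and "at
    least 50%" as fraction >= 0.5; a negative fire-sourced value can never
    satisfy the share rule.  Cell-dates with NaN in any needed field are
    category "none" and counted in ``n_missing``.
    """
    th = thresholds or SfapThresholds()
    for f in (pm_fire, o3_total, o3_fire):
        if not pm_total.aligned_with(f):
            raise ValueError("SFAP input fields are not aligned")
    pt, pf = pm_total.values, pm_fire.values
    ot, of = o3_total.values, o3_fire.values
    missing = np.isnan(pt) | np.isnan(pf) | np.isnan(ot) | np.isnan(of)
    with np.errstate(invalid="ignore"):
        pm_hit = (pt > th.pm_guideline) & (pf >= th.fire_share * pt)
        o3_hit = (ot > th.o3_guideline) & (of >= th.fire_share * ot)
    pm_hit &= ~missing
    o3_hit &= ~missing
    category = np.zeros(pt.shape, dtype=np.int8)
    category[pm_hit & ~o3_hit] = 1
    category[~pm_hit & o3_hit] = 2
    category[pm_hit & o3_hit] = 3
    return SfapFlags(pm_total.grid, pm_total.dates, category, th,
                     n_missing=int(missing.sum()))


# ---------------------------------------------------------------------------
# population handling

def aggregate_population(fine_counts: np.ndarray, fine_grid: GridSpec,
                         target: GridSpec) -> np.ndarray:
    """Sum a nested fine population raster into target cells (conservative)."""
    ry = target.dlat / fine_grid.dlat
    rx = target.dlon / fine_grid.dlon
    if abs(ry - round(ry)) > 1e-9 or abs(rx - round(rx)) > 1e-9:
        raise ValueError("fine raster does not nest within the target grid")
    by, bx = int(round(ry)), int(round(rx))
    fine_counts = np.asarray(fine_counts, dtype=float)
    if fine_counts.shape != fine_grid.shape:
        raise ValueError("counts shape does not match the fine grid")
    if fine_grid.nlat % by or fine_grid.nlon % bx:
        raise ValueError("fine raster does not tile the target cells")
    v = fine_counts.reshape(target.nlat, by, target.nlon, bx)
    return v.sum(axis=(1, 3))


def adjust_to_reference(raster: PopulationRaster) -> PopulationRaster:
    """Rescale each country's cells so its sum matches the official total.

    The adjustment coefficient is reference_total / raster_sum per country;
    the operation is idempotent (a second application multiplies by 1).
    """
    counts = raster.counts.copy()
    for c, ref in raster.reference_totals.items():
        mask = raster.country_id == c
        s = raster.counts[mask].sum()
        if s == 0:
            if ref > 0 and mask.any():
                raise ValueError(f"country {c} has reference {ref} but zero raster sum")
            continue
        counts[mask] *= ref / s
    return PopulationRaster(raster.grid, raster.year, counts,
                            raster.country_id, raster.reference_totals)


# ---------------------------------------------------------------------------
# metrics

def _check_pop(flags: SfapFlags, pop: PopulationRaster):
    if pop.grid != flags.grid:
        raise ValueError("population raster grid differs from the flag grid")


def person_days(flags: SfapFlags, pop: PopulationRaster,
                category: str | None = None) -> float:
    """Total person-days: sum over cell-dates of flag × cell population."""
    _check_pop(flags, pop)
    if category is None:
        mask = flags.flag
    else:
        mask = flags.category == CATEGORIES.index(category)
    return float(np.einsum("tij,ij->", mask.astype(float), pop.counts))


def days_per_person(total_person_days: float, pop: PopulationRaster) -> float:
    """Average SFAP days per person: person-days / total population."""
    total = pop.total
    if total <= 0:
        raise ValueError("total population must be positive")
    return total_person_days / total


def people_exposed(flags: SfapFlags, pop: PopulationRaster) -> float:
    """Population of cells with at least one flagged day."""
    _check_pop(flags, pop)
    any_day = flags.flag.any(axis=0)
    return float(pop.counts[any_day].sum())


def pop_weighted_mean(conc: DailyField, pop: PopulationRaster,
                      period: slice | None = None) -> float:
    """Population-weighted mean concentration over a period.

    Each cell contributes its period-mean concentration weighted by its
    population; all-NaN cells are excluded from both numerator and weight
    sum.  Returns NaN when no cell has data.
    """
    if pop.grid != conc.grid:
        raise ValueError("population raster grid differs from the field grid")
    vals = conc.values if period is None else conc.values[period]
    if vals.size == 0:
        return float("nan")
    with np.errstate(invalid="ignore"):
        cell_mean = np.nanmean(vals, axis=0)
    ok = np.isfinite(cell_mean)
    wsum = pop.counts[ok].sum()
    if wsum == 0 or not ok.any():
        return float("nan")
    return float(np.sum(pop.counts[ok] * cell_mean[ok]) / wsum)


@dataclass
class ExposureSummary:
    """The four exposure metrics plus the category split for a region-year."""

    region: str
    year: int
    person_days: float
    days_per_person: float
    people_exposed: float
    pw_mean_pm25: float
    pw_mean_o3: float
    person_days_pm_only: float
    person_days_o3_only: float
    person_days_both: float
    total_population: float

    def as_row(self) -> dict:
        return dict(self.__dict__)


def summarize_exposure(flags: SfapFlags, pop: PopulationRaster,
                       pm_fire: DailyField | None = None,
                       o3_fire: DailyField | None = None,
                       region: str = "all",
                       region_mask: np.ndarray | None = None) -> ExposureSummary:
    """Exposure metrics for one region-year.

    ``region_mask`` restricts cells (True = inside region); population
    outside the mask is zeroed.  ``pm_fire``/``o3_fire`` feed the
    population-weighted mean concentrations when given.
    """
    year = int(flags.dates.year[0]) if len(flags.dates) else pop.year
    if region_mask is not None:
        pop = PopulationRaster(pop.grid, pop.year,
                               np.where(region_mask, pop.counts, 0.0),
                               pop.country_id, pop.reference_totals)
    pd_total = person_days(flags, pop)
    return ExposureSummary(
        region=region, year=year,
        person_days=pd_total,
        days_per_person=days_per_person(pd_total, pop) if pop.total > 0 else float("nan"),
        people_exposed=people_exposed(flags, pop),
        pw_mean_pm25=pop_weighted_mean(pm_fire, pop) if pm_fire else float("nan"),
        pw_mean_o3=pop_weighted_mean(o3_fire, pop) if o3_fire else float("nan"),
        person_days_pm_only=person_days(flags, pop, "pm_only"),
        person_days_o3_only=person_days(flags, pop, "o3_only"),
        person_days_both=person_days(flags, pop, "both"),
        total_population=pop.total,
    )


def exposure_table(summaries: list[ExposureSummary]) -> pd.DataFrame:
    """Tidy (region, year, metric, value) table from summaries."""
    rows = []
    for s in summaries:
        for metric, value in s.as_row().items():
            if metric in ("region", "year"):
                continue
            rows.append({"region": s.region, "year": s.year,
                         "metric": metric, "value": value})
    return pd.DataFrame(rows)
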