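"""Static-chamber N2O flux and cumulative seasonal emission.

The chamber flux follows the closed-chamber protocol

    f = rho * (V/A) * (dC/dt) * 273 / (273 + T)

with f in ug m-2 h-1, rho the N2O density at STP (kg m-3), V/A the chamber
headspace height (m), dC/dt the concentration rise (ul l-1 h-1) and T the
chamber air temperature (degC). Cumulative emission over a season is the
trapezoid over sampling dates

    M = sum (F_{N+1} + F_N) * 0.5 * (T_{N+1} - T_N) * 24 * 1e-2

with F in mg m-2 h-1, T in days since first sampling and M in kg ha-1.
The factor 24*1e-2 converts mg m-2 day-increments to kg ha-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: N2O density at STP: 44.013 g mol-1 / 22.414 l mol-1 (kg m-3).
N2O_DENSITY_STP = 1.964

#: Chamber geometry of the emulated trial: 38 cm x 35 cm footprint,
#: 36.5 cm height.
DEFAULT_CHAMBER_AREA = 0.38 * 0.35          # m2
DEFAULT_CHAMBER_VOLUME = DEFAULT_CHAMBER_AREA * 0.365   # m3


@dataclass
class ChamberSeries:
    """One chamber closure: concentrations sampled at minutes after closing."""

    times_min: np.ndarray          # minutes since closure, strictly increasing
    conc_ul_l: np.ndarray          # N2O concentration, ul l-1
    volume_m3: float = DEFAULT_CHAMBER_VOLUME
    area_m2: float = DEFAULT_CHAMBER_AREA
    temperature_c: float = 20.0
    gas_density: float = N2O_DENSITY_STP   # kg m-3 at STP
    plot_id: str | None = None
    date_day: float | None = None  # days since first sampling

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.conc_ul_l = np.asarray(self.conc_ul_l, dtype=float)
        if self.times_min.size < 2:
            raise ValueError("chamber series needs at least 2 points")
        if self.times_min.size != self.conc_ul_l.size:
            raise ValueError("times and concentrations differ in length")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.volume_m3 <= 0 or self.area_m2 <= 0 or self.gas_density <= 0:
            raise ValueError("V, A and gas density must be positive")
        if self.temperature_c <= -273:
            raise ValueError("temperature below absolute zero")


@dataclass
class FluxRecord:
    plot_id: str | None
    date_day: float | None
    flux_ug_m2_h: float
    slope_ul_l_h: float
    r_squared: float


@dataclass
class CumulativeEmission:
    plot_id: str | None
    M_kg_ha: float
    n_intervals: int


def fit_slope(series: ChamberSeries) -> tuple[float, float]:
    """OLS slope of concentration on closure time, in ul l-1 per hour.

    r^2 is 1 exactly for two points or collinear data; a constant series
    has slope 0 and, having zero residuals, r^2 = 1.
    """
    t, c = series.times_min, series.conc_ul_l
    slope_per_min, intercept = np.polyfit(t, c, 1)
    fitted = slope_per_min * t + intercept
    ss_res = float(np.sum((c - fitted) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    # a numerically constant series is a perfect (zero-slope) fit
    tiny = 1e-20 * max(1.0, float(np.max(np.abs(c))) ** 2) * c.size
    r2 = 1.0 if ss_tot <= tiny else 1.0 - ss_res / ss_tot
    return float(slope_per_min * 60.0), r2


def compute_flux(series: ChamberSeries) -> FluxRecord:
    """Chamber N2O flux in ug m-2 h-1 from one closure series."""
    slope, r2 = fit_slope(series)
    f = (series.gas_density * (series.volume_m3 / series.area_m2) * slope
         * 273.0 / (273.0 + series.temperature_c))
    return FluxRecord(series.plot_id, series.date_day, float(f), slope, r2)


def flux_ug_to_mg(flux_ug_m2_h):
    """Convert per-date fluxes (ug m-2 h-1) to the mg m-2 h-1 scale the
    cumulative-emission formula expects."""
    return np.asarray(flux_ug_m2_h, dtype=float) * 1e-3


def cumulative_emission(days, fluxes_mg_m2_h, plot_id: str | None = None) -> CumulativeEmission:
    """Seasonal cumulative N2O emission (kg ha-1) by trapezoidal integration.

    ``days`` are days since the first sampling (strictly increasing, >= 2
    points); ``fluxes_mg_m2_h`` are the per-date fluxes in mg m-2 h-1
    (use :func:`flux_ug_to_mg` on :class:`FluxRecord` fluxes).
    """
    days = np.asarray(days, dtype=float)
    fluxes = np.asarray(fluxes_mg_m2_h, dtype=float)
    if days.size != fluxes.size:
        raise ValueError("days and fluxes differ in length")
    if days.size < 2:
        raise ValueError("cumulative emission needs at least 2 sampling dates")
    if not np.all(np.diff(days) > 0):
        raise ValueError("sampling dates must be strictly increasing")
    m = float(np.sum((fluxes[1:] + fluxes[:-1]) * 0.5 * np.diff(days)) * 24.0 * 1e-2)
    return CumulativeEmission(plot_id, m, days.size - 1)


def cumulative_from_records(records: list[FluxRecord]) -> CumulativeEmission:
    """Integrate a plot's ordered :class:`FluxRecord` list (ug-scale fluxes)."""
    if any(r.date_day is None for r in records):
        raise ValueError("flux records need date_day for integration")
    days = [r.date_day for r in records]
    fluxes = flux_ug_to_mg([r.flux_ug_m2_h for r in records])
    plot_ids = {r.plot_id for r in records}
    plot_id = plot_ids.pop() if len(plot_ids) == 1 else None
    return cumulative_emission(days, fluxes, plot_id=plot_id)
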