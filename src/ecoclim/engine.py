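"""The weekly growth/stress suitability engine.

For each grid cell the engine derives a 52-week climate series, spins up a
soil-moisture bucket, evaluates weekly temperature and moisture growth
indices (piecewise-linear trapezoids over DV0..DV3 and SM0..SM3), and
accumulates four annual stress indices (cold, heat, dry, wet) from weekly
threshold exceedances.  These combine into the Ecoclimatic Index

    EI = 100 * GI_A * (1 - CS)(1 - HS)(1 - DS)(1 - WS)

on a 0-100 scale, classified as unsuitable (EI = 0), suitable (0 < EI < 30)
or highly suitable (EI >= 30).

Hydrology is a single-bucket water balance: weekly soil moisture (as a
proportion of holding capacity) is updated by the precipitation surplus
over a temperature-driven potential evapotranspiration; water above field
capacity runs off before the next week, but the within-week value may
exceed 1 (up to ``sm_cap``) so waterlogging and wet stress beyond SMWS are
representable.  The annual cycle is iterated from ``sm_init`` until it
converges (spin-up), removing dependence on the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_grid import ClimateGrid, GridCell, WeeklySeries, monthly_to_weekly
from .params import SpeciesParameters

__all__ = [
    "UNSUITABLE",
    "SUITABLE",
    "HIGH",
    "EI_ZERO_TOL",
    "HIGH_EI_THRESHOLD",
    "ConvergenceError",
    "CellResult",
    "temperature_index",
    "moisture_index",
    "potential_evapotranspiration",
    "soil_moisture_series",
    "annual_growth_index",
    "stress_index",
    "ecoclimatic_index",
    "classify",
    "run_cell",
    "run_grid",
]

UNSUITABLE = "unsuitable"
SUITABLE = "suitable"
HIGH = "high"

#: EI below this is treated as exactly zero (absorbs rounding).
EI_ZERO_TOL = 1e-9
#: EI at or above this is classed highly suitable.
HIGH_EI_THRESHOLD = 30.0

_SPINUP_TOL = 1e-6
_SPINUP_MAX_YEARS = 100


class ConvergenceError(RuntimeError):
    """Soil-moisture spin-up failed to converge; carries the residual."""

    def __init__(self, residual: float):
        super().__init__(
            f"soil-moisture spin-up did not converge within {_SPINUP_MAX_YEARS} years "
            f"(residual {residual:.3e})"
        )
        self.residual = residual


@dataclass(frozen=True)
class CellResult:
    """Annual suitability summary for one cell."""

    cell_id: str
    lat: float
    lon: float
    gi_a: float
    cs: float
    hs: float
    ds: float
    ws: float
    ei: float
    suitability: str


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    """Piecewise-linear response: 0 outside (lo, hi), 1 on [opt_lo, opt_hi]."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.asarray(x, dtype=float)
    rising = (x - lo) / (opt_lo - lo)
    falling = (hi - x) / (hi - opt_hi)
    out = np.clip(np.minimum(rising, falling), 0.0, 1.0)
    return float(out) if scalar else out


def temperature_index(tavg, p: SpeciesParameters):
    """Weekly temperature growth index: trapezoid over DV0, DV1, DV2, DV3."""
    return _trapezoid(tavg, p.dv0, p.dv1, p.dv2, p.dv3)


def moisture_index(sm, p: SpeciesParameters):
    """Weekly moisture growth index: trapezoid over SM0, SM1, SM2, SM3."""
    return _trapezoid(sm, p.sm0, p.sm1, p.sm2, p.sm3)


def potential_evapotranspiration(tavg, p: SpeciesParameters):
    """Temperature-driven PET in mm/week: pet_coeff * max(0, 0.46*T + 8.13)."""
    return p.pet_coeff * np.maximum(0.0, 0.46 * np.asarray(tavg, dtype=float) + 8.13)


def soil_moisture_series(weeks: WeeklySeries, p: SpeciesParameters) -> np.ndarray:
    """Converged weekly soil-moisture cycle (proportion of capacity).

    Weekly update: sm[w] = clamp(prev + (precip[w] - pet[w]) / capacity,
    0, sm_cap); the state carried into the next week is min(sm[w], 1) —
    water above field capacity runs off.  The annual cycle is iterated from
    ``sm_init`` until successive years differ by < 1e-6 (at most 100
    years); non-convergence raises :class:`ConvergenceError`.
    """
    pet = potential_evapotranspiration(weeks.tavg, p)
    delta = (weeks.precip - pet) / p.soil_capacity
    sm = np.empty(52)
    state = p.sm_init
    prev_cycle = None
    for _ in range(_SPINUP_MAX_YEARS):
        for w in range(52):
            val = min(max(state + delta[w], 0.0), p.sm_cap)
            sm[w] = val
            state = min(val, 1.0)
        if prev_cycle is not None:
            residual = float(np.max(np.abs(sm - prev_cycle)))
            if residual < _SPINUP_TOL:
                return sm.copy()
        prev_cycle = sm.copy()
    raise ConvergenceError(float(np.max(np.abs(sm - prev_cycle))))


def annual_growth_index(weeks: WeeklySeries, sm: np.ndarray, p: SpeciesParameters) -> float:
    """Annual growth index: mean over weeks of TI(tavg) * MI(sm)."""
    ti = temperature_index(weeks.tavg, p)
    mi = moisture_index(sm, p)
    return float(np.mean(ti * mi))


def stress_index(exceedances, rate: float) -> float:
    """Annual stress index from weekly threshold exceedances.

    Accumulation A = 52 * sum_w |rate| * exceedance[w], saturating at 1.
    Exceedances must be the caller-computed non-negative weekly amounts by
    which the relevant series crosses the stress threshold.
    """
    ex = np.asarray(exceedances, dtype=float)
    if np.any(ex < 0):
        raise ValueError("stress exceedances must be non-negative")
    return float(min(1.0, 52.0 * abs(rate) * ex.sum()))


def ecoclimatic_index(gi_a: float, cs: float, hs: float, ds: float, ws: float) -> float:
    """EI = 100 * GI_A * (1-CS)(1-HS)(1-DS)(1-WS), on [0, 100]."""
    for name, v in (("gi_a", gi_a), ("cs", cs), ("hs", hs), ("ds", ds), ("ws", ws)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} out of [0, 1]")
    return 100.0 * gi_a * (1 - cs) * (1 - hs) * (1 - ds) * (1 - ws)


def classify(ei: float) -> str:
    """Three-class suitability: EI = 0 / 0 < EI < 30 / EI >= 30."""
    if not 0.0 <= ei <= 100.0 + 1e-9:
        raise ValueError(f"ei={ei} out of [0, 100]")
    if ei < EI_ZERO_TOL:
        return UNSUITABLE
    if ei < HIGH_EI_THRESHOLD:
        return SUITABLE
    return HIGH


def prepare_cell(cell: GridCell, p: SpeciesParameters) -> tuple[WeeklySeries, np.ndarray]:
    """Weekly series and converged soil moisture for a cell.

    Split out so parameter-sweep callers can reuse the (parameter-
    independent) weekly climate and the bucket cycle, which depends only on
    the hydrology constants, across many evaluations.
    """
    weeks = monthly_to_weekly(cell.normals)
    return weeks, soil_moisture_series(weeks, p)


def evaluate_cell(
    cell: GridCell, weeks: WeeklySeries, sm: np.ndarray, p: SpeciesParameters
) -> CellResult:
    """Indices, stresses, EI and class from precomputed weekly inputs."""
    gi_a = annual_growth_index(weeks, sm, p)
    cs = stress_index(np.maximum(0.0, p.ttcs - weeks.tmin), p.thcs)
    hs = stress_index(np.maximum(0.0, weeks.tmax - p.tths), p.thhs)
    ds = stress_index(np.maximum(0.0, p.smds - sm), p.hds)
    ws = stress_index(np.maximum(0.0, sm - p.smws), p.hws)
    ei = ecoclimatic_index(gi_a, cs, hs, ds, ws)
    return CellResult(
        cell_id=cell.cell_id,
        lat=cell.lat,
        lon=cell.lon,
        gi_a=gi_a,
        cs=cs,
        hs=hs,
        ds=ds,
        ws=ws,
        ei=ei,
        suitability=classify(ei),
    )


def run_cell(cell: GridCell, p: SpeciesParameters) -> CellResult:
    """Full deterministic evaluation of one cell."""
    weeks, sm = prepare_cell(cell, p)
    return evaluate_cell(cell, weeks, sm, p)


def run_grid(grid: ClimateGrid, p: SpeciesParameters) -> list[CellResult]:
    """Evaluate every cell; results ordered by cell_id, order-independent."""
    if len(grid) == 0:
        raise ValueError("cannot run an empty grid")
    return [run_cell(cell, p) for cell in grid]
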