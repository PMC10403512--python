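"""One-at-a-time parameter sensitivity of the suitability map.

Each of the sixteen biological parameters is moved to its low and to its
high perturbation value (32 perturbed runs; the baseline is computed
once), the grid is re-evaluated, and the percent change of the
cosine-latitude-weighted area of each suitability class relative to the
baseline is reported.  A parameter is labelled *sensitive* when any of its
runs changes any class area by at least a threshold (2% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .climate_grid import ClimateGrid
from .engine import HIGH, SUITABLE, UNSUITABLE, CellResult, evaluate_cell, prepare_cell
from .params import PARAM_NAMES, ParameterError, PerturbationTable, SpeciesParameters

__all__ = [
    "SensitivityRow",
    "perturb",
    "class_area",
    "run_sensitivity",
    "label_sensitivity",
    "write_sensitivity_csv",
]

CLASSES = (UNSUITABLE, SUITABLE, HIGH)


@dataclass(frozen=True)
class SensitivityRow:
    """Outcome of one perturbed run.

    ``pct_change`` maps each class to its percent area change relative to
    the baseline, or None where the baseline class area is zero
    (undefined).  ``sensitive`` is filled by :func:`label_sensitivity`.
    """

    parameter: str
    direction: str
    value: float
    pct_change: dict[str, float | None]
    sensitive: bool | None = None


def perturb(
    params: SpeciesParameters,
    name: str,
    direction: str,
    table: PerturbationTable,
) -> SpeciesParameters:
    """Copy of *params* with one parameter at its low or high table value.

    The full parameter invariants are re-checked; a perturbation that
    breaks the threshold ordering raises :class:`ParameterError` naming
    the conflict.
    """
    if name not in PARAM_NAMES:
        raise ParameterError(f"unknown parameter {name!r}")
    if direction not in ("low", "high"):
        raise ParameterError(f"direction must be 'low' or 'high', got {direction!r}")
    low, _, high = table[name]
    value = low if direction == "low" else high
    try:
        return params.replace(**{name: value})
    except ParameterError as err:
        raise ParameterError(f"perturbing {name}={value} ({direction}): {err}") from err


def class_area(results: Sequence[CellResult]) -> dict[str, float]:
    """Cosine-latitude-weighted area per suitability class.

    On an equal-angle grid the true cell area scales with cos(latitude);
    the weights are dimensionless (cell counts at the equator).
    """
    if not results:
        raise ValueError("class_area requires non-empty results")
    areas = {c: 0.0 for c in CLASSES}
    for r in results:
        areas[r.suitability] += float(np.cos(np.radians(r.lat)))
    return areas


def run_sensitivity(
    grid: ClimateGrid,
    params: SpeciesParameters,
    table: PerturbationTable,
) -> list[SensitivityRow]:
    """The 32-run one-at-a-time sensitivity experiment.

    The weekly climate and the soil-moisture cycle depend only on the
    hydrology constants, which perturbations never touch, so they are
    prepared once per cell and shared across the baseline and all 32
    perturbed evaluations.
    """
    prepared = [(cell, *prepare_cell(cell, params)) for cell in grid]
    baseline = [evaluate_cell(cell, weeks, sm, params) for cell, weeks, sm in prepared]
    base_area = class_area(baseline)

    rows: list[SensitivityRow] = []
    for name in PARAM_NAMES:
        for direction in ("low", "high"):
            p = perturb(params, name, direction, table)
            results = [evaluate_cell(cell, weeks, sm, p) for cell, weeks, sm in prepared]
            area = class_area(results)
            pct: dict[str, float | None] = {}
            for cls in CLASSES:
                if base_area[cls] == 0.0:
                    pct[cls] = None
                else:
                    pct[cls] = 100.0 * (area[cls] - base_area[cls]) / base_area[cls]
            rows.append(
                SensitivityRow(
                    parameter=name,
                    direction=direction,
                    value=getattr(p, name),
                    pct_change=pct,
                )
            )
    return rows


def label_sensitivity(
    rows: Iterable[SensitivityRow], threshold_pct: float = 2.0
) -> list[SensitivityRow]:
    """Mark each row's parameter sensitive iff any of its rows moves any
    class area by at least *threshold_pct* percent (absolute)."""
    rows = list(rows)
    flagged: set[str] = set()
    for row in rows:
        if any(
            v is not None and abs(v) >= threshold_pct for v in row.pct_change.values()
        ):
            flagged.add(row.parameter)
    return [replace(r, sensitive=r.parameter in flagged) for r in rows]


def write_sensitivity_csv(
    rows: Sequence[SensitivityRow], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    df = pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "direction": r.direction,
                "value": r.value,
                "pct_change_unsuitable": r.pct_change[UNSUITABLE],
                "pct_change_suitable": r.pct_change[SUITABLE],
                "pct_change_high": r.pct_change[HIGH],
                "sensitive": r.sensitive,
            }
            for r in rows
        ]
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
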