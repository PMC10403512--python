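"""Baseline-versus-future comparison of suitability grids.

Future climates are supplied as full climate grids and run through the
engine, mirroring the GCM-fields -> model -> EI workflow; this module then
computes per-cell EI deltas and class transitions, per-stress change
tallies, and (given two future projections) a two-model agreement map of
the direction of EI change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .engine import HIGH, SUITABLE, UNSUITABLE, CellResult

__all__ = [
    "TRANSITIONS",
    "AGREEMENT_CATEGORIES",
    "CellChange",
    "AgreementCell",
    "ei_change",
    "agreement_map",
    "stress_change_summary",
    "write_change_csv",
    "write_agreement_csv",
]

TRANSITIONS = (
    "stable_unsuitable",
    "stable_suitable",
    "stable_high",
    "gained",
    "lost",
    "upgraded",
    "downgraded",
)
AGREEMENT_CATEGORIES = ("both_increase", "both_decrease", "disagree", "both_no_change")

#: Stress-index deltas within this are tallied as "no change".
STRESS_CHANGE_TOL = 0.01


@dataclass(frozen=True)
class CellChange:
    """Per-cell future-minus-baseline change."""

    cell_id: str
    lat: float
    lon: float
    ei_base: float
    ei_future: float
    delta_ei: float
    transition: str
    delta_cs: float
    delta_hs: float
    delta_ds: float
    delta_ws: float


@dataclass(frozen=True)
class AgreementCell:
    """Direction-of-change agreement between two projections for one cell."""

    cell_id: str
    lat: float
    lon: float
    category: str


def _transition(base_class: str, future_class: str) -> str:
    if base_class == future_class:
        return f"stable_{base_class}"
    if base_class == UNSUITABLE:
        return "gained"
    if future_class == UNSUITABLE:
        return "lost"
    if base_class == SUITABLE and future_class == HIGH:
        return "upgraded"
    if base_class == HIGH and future_class == SUITABLE:
        return "downgraded"
    raise AssertionError(f"unreachable: {base_class} -> {future_class}")


def _match_cells(
    a: Sequence[CellResult], b: Sequence[CellResult], what: str
) -> list[tuple[CellResult, CellResult]]:
    da = {r.cell_id: r for r in a}
    db = {r.cell_id: r for r in b}
    if set(da) != set(db):
        only_a = sorted(set(da) - set(db))
        only_b = sorted(set(db) - set(da))
        raise ValueError(
            f"{what}: cell sets differ (only in first: {only_a[:10]}, "
            f"only in second: {only_b[:10]})"
        )
    return [(da[k], db[k]) for k in sorted(da)]


def ei_change(
    baseline: Sequence[CellResult], future: Sequence[CellResult]
) -> list[CellChange]:
    """Per-cell EI/stress deltas and class-transition labels."""
    changes = []
    for base, fut in _match_cells(baseline, future, "ei_change"):
        changes.append(
            CellChange(
                cell_id=base.cell_id,
                lat=base.lat,
                lon=base.lon,
                ei_base=base.ei,
                ei_future=fut.ei,
                delta_ei=fut.ei - base.ei,
                transition=_transition(base.suitability, fut.suitability),
                delta_cs=fut.cs - base.cs,
                delta_hs=fut.hs - base.hs,
                delta_ds=fut.ds - base.ds,
                delta_ws=fut.ws - base.ws,
            )
        )
    return changes


def agreement_map(
    change1: Sequence[CellChange],
    change2: Sequence[CellChange],
    tol_ei: float = 1.0,
) -> list[AgreementCell]:
    """Do two projections agree on the direction of EI change per cell?

    |delta| < tol_ei counts as no change.  Both beyond tolerance with the
    same sign -> both_increase / both_decrease; both within ->
    both_no_change; anything else -> disagree.
    """
    d1 = {c.cell_id: c for c in change1}
    d2 = {c.cell_id: c for c in change2}
    if set(d1) != set(d2):
        raise ValueError("agreement_map: cell sets differ")
    out = []
    for cid in sorted(d1):
        a, b = d1[cid].delta_ei, d2[cid].delta_ei
        a_flat, b_flat = abs(a) < tol_ei, abs(b) < tol_ei
        if a_flat and b_flat:
            cat = "both_no_change"
        elif a_flat or b_flat:
            cat = "disagree"
        elif a > 0 and b > 0:
            cat = "both_increase"
        elif a < 0 and b < 0:
            cat = "both_decrease"
        else:
            cat = "disagree"
        out.append(
            AgreementCell(cell_id=cid, lat=d1[cid].lat, lon=d1[cid].lon, category=cat)
        )
    return out


def stress_change_summary(
    changes: Sequence[CellChange], tol: float = STRESS_CHANGE_TOL
) -> dict[str, dict[str, int]]:
    """Per-stress cell tallies of increase / decrease / no change."""
    if not changes:
        raise ValueError("stress_change_summary requires non-empty changes")
    summary: dict[str, dict[str, int]] = {}
    for stress, attr in (
        ("cs", "delta_cs"),
        ("hs", "delta_hs"),
        ("ds", "delta_ds"),
        ("ws", "delta_ws"),
    ):
        inc = sum(1 for c in changes if getattr(c, attr) > tol)
        dec = sum(1 for c in changes if getattr(c, attr) < -tol)
        summary[stress] = {
            "increase": inc,
            "decrease": dec,
            "no_change": len(changes) - inc - dec,
        }
    return summary


def write_change_csv(
    changes: Sequence[CellChange], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    df = pd.DataFrame([c.__dict__ for c in changes])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_agreement_csv(
    cells: Sequence[AgreementCell], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    df = pd.DataFrame([c.__dict__ for c in cells])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
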