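"""Plate-reader BRET ratio analysis.

Each well is measured in three consecutive phases (baseline, agonist,
saturation) of a fixed number of cycles.  The per-cycle BRET ratio is
YFP counts divided by nanoLuc counts.  Each phase is fitted by an ordinary
least-squares line over (cycle time, ratio); the signal change at a phase
boundary is the distance between the fitted line of the following phase
evaluated at its first cycle time and the fitted line of the previous phase
evaluated at its last cycle time.  The maximum change is the exact sum of the
agonist-induced and additional (saturating-reference) changes, and the
agonist change is normalized to it per well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError, TraceError

__all__ = [
    "BretChangeResult",
    "compute_bret_ratio",
    "fit_phase_lines",
    "compute_phase_changes",
    "analyze_plate",
]

PHASE_ORDER = ("baseline", "agonist", "saturation")


@dataclass
class BretChangeResult:
    """Phase-boundary signal changes for one well.

    ``max_change == agonist_change + additional_change`` holds exactly by
    construction.  ``normalized_agonist_change`` is None when the maximum
    change is not positive (flagged degenerate).
    """

    well_id: str
    agonist_change: float
    additional_change: float
    max_change: float
    normalized_agonist_change: float | None
    phase_lines: dict[str, tuple[float, float]]
    degenerate: bool = False


def compute_bret_ratio(yfp, nluc, well_id: str = "?") -> np.ndarray:
    """Per-cycle BRET ratio yfp/nluc; errors name the offending cycle."""
    yfp = np.asarray(yfp, dtype=float)
    nluc = np.asarray(nluc, dtype=float)
    bad = np.nonzero(nluc <= 0)[0]
    if bad.size:
        raise TraceError(
            f"well {well_id!r}: non-positive nluc signal at cycle {int(bad[0])}"
        )
    return yfp / nluc


def fit_phase_lines(
    cycle_time, ratio, phase_labels
) -> dict[str, tuple[float, float]]:
    """OLS line (intercept, slope) per phase over (cycle_time, ratio)."""
    cycle_time = np.asarray(cycle_time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    phase_labels = np.asarray(phase_labels)
    lines: dict[str, tuple[float, float]] = {}
    for phase in PHASE_ORDER:
        sel = phase_labels == phase
        if sel.sum() < 2:
            raise FitError(
                f"phase {phase!r} has {int(sel.sum())} cycles; need >= 2 for a line fit"
            )
        slope, intercept = np.polyfit(cycle_time[sel], ratio[sel], 1)
        lines[phase] = (float(intercept), float(slope))
    return lines


def _line_at(line: tuple[float, float], t: float) -> float:
    b, m = line
    return b + m * t


def compute_phase_changes(
    lines: dict[str, tuple[float, float]],
    phase_boundaries: dict[str, tuple[float, float]],
    well_id: str = "?",
) -> BretChangeResult:
    """Signal changes from fitted-line values at the scheduled boundary times.

    ``phase_boundaries`` maps each phase to its (first, last) cycle times.
    agonist_change   = agonist line at its first time - baseline line at its last
    additional_change = saturation line at its first time - agonist line at its last
    """
    for phase in PHASE_ORDER:
        if phase not in lines or phase not in phase_boundaries:
            raise FitError(f"missing fitted line or boundaries for phase {phase!r}")
    agonist_change = _line_at(
        lines["agonist"], phase_boundaries["agonist"][0]
    ) - _line_at(lines["baseline"], phase_boundaries["baseline"][1])
    additional_change = _line_at(
        lines["saturation"], phase_boundaries["saturation"][0]
    ) - _line_at(lines["agonist"], phase_boundaries["agonist"][1])
    max_change = agonist_change + additional_change
    degenerate = max_change <= 0
    normalized = None if degenerate else agonist_change / max_change
    return BretChangeResult(
        well_id=well_id,
        agonist_change=agonist_change,
        additional_change=additional_change,
        max_change=max_change,
        normalized_agonist_change=normalized,
        phase_lines=dict(lines),
        degenerate=degenerate,
    )


def analyze_well(df: pd.DataFrame, well_id: str = "?") -> BretChangeResult:
    """Run the full per-well analysis on a long-format cycle frame."""
    ratio = compute_bret_ratio(df["yfp"], df["nluc"], well_id=well_id)
    t = np.asarray(df["cycle_time_s"], dtype=float)
    labels = np.asarray(df["phase"])
    lines = fit_phase_lines(t, ratio, labels)
    boundaries = {}
    for phase in PHASE_ORDER:
        tp = t[labels == phase]
        boundaries[phase] = (float(tp.min()), float(tp.max()))
    return compute_phase_changes(lines, boundaries, well_id=well_id)


def analyze_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well phase-change analysis of a whole plate.

    Expects columns well_id, cycle_time_s, phase, yfp, nluc (agonist and
    conc_M are carried through when present).
    """
    rows = []
    for well_id, df in plate.groupby("well_id", sort=True):
        res = analyze_well(df, well_id=str(well_id))
        row = {
            "well_id": well_id,
            "agonist_change": res.agonist_change,
            "additional_change": res.additional_change,
            "max_change": res.max_change,
            "normalized_agonist_change": res.normalized_agonist_change,
            "degenerate": res.degenerate,
        }
        for extra in ("agonist", "conc_M"):
            if extra in df.columns:
                row[extra] = df[extra].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
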