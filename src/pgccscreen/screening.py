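"""Plate normalization, response transform and screen categorization.

Each plate carries control wells (untreated) alongside compound wells; a
compound's normalized count for a quantity (PGCC, non-PGCC, total live) is
its well count divided by the mean of the plate's control wells for the same
quantity.  The machine-learning prediction target is
``y = log2(normalized PGCC count + 1e-3)``; more negative means stronger
PGCC inhibition.

Compound categories (flags are independent and may co-occur):

=================  =============================================
total_inhibited    normalized total live count <= 0.5
pgcc_enriched      normalized PGCC count >= 2
pgcc_reduced_2x    normalized PGCC count <= 0.5
pgcc_reduced_10x   normalized PGCC count <= 0.1
dual_inhibitor     normalized PGCC and non-PGCC counts both <= 0.5
=================  =============================================

"At least k-fold reduction" is read as ratio <= 1/k with inclusive
boundaries throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import WellCounts

__all__ = [
    "PSEUDOCOUNT",
    "CATEGORY_NAMES",
    "PlateLayout",
    "normalize_plate",
    "transform_response",
    "inverse_transform_response",
    "categorize_compound",
    "summarize_screen",
]

#: Pseudocount added to the normalized PGCC ratio before the log2 transform,
#: keeping wells with zero surviving PGCCs finite.
PSEUDOCOUNT: float = 1e-3

CATEGORY_NAMES: tuple[str, ...] = (
    "total_inhibited",
    "pgcc_enriched",
    "pgcc_reduced_2x",
    "pgcc_reduced_10x",
    "dual_inhibitor",
)


@dataclass
class PlateLayout:
    """Maps wells to their role: control or a specific compound.

    The screening format places 88 test conditions and 8 control wells on a
    96-well plate; any layout with >= 1 control well is accepted.
    """

    plate_id: str
    control_wells: list[str]
    compound_wells: dict[str, str] = field(default_factory=dict)  # well -> compound

    def __post_init__(self) -> None:
        if not self.control_wells:
            raise ValueError(f"plate {self.plate_id} has no control wells")
        overlap = set(self.control_wells) & set(self.compound_wells)
        if overlap:
            raise ValueError(f"wells assigned both roles: {sorted(overlap)}")

    @classmethod
    def from_frame(cls, platemap: pd.DataFrame, plate_id: str) -> "PlateLayout":
        """Build from a plate-map table (well_id, plate_id, role, compound_id)."""
        sub = platemap[platemap["plate_id"].astype(str) == str(plate_id)]
        controls = sub.loc[sub["role"] == "control", "well_id"].astype(str).tolist()
        cmpds = {
            str(r.well_id): str(r.compound_id)
            for r in sub[sub["role"] == "compound"].itertuples()
        }
        return cls(plate_id=str(plate_id), control_wells=controls, compound_wells=cmpds)


def transform_response(norm_pgcc: float | np.ndarray) -> float | np.ndarray:
    """log2(normalized PGCC count + 1e-3); strictly increasing."""
    arr = np.asarray(norm_pgcc, dtype=float)
    if np.any(arr < 0):
        raise ValueError("normalized PGCC count must be non-negative")
    out = np.log2(arr + PSEUDOCOUNT)
    return float(out) if np.isscalar(norm_pgcc) or arr.ndim == 0 else out


def inverse_transform_response(y: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`transform_response` (for round-trip checks/plots)."""
    arr = np.asarray(y, dtype=float)
    out = np.exp2(arr) - PSEUDOCOUNT
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def _control_means(
    counts_by_well: dict[str, WellCounts], layout: PlateLayout, statistic: str
) -> dict[str, float]:
    missing = [w for w in layout.control_wells if w not in counts_by_well]
    if missing:
        raise ValueError(f"missing counts for control wells {missing}")
    agg = np.median if statistic == "median" else np.mean
    ctrl = [counts_by_well[w] for w in layout.control_wells]
    return {
        "pgcc": float(agg([c.n_pgcc for c in ctrl])),
        "nonpgcc": float(agg([c.n_nonpgcc for c in ctrl])),
        "total": float(agg([c.n_live for c in ctrl])),
    }


def normalize_plate(
    counts: list[WellCounts],
    layout: PlateLayout,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Per-compound normalized counts and the log2 prediction target.

    Each compound well's PGCC / non-PGCC / total-live count is divided by the
    plate's control aggregate (arithmetic mean by default; median optional)
    of the same quantity.  "Total" means total live (PGCC + non-PGCC); dead
    cells never enter the ratios.  A zero control aggregate yields a flagged
    undefined ratio (NaN + ``excluded_reason``), not an exception.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    counts_by_well = {c.well_id: c for c in counts}
    ctrl = _control_means(counts_by_well, layout, statistic)
    rows = []
    for well, compound in layout.compound_wells.items():
        if well not in counts_by_well:
            raise ValueError(f"missing counts for compound well {well}")
        wc = counts_by_well[well]
        reason = ""
        ratios = {}
        for key, numer in (
            ("pgcc", wc.n_pgcc),
            ("nonpgcc", wc.n_nonpgcc),
            ("total", wc.n_live),
        ):
            if ctrl[key] == 0:
                ratios[key] = np.nan
                reason = f"zero control {key} count"
            else:
                ratios[key] = numer / ctrl[key]
        rows.append(
            {
                "compound_id": compound,
                "plate_id": layout.plate_id,
                "well_id": well,
                "norm_pgcc": ratios["pgcc"],
                "norm_nonpgcc": ratios["nonpgcc"],
                "norm_total": ratios["total"],
                "y_target": (
                    transform_response(ratios["pgcc"])
                    if np.isfinite(ratios["pgcc"])
                    else np.nan
                ),
                "excluded": bool(reason),
                "excluded_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def categorize_compound(
    norm_total: float, norm_pgcc: float, norm_nonpgcc: float
) -> set[str]:
    """Category flags for one compound; see the module docstring for rules."""
    if any(not np.isfinite(v) for v in (norm_total, norm_pgcc, norm_nonpgcc)):
        raise ValueError("undefined ratios: compound is unclassifiable")
    flags = set()
    if norm_total <= 0.5:
        flags.add("total_inhibited")
    if norm_pgcc >= 2:
        flags.add("pgcc_enriched")
    if norm_pgcc <= 0.5:
        flags.add("pgcc_reduced_2x")
    if norm_pgcc <= 0.1:
        flags.add("pgcc_reduced_10x")
    if norm_pgcc <= 0.5 and norm_nonpgcc <= 0.5:
        flags.add("dual_inhibitor")
    return flags


def summarize_screen(
    table: pd.DataFrame, exclusions: list[str] | None = None
) -> dict[str, int]:
    """Screen-level summary: library size, screened size and category counts.

    ``exclusions`` lists compounds removed before any thresholding (e.g.
    fluorescent compounds that interfere with imaging).  Compounds with
    undefined ratios are reported as unclassifiable.  An exclusion id absent
    from the library triggers a warning, not an error.
    """
    exclusions = exclusions or []
    library_ids = set(table["compound_id"].astype(str))
    unknown = [e for e in exclusions if e not in library_ids]
    if unknown:
        warnings.warn(f"exclusion ids not in library: {unknown}", stacklevel=2)
    excluded = set(exclusions) & library_ids
    screened = table[~table["compound_id"].astype(str).isin(excluded)]
    summary = {
        "library_size": len(library_ids),
        "excluded": len(excluded),
        "screened": len(library_ids) - len(excluded),
        "unclassifiable": 0,
    }
    for name in CATEGORY_NAMES:
        summary[name] = 0
    for row in screened.itertuples():
        try:
            flags = categorize_compound(row.norm_total, row.norm_pgcc, row.norm_nonpgcc)
        except ValueError:
            summary["unclassifiable"] += 1
            continue
        for f in flags:
            summary[f] += 1
    return summary
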