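"""Ring-level xylem anatomical traits from cell-level tracheid records.

A conifer ring is a radial file of tracheids that starts with wide,
thin-walled earlywood cells and ends with narrow, thick-walled latewood
cells.  This module classifies cells into the two zones with Mork's
index, and aggregates cell measurements into per-ring traits:

* ``EWW`` / ``LWW`` — earlywood / latewood width (summed radial cell
  extents per zone, μm),
* ``CWT.ew`` / ``CWT.lw`` — mean cell wall thickness per zone (μm),
* ``DEN.ew`` / ``DEN.lw`` — anatomical wood density, the cell-wall area
  fraction CWA / (CWA + LA) per zone,
* ``DH.ew`` / ``DH.lw`` — hydraulically weighted mean conduit diameter
  Σd⁵ / Σd⁴ per zone (μm).

Lumen diameter is taken as the equivalent-circle diameter of the lumen
area, d = 2·sqrt(LA/π); the cell wall area of a single tracheid is
approximated by the wall band around that circle, CWA = 4·CWT·(d + CWT).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ring-trait column names, in canonical order.
TRAIT_COLUMNS = [
    "EWW", "LWW", "CWT.ew", "CWT.lw",
    "DEN.ew", "DEN.lw", "DH.ew", "DH.lw",
]

#: Mork's-index threshold: a cell is latewood when 4·CWT/d ≥ this.
MORK_THRESHOLD = 1.0


@dataclass
class CellRecord:
    """One tracheid measurement.

    Radial position is μm from the earlywood edge of the ring; ``LA``
    is lumen area (μm²), ``CWT`` the mean wall thickness (μm) and
    ``radial_extent`` the cell's radial footprint (μm).
    """

    tree_id: str
    year: int
    radial_position: float
    radial_extent: float
    LA: float
    CWT: float


def equivalent_diameter(lumen_area) -> np.ndarray | float:
    """Equivalent-circle diameter of a lumen area: d = 2·sqrt(LA/π)."""
    return 2.0 * np.sqrt(np.asarray(lumen_area, dtype=float) / math.pi)


def mork_index(cwt: float, lumen_diameter: float) -> float:
    """Mork's index 4·CWT / lumen diameter.

    Cells with index ≥ 1 are latewood.  A zero lumen diameter (fully
    occluded cell) is classified latewood by convention.
    """
    if lumen_diameter < 0:
        raise ValueError("lumen diameter must be non-negative")
    if lumen_diameter == 0:
        logger.warning("zero lumen diameter: classified latewood by convention")
        return math.inf
    return 4.0 * cwt / lumen_diameter


def is_latewood(cwt, lumen_diameter) -> np.ndarray:
    """Vectorized latewood classification by Mork's index."""
    cwt = np.asarray(cwt, dtype=float)
    d = np.asarray(lumen_diameter, dtype=float)
    with np.errstate(divide="ignore"):
        idx = np.where(d > 0, 4.0 * cwt / np.where(d > 0, d, 1.0), np.inf)
    return idx >= MORK_THRESHOLD


def cell_wall_area(la, cwt) -> np.ndarray:
    """Wall-band approximation of single-cell wall area.

    The wall is modelled as a band of thickness CWT around the
    equivalent circle: CWA = 4·CWT·(d + CWT).
    """
    d = equivalent_diameter(la)
    cwt = np.asarray(cwt, dtype=float)
    return 4.0 * cwt * (d + cwt)


def anatomical_density(cwa: float, la: float) -> float:
    """Anatomical wood density DEN = CWA / (CWA + LA), in [0, 1]."""
    if cwa < 0 or la < 0:
        raise ValueError("areas must be non-negative")
    if cwa + la == 0:
        raise ValueError("CWA + LA must be positive")
    return cwa / (cwa + la)


def hydraulic_diameter(lumen_areas) -> float:
    """Hydraulically weighted mean diameter Σd⁵/Σd⁴ from lumen areas.

    Converts each lumen area to its equivalent-circle diameter and
    weights by d⁴ (Hagen-Poiseuille conductance), so the largest
    conduits, which dominate flow, dominate the mean.
    """
    la = np.asarray(lumen_areas, dtype=float)
    if la.size == 0:
        raise ValueError("empty lumen-area collection")
    if np.any(la <= 0):
        raise ValueError("lumen areas must be positive")
    d = equivalent_diameter(la)
    return float(np.sum(d ** 5) / np.sum(d ** 4))


def _zone_traits(zone: pd.DataFrame) -> tuple[float, float, float, float]:
    """(width, CWT mean, DEN, DH) for the cells of one zone."""
    width = float(zone["radial_extent_um"].sum())
    cwt = float(zone["cwt_um"].mean())
    cwa = float(cell_wall_area(zone["lumen_area_um2"], zone["cwt_um"]).sum())
    la = float(zone["lumen_area_um2"].sum())
    den = anatomical_density(cwa, la)
    dh = hydraulic_diameter(zone["lumen_area_um2"].to_numpy())
    return width, cwt, den, dh


def aggregate_ring(cells: pd.DataFrame) -> dict:
    """Aggregate the cells of one tree-year into a ring-trait row.

    Zones come from per-cell Mork's index.  A ring in which one zone is
    empty gets width 0 for that zone and NaN for its other traits, with
    an ``incomplete_ring`` flag.
    """
    if len(cells) == 0:
        raise ValueError("ring must contain at least one cell")
    d = equivalent_diameter(cells["lumen_area_um2"])
    lw = is_latewood(cells["cwt_um"], d)

    row: dict = {
        "tree_id": cells["tree_id"].iloc[0],
        "year": int(cells["year"].iloc[0]),
        "incomplete_ring": False,
    }
    for zone_name, mask in (("ew", ~lw), ("lw", lw)):
        zone = cells.loc[mask]
        wkey = "EWW" if zone_name == "ew" else "LWW"
        if len(zone) == 0:
            row[wkey] = 0.0
            row[f"CWT.{zone_name}"] = np.nan
            row[f"DEN.{zone_name}"] = np.nan
            row[f"DH.{zone_name}"] = np.nan
            row["incomplete_ring"] = True
            logger.warning(
                "tree %s year %s: empty %swood zone",
                row["tree_id"], row["year"], "early" if zone_name == "ew" else "late",
            )
            continue
        width, cwt, den, dh = _zone_traits(zone)
        row[wkey] = width
        row[f"CWT.{zone_name}"] = cwt
        row[f"DEN.{zone_name}"] = den
        row[f"DH.{zone_name}"] = dh
    return row


def cells_to_traits(cells: pd.DataFrame) -> pd.DataFrame:
    """Ring-trait table (one row per tree-year) from a cell table.

    Expects columns ``tree_id, year, radial_position_um,
    radial_extent_um, lumen_area_um2, cwt_um``.
    """
    rows = [
        aggregate_ring(grp)
        for _, grp in cells.groupby(["tree_id", "year"], sort=True)
    ]
    out = pd.DataFrame(rows)
    return out.sort_values(["tree_id", "year"]).reset_index(drop=True)


def pca_summary(traits: pd.DataFrame) -> np.ndarray:
    """Variance-explained fractions of the trait correlation matrix.

    Standardizes each trait column and eigen-decomposes the correlation
    matrix; returns the fractions (descending), which sum to 1.  Used to
    summarize redundancy among anatomical traits before selecting one
    representative per trait group.
    """
    x = np.asarray(traits, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.any(np.isnan(x)):
        raise ValueError("missing values not allowed in PCA input")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"constant trait column(s) at index {bad}: zero variance")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()
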