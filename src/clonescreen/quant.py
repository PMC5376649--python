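"""Image- and assay-derived quantification statistics.

Covers the small downstream statistics of a clonal-growth study: the
semi-quantitative H-score of immunostaining intensity, nuclear/cytoplasmic
localization categories from median-intensity ratios, colony-forming
efficiency with a minimum colony-area filter, ΔΔCt relative expression and
positive-cell fractions.  Inputs are per-cell / per-colony tables produced
upstream by imaging software; segmentation and background subtraction are
out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

LOCALIZATION_CATEGORIES = ("N>C", "N=C", "N<C")

#: Default half-width (log2 units) of the "N=C" band around ratio 1.
DEFAULT_LOC_TOL = 0.2

#: Default minimum colony area (mm^2) retained by the particle filter.
DEFAULT_MIN_AREA = 0.01


# ---------------------------------------------------------------------------
# Nuclear / cytoplasmic localization
# ---------------------------------------------------------------------------

def nuclear_cytoplasmic_ratio(nucleus_median: float, cytoplasm_median: float) -> float:
    """Ratio of median nuclear to median cytoplasmic fluorescence intensity."""
    if nucleus_median < 0 or cytoplasm_median < 0:
        raise ValidationError("intensities must be non-negative")
    if cytoplasm_median == 0:
        raise ValidationError("cytoplasm median intensity is zero; cell unquantifiable")
    return nucleus_median / cytoplasm_median


def nc_ratios(cells: pd.DataFrame) -> pd.Series:
    """Per-cell N/C ratios from a table with columns
    nucleus_median / cytoplasm_median (indexed by cell id).

    Cells with zero cytoplasmic signal are unquantifiable: they are
    excluded from the result and logged.
    """
    for col in ("nucleus_median", "cytoplasm_median"):
        if col not in cells.columns:
            raise ValidationError(f"cell table lacks column {col!r}")
    bad = cells.index[cells["cytoplasm_median"] <= 0]
    if len(bad):
        logger.warning(
            "%d cell(s) excluded (zero cytoplasmic signal): %s%s",
            len(bad), list(bad[:5]), "..." if len(bad) > 5 else "",
        )
    ok = cells.drop(index=bad)
    return ok["nucleus_median"] / ok["cytoplasm_median"]


def classify_localization(ratio: float, tol: float = DEFAULT_LOC_TOL) -> str:
    """Categorize a cell's N/C ratio as "N>C", "N=C" or "N<C".

    "N=C" when |log2(ratio)| <= tol; the category is invariant to scaling
    both intensities by the same factor.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    l2 = math.log2(ratio)
    if abs(l2) <= tol:
        return "N=C"
    return "N>C" if l2 > tol else "N<C"


def localization_distribution(
    ratios: Sequence[float] | pd.Series, tol: float = DEFAULT_LOC_TOL
) -> dict[str, float]:
    """Percentage of cells in each localization category (sums to 100)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValidationError("no cells to classify")
    cats = [classify_localization(r, tol) for r in ratios]
    return {
        c: 100.0 * cats.count(c) / len(cats) for c in LOCALIZATION_CATEGORIES
    }


# ---------------------------------------------------------------------------
# H-score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryDistribution:
    """Percentages of cells at staining intensity categories 0-3."""

    p0: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        ps = (self.p0, self.p1, self.p2, self.p3)
        # tolerate float round-off at the boundaries, same order as the sum check
        if any(not -1e-6 <= p <= 100 + 1e-6 for p in ps):
            raise ValidationError("category percentages must lie in [0, 100]")
        if abs(sum(ps) - 100.0) > 1e-6:
            raise ValidationError(
                f"category percentages sum to {sum(ps)!r}, expected 100"
            )


def h_score(dist: CategoryDistribution | Sequence[float]) -> float:
    """Semi-quantitative immunostaining H-score in [0, 300].

    H = (% cells at category 1)·1 + (% at category 2)·2 + (% at category 3)·3,
    where categories 0-3 grade staining intensity from absent to strong.
    A population entirely at category 3 scores 300.
    """
    if not isinstance(dist, CategoryDistribution):
        dist = CategoryDistribution(*dist)
    return dist.p1 * 1 + dist.p2 * 2 + dist.p3 * 3


# ---------------------------------------------------------------------------
# Colony statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColonyStats:
    """CFE and the filtered colony-area distribution summary."""

    cfe_percent: float
    colonies_per_well: dict[str, int]
    n_colonies: int
    n_excluded: int
    area_median: float
    area_q1: float
    area_q3: float

    def summary(self) -> str:
        return (
            f"CFE {self.cfe_percent:.2f}% over {len(self.colonies_per_well)} well(s); "
            f"{self.n_colonies} colonies retained ({self.n_excluded} below the "
            f"area filter); area median {self.area_median:.3g} mm^2 "
            f"[IQR {self.area_q1:.3g}-{self.area_q3:.3g}]"
        )


def colony_stats(
    colonies: pd.DataFrame,
    cells_seeded: Mapping[str, int] | int,
    min_area: float = DEFAULT_MIN_AREA,
) -> ColonyStats:
    """Colony-forming efficiency and area distribution after size filtering.

    ``colonies`` has columns well_id and area_mm2 (one row per detected
    particle).  Particles smaller than ``min_area`` (default 0.01 mm^2)
    are excluded before counting.  CFE is the mean over wells of
    100 x colonies / cells seeded; ``cells_seeded`` maps well_id to the
    number of seeded cells (an int applies to every well).
    """
    for col in ("well_id", "area_mm2"):
        if col not in colonies.columns:
            raise ValidationError(f"colony table lacks column {col!r}")
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    wells_in_table = list(pd.unique(colonies["well_id"]))
    if isinstance(cells_seeded, int):
        seeded = {w: cells_seeded for w in wells_in_table}
    else:
        seeded = dict(cells_seeded)
        unknown = set(wells_in_table) - set(seeded)
        if unknown:
            raise ValidationError(f"wells without seeding counts: {sorted(unknown)}")
    if not seeded:
        raise ValidationError("no wells")
    if any(v <= 0 for v in seeded.values()):
        raise ValidationError("cells seeded per well must be positive")

    kept = colonies[colonies["area_mm2"] >= min_area]
    n_excluded = len(colonies) - len(kept)
    per_well = {
        w: int((kept["well_id"] == w).sum()) for w in seeded
    }
    cfe = float(np.mean([100.0 * per_well[w] / seeded[w] for w in seeded]))
    areas = kept["area_mm2"].to_numpy(float)
    if areas.size:
        q1, med, q3 = np.percentile(areas, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    return ColonyStats(
        cfe_percent=cfe,
        colonies_per_well=per_well,
        n_colonies=int(len(kept)),
        n_excluded=int(n_excluded),
        area_median=float(med),
        area_q1=float(q1),
        area_q3=float(q3),
    )


# ---------------------------------------------------------------------------
# qPCR relative expression and positive fractions
# ---------------------------------------------------------------------------

def relative_expression(
    ct_target_sample: float,
    ct_housekeeping_sample: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """ΔΔCt fold change of a target transcript versus a control condition.

    ΔΔCt = (Ct_target − Ct_housekeeping)_sample − (Ct_target − Ct_housekeeping)_control,
    fold = 2^−ΔΔCt (amplification efficiency fixed at 2; the housekeeping
    gene, e.g. 18S rRNA, normalizes input amounts).
    """
    cts = (ct_target_sample, ct_housekeeping_sample, ct_target_control, ct_housekeeping_control)
    if any(not math.isfinite(c) for c in cts):
        raise ValidationError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_housekeeping_sample) - (
        ct_target_control - ct_housekeeping_control
    )
    return 2.0 ** (-ddct)


def log2_relative_expression(
    ct_target_sample: float,
    ct_housekeeping_sample: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """log2 of the ΔΔCt fold change (= −ΔΔCt)."""
    return math.log2(
        relative_expression(
            ct_target_sample,
            ct_housekeeping_sample,
            ct_target_control,
            ct_housekeeping_control,
        )
    )


def positive_fraction(n_positive: int, n_total: int) -> float:
    """Percentage of positive cells (e.g. Ki67+ cells, expanding clones)."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if n_positive < 0 or n_positive > n_total:
        raise ValidationError("need 0 <= n_positive <= n_total")
    return 100.0 * n_positive / n_total
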