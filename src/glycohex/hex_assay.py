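"""Hexosaminidase activity assay processing and viability computation.

Fluorometric plate readings are converted to enzyme activities via a 4-MU
(4-methylumbelliferone) standard curve:

    activity = ((mean sample fluorescence - mean blank) / slope)
               / incubation time / input amount

in 4-MU amount per minute per input amount (ug protein or ul plasma). MUG
wells report total Hex activity, MUGS wells the HEXA-specific activity, and
the HEXB proxy is max(MUG - MUGS, 0) — a negative difference is biologically
impossible and clamped with a warning. Cross-plate comparability comes from
normalizing each plate to the mean activity of its control samples
("relative activity units", controls average 1.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StandardCurve",
    "ActivityResult",
    "fit_standard_curve",
    "quantify_activity",
    "hexb_proxy",
    "normalize_plate",
    "viability",
    "process_plate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of fluorescence against 4-MU concentration."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class ActivityResult:
    """Per-sample activities (one plate): raw and plate-normalized."""

    activities: pd.DataFrame  # index sample_id; columns mug, mugs, hexb, mug_cv, mugs_cv
    relative: pd.DataFrame    # same index; columns mug, mugs, hexb in relative units
    curve: StandardCurve


def fit_standard_curve(
    concentrations: Sequence[float], fluorescence: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares standard curve; warns if R^2 < 0.98.

    Requires at least 3 distinct concentrations and a positive fitted slope.
    """
    conc = np.asarray(concentrations, dtype=float)
    fluo = np.asarray(fluorescence, dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    res = sps.linregress(conc, fluo)
    if res.slope <= 0:
        raise ValueError(f"fitted standard-curve slope {res.slope:g} is not positive")
    r2 = float(res.rvalue**2)
    if r2 < 0.98:
        logger.warning("standard curve R^2 = %.4f below 0.98; check calibration", r2)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def quantify_activity(
    well_fluorescence: Sequence[float],
    curve: StandardCurve,
    blank_fluorescence: Sequence[float],
    incubation_min: float,
    input_amount: float,
) -> tuple[float, Optional[float]]:
    """Activity of one sample/substrate from its replicate wells.

    Mean replicate fluorescence minus mean blank, through the curve slope,
    per minute per input amount. Negative blank-corrected products clamp to
    0 with a warning. Returns (activity, replicate CV) — the CV is None with
    fewer than 2 replicates.
    """
    wells = np.asarray(well_fluorescence, dtype=float)
    blanks = np.asarray(blank_fluorescence, dtype=float)
    if blanks.size == 0:
        raise ValueError("blank wells are required")
    if wells.size == 0:
        raise ValueError("no replicate wells supplied")
    if incubation_min <= 0 or input_amount <= 0:
        raise ValueError("incubation time and input amount must be positive")
    signal = wells.mean() - blanks.mean()
    product = signal / curve.slope
    if product < 0:
        logger.warning("blank-corrected signal negative (%.3g); activity clamped to 0", product)
        product = 0.0
    activity = product / incubation_min / input_amount
    cv = None
    if wells.size >= 2 and wells.mean() != 0:
        cv = float(wells.std(ddof=1) / abs(wells.mean()))
    return float(activity), cv


def hexb_proxy(mug: float, mugs: float) -> float:
    """HEXB activity proxy: max(MUG - MUGS, 0); clamping is logged."""
    if mug is None or mugs is None or not np.isfinite([mug, mugs]).all():
        raise ValueError("both MUG and MUGS activities are required")
    diff = mug - mugs
    if diff < 0:
        logger.warning("MUGS (%.3g) exceeds MUG (%.3g); HEXB proxy clamped to 0 "
                       "(possible assay failure)", mugs, mug)
        return 0.0
    return float(diff)


def normalize_plate(
    activities: Mapping[str, float] | pd.Series, control_ids: Sequence[str], stat: str = "mean"
) -> pd.Series:
    """Divide every activity by the plate's control aggregate (mean by default).

    Controls average to 1.0 afterwards; output is in relative activity
    units, invariant to plate-level batch factors.
    """
    act = pd.Series(dict(activities), dtype=float) if not isinstance(activities, pd.Series) else activities.astype(float)
    controls = [c for c in control_ids if c in act.index]
    if not controls:
        raise ValueError("no control samples on the plate")
    ref = float(act.loc[controls].mean()) if stat == "mean" else float(act.loc[controls].median())
    if ref <= 0:
        raise ValueError("control aggregate activity is not positive")
    return act / ref


def viability(abs_treated: float, abs_vehicle: float, abs_blank: float) -> float:
    """Percent viability relative to vehicle after blank subtraction."""
    if abs_vehicle <= abs_blank:
        raise ValueError("vehicle absorbance must exceed blank absorbance")
    return 100.0 * (abs_treated - abs_blank) / (abs_vehicle - abs_blank)


def process_plate(plate: pd.DataFrame, control_ids: Optional[Sequence[str]] = None) -> ActivityResult:
    """End-to-end processing of one plate-layout table.

    Expects the layout emitted by the synthetic generator (columns: well,
    role, sample_id, substrate, replicate, concentration, fluorescence) with
    incubation time and input amount in ``plate.attrs``. Fits the standard
    curve, quantifies MUG/MUGS per sample, derives the HEXB proxy, and
    normalizes to the plate controls when control ids are available.
    """
    incubation = float(plate.attrs.get("incubation_min", 30.0))
    amount = float(plate.attrs.get("input_amount", 1.0))
    if control_ids is None:
        control_ids = plate.attrs.get("control_ids", [])

    std = plate[plate["role"] == "standard"]
    curve = fit_standard_curve(std["concentration"], std["fluorescence"])
    blanks = plate.loc[plate["role"] == "blank", "fluorescence"].to_numpy()

    records = {}
    samples = plate[plate["role"] == "sample"]
    for sample_id, sub in samples.groupby("sample_id"):
        rec = {}
        for substrate in ("MUG", "MUGS"):
            wells = sub.loc[sub["substrate"] == substrate, "fluorescence"].to_numpy()
            if wells.size == 0:
                raise ValueError(f"sample {sample_id!r} has no {substrate} wells")
            act, cv = quantify_activity(wells, curve, blanks, incubation, amount)
            rec[substrate.lower()] = act
            rec[f"{substrate.lower()}_cv"] = cv
        rec["hexb"] = hexb_proxy(rec["mug"], rec["mugs"])
        records[sample_id] = rec
    activities = pd.DataFrame.from_dict(records, orient="index")
    activities.index.name = "sample_id"

    relative = pd.DataFrame(index=activities.index)
    if control_ids:
        for col in ("mug", "mugs", "hexb"):
            try:
                relative[col] = normalize_plate(activities[col], control_ids)
            except ValueError:
                relative[col] = np.nan
    else:
        relative[["mug", "mugs", "hexb"]] = np.nan
    return ActivityResult(activities=activities, relative=relative, curve=curve)
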