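"""Enzyme-assay arithmetic: standard curves, initial rates, specific activity.

The measurement chain emulated here is a plate-reader kinetic assay: NAD(P)H
formation followed at 340 nm (or formaldehyde by Nash reagent at 412 nm),
absorbance converted to concentration through a standard curve, the initial
rate taken as the least-squares slope over the early linear phase, and the
rate converted to enzyme units.

One unit (U) is defined here, following the assay protocol reproduced, as
the enzyme converting 1 mM of substrate per minute in the reaction mix — a
concentration rate.  The conventional amount-based unit (1 umol/min) is
available via ``units="umol"`` together with the reaction volume (200 uL in
the protocol).  Protein in whole-cell assays is estimated from OD600 under
the rule that 1 L of culture at OD600 = 1 holds 0.250 g biomass, half of it
protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayTrace",
    "ActivityResult",
    "fit_standard_curve",
    "initial_rate",
    "specific_activity",
    "protein_from_od",
    "phb_content",
    "DEFAULT_REACTION_VOLUME_L",
]

DEFAULT_REACTION_VOLUME_L = 200e-6  # 200 uL assay mix
R2_WARN_THRESHOLD = 0.98


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-concentration calibration."""

    analyte: str
    slope: float  # AU per mM
    intercept: float  # AU
    r_squared: float

    def to_concentration(self, absorbance) -> np.ndarray:
        """Invert the curve: AU -> mM."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class AssayTrace:
    """One kinetic read: absorbance vs time."""

    times: tuple  # minutes, strictly increasing
    absorbances: tuple  # AU
    wavelength: float = 340.0  # nm
    replicate_id: str = "r1"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size != a.size:
            raise ValueError("times and absorbances must have equal length")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", tuple(t.tolist()))
        object.__setattr__(self, "absorbances", tuple(a.tolist()))


@dataclass(frozen=True)
class ActivityResult:
    rate: float  # mM/min in the assay mix
    total_units: float  # U under the selected unit convention
    specific_activity: float  # mU per mg protein
    protein_mg: float
    units: str = "paper"  # "paper" (mM/min) or "umol" (umol/min)


def _r_squared(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-30:
        # constant response: a flat fit explains it perfectly
        return 1.0 if ss_res <= 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_standard_curve(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str = "NADH",
) -> StandardCurve:
    """Ordinary least squares line (free intercept) through calibration points.

    Requires >= 3 points and >= 2 distinct concentrations.  A fit with
    r^2 below 0.98 triggers a :class:`UserWarning` — the curve is returned
    anyway, the caller decides.
    """
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if conc.size != ab.size:
        raise ValueError("concentrations and absorbances must have equal length")
    if conc.size < 3:
        raise ValueError("a standard curve needs at least 3 points")
    if np.unique(conc).size < 2:
        raise ValueError("degenerate design: all concentrations equal")
    fit = stats.linregress(conc, ab)
    r2 = _r_squared(conc, ab, fit.slope, fit.intercept)
    if r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"standard curve r^2 = {r2:.4f} below {R2_WARN_THRESHOLD}; "
            "calibration may be unreliable",
            UserWarning,
            stacklevel=2,
        )
    return StandardCurve(analyte=analyte, slope=float(fit.slope),
                         intercept=float(fit.intercept), r_squared=float(r2))


def initial_rate(
    trace: AssayTrace,
    curve: StandardCurve,
    window: Optional[int] = None,
    r2_threshold: float = R2_WARN_THRESHOLD,
    blank: float = 0.0,
) -> float:
    """Initial reaction rate (mM/min) from an absorbance trace.

    Absorbances (optionally blank-subtracted) are converted to concentration
    through ``curve`` and a least-squares slope is fitted over the first
    ``window`` points.  When ``window`` is None the first 5 points are used,
    falling back to the longest prefix whose linear fit has r^2 >=
    ``r2_threshold`` (the protocol reads "until a steady state is reached";
    the prefix rule operationalizes that).
    """
    t = np.asarray(trace.times, dtype=float)
    conc = curve.to_concentration(np.asarray(trace.absorbances, dtype=float) - blank)

    def slope_of(k: int) -> tuple:
        fit = stats.linregress(t[:k], conc[:k])
        return float(fit.slope), _r_squared(t[:k], conc[:k], fit.slope, fit.intercept)

    if window is not None:
        if not 2 <= window <= t.size:
            raise ValueError(f"window must be in [2, {t.size}], got {window}")
        return slope_of(window)[0]

    k = min(5, t.size)
    slope, r2 = slope_of(k)
    if r2 >= r2_threshold:
        return slope
    # longest linear prefix; 2 points are always exactly linear
    for k in range(t.size, 1, -1):
        slope, r2 = slope_of(k)
        if r2 >= r2_threshold:
            return slope
    return slope_of(2)[0]


def specific_activity(
    rate: float,
    protein_mg: float,
    units: str = "paper",
    reaction_volume_l: float = DEFAULT_REACTION_VOLUME_L,
) -> ActivityResult:
    """Convert an initial rate into total and specific activity.

    ``units="paper"`` applies the concentration-based unit definition
    literally: U = mM substrate per minute, so ``total_units == rate``.
    ``units="umol"`` applies the conventional amount-based definition,
    U = umol/min = rate [mM/min] x reaction volume [L] x 1000.
    Specific activity is 1000 x U / protein_mg, reported in mU/mg.
    """
    if protein_mg <= 0:
        raise ValueError(f"protein mass must be positive, got {protein_mg}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if units == "paper":
        total = rate
    elif units == "umol":
        if reaction_volume_l <= 0:
            raise ValueError("reaction volume must be positive")
        total = rate * reaction_volume_l * 1000.0
    else:
        raise ValueError(f"units must be 'paper' or 'umol', got {units!r}")
    return ActivityResult(
        rate=rate,
        total_units=total,
        specific_activity=1000.0 * total / protein_mg,
        protein_mg=protein_mg,
        units=units,
    )


def protein_from_od(od600: float, culture_volume_l: float) -> float:
    """Protein (mg) in a culture, from optical density.

    Rule: 1 L at OD600 = 1 contains 0.250 g dry biomass, half of which is
    protein, i.e. 125 mg protein per OD-liter.
    """
    if od600 < 0:
        raise ValueError(f"OD600 must be >= 0, got {od600}")
    if culture_volume_l <= 0:
        raise ValueError(f"culture volume must be positive, got {culture_volume_l}")
    return od600 * culture_volume_l * 250.0 * 0.5


def phb_content(phb_conc_g_l: float, cell_conc_g_l: float) -> float:
    """PHB content, percent w/w of dry cell weight.

    Both inputs are dry weights per liter of culture broth; PHB is part of
    the cell mass, so a PHB concentration exceeding the cell concentration
    is an inconsistent measurement and raises.
    """
    if cell_conc_g_l <= 0:
        raise ValueError(f"cell concentration must be positive, got {cell_conc_g_l}")
    if phb_conc_g_l < 0:
        raise ValueError(f"PHB concentration must be >= 0, got {phb_conc_g_l}")
    if phb_conc_g_l > cell_conc_g_l:
        raise ValueError(
            f"inconsistent input: PHB {phb_conc_g_l} g/L exceeds cell mass {cell_conc_g_l} g/L"
        )
    return 100.0 * phb_conc_g_l / cell_conc_g_l
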