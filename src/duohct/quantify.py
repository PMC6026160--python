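"""PSL → activity calibration and distribution-volume / hematocrit maps.

The diluted-blood reference spot on each plate has a known activity
concentration (whole blood over the dilution factor), so the mean PSL over
the spot fixes a single MBq/g-per-PSL factor per isotope image.  Because
spot and tissue share plate gain, section thickness and density, those all
cancel — the calibration is what makes the maps quantitative.

From the calibrated single-isotope concentration images the tracer
distribution volumes follow as percent of tissue mass:

    Vrbc = 100 · C_tc / c_tc_rbc        (RBC tracer vs pure-RBC reference)
    Vp   = 100 · C_i  / c_i_plasma      (albumin tracer vs plasma reference)
    Vv   = Vp + Vrbc
    tHct = Vrbc / (Vrbc + Vp)           (masked where Vv is too small)

The same ratios applied to weighed gamma-well-counted samples give the
scalar (per-sample) hematocrit path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BloodPanel, PSLImage
from .separation import CalibrationError

__all__ = [
    "ActivityMap",
    "VolumeMaps",
    "GWCSample",
    "calibrate",
    "distribution_volume",
    "compose_maps",
    "gwc_hct",
    "arg_bhct",
    "percent_id_per_g",
]


@dataclass
class ActivityMap:
    """Per-pixel activity concentration in MBq/g at the reference time."""

    values: np.ndarray
    isotope_name: str
    calib_factor: float  # MBq/g per PSL

    def __post_init__(self) -> None:
        if self.calib_factor <= 0:
            raise ValueError("calib_factor must be > 0")


@dataclass
class VolumeMaps:
    """Co-registered Vp / Vrbc / Vv (%) and tHct (fraction) maps.

    ``thct_frac`` is NaN wherever Vv fell below the definition threshold
    ``vv_min_pct`` (avascular pixels have no meaningful hematocrit).
    """

    vp_pct: np.ndarray
    vrbc_pct: np.ndarray
    vv_pct: np.ndarray
    thct_frac: np.ndarray
    vv_min_pct: float


@dataclass(frozen=True)
class GWCSample:
    """One weighed, gamma-well-counted tissue sample (MBq/g at t = 0)."""

    tissue_id: str
    a_tc: float
    a_i: float
    mass_g: float

    def __post_init__(self) -> None:
        if self.a_tc < 0 or self.a_i < 0:
            raise ValueError("activities must be >= 0")
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")


def calibrate(psl: PSLImage, blood_mask: np.ndarray, known_conc: float,
              dilution: float, isotope_name: str = "") -> ActivityMap:
    """Convert a single-isotope PSL image to MBq/g using the diluted-blood
    reference spot.

    ``known_conc`` is the whole-blood concentration of the matching isotope
    at t = 0; the spot itself holds ``known_conc / dilution``.  The factor
    ``calib_factor = (known_conc / dilution) / mean(PSL[spot])`` then maps
    every pixel, cancelling plate gain and section mass.
    """
    if not blood_mask.any():
        raise CalibrationError("blood-spot mask is empty")
    spot_mean = float(psl.values[blood_mask].mean())
    if spot_mean <= 0:
        raise CalibrationError(f"blood-spot mean PSL is {spot_mean:.3g} (<= 0)")
    calib = (known_conc / dilution) / spot_mean
    return ActivityMap(values=psl.values * calib, isotope_name=isotope_name,
                       calib_factor=calib)


def distribution_volume(c_tissue: ActivityMap | np.ndarray,
                        c_reference_fraction: float) -> np.ndarray:
    """Tracer distribution volume in percent: 100 · C_tissue / C_reference.

    The reference is the concentration of the blood fraction the tracer
    lives in (RBC fraction for ⁹⁹ᵐTc, plasma fraction for ¹²⁵I).
    """
    if c_reference_fraction <= 0:
        raise ValueError("reference fraction concentration must be > 0")
    values = c_tissue.values if isinstance(c_tissue, ActivityMap) else np.asarray(c_tissue)
    return 100.0 * values / c_reference_fraction


def compose_maps(vp_pct: np.ndarray, vrbc_pct: np.ndarray,
                 vv_min_pct: float = 0.5) -> VolumeMaps:
    """Combine the two distribution volumes into Vv and tHct maps.

    ``vv = vp + vrbc`` exactly; ``thct = vrbc / vv`` where ``vv >= vv_min``
    and NaN elsewhere, so the near-avascular background never produces a
    0/0 hematocrit.
    """
    vp = np.asarray(vp_pct, dtype=float)
    vrbc = np.asarray(vrbc_pct, dtype=float)
    if vp.shape != vrbc.shape:
        raise ValueError("vp and vrbc shapes differ")
    vv = vp + vrbc
    thct = np.full(vv.shape, np.nan)
    defined = vv >= vv_min_pct
    thct[defined] = vrbc[defined] / vv[defined]
    return VolumeMaps(vp_pct=vp, vrbc_pct=vrbc, vv_pct=vv, thct_frac=thct,
                      vv_min_pct=vv_min_pct)


def gwc_hct(sample: GWCSample, panel: BloodPanel) -> float:
    """Hematocrit of one counted sample from its two tracer activities.

    The sample's RBC and plasma distribution volumes are formed against the
    blood-fraction references and combined as vrbc / (vrbc + vp).  A whole-
    blood sample returns the capillary hematocrit exactly when the panel is
    internally consistent.
    """
    if panel.c_tc_rbc <= 0 or panel.c_i_plasma <= 0:
        raise ValueError("panel fraction concentrations must be > 0")
    vrbc_s = sample.a_tc / panel.c_tc_rbc
    vp_s = sample.a_i / panel.c_i_plasma
    total = vrbc_s + vp_s
    if total == 0:
        raise ValueError(f"sample {sample.tissue_id!r}: both volumes are zero")
    return vrbc_s / total


def arg_bhct(maps: VolumeMaps, blood_mask: np.ndarray) -> float:
    """Whole-blood hematocrit estimated from the autoradiograph itself:
    mean tHct over the diluted-blood spot (the dilution cancels in the
    RBC/plasma ratio, so the spot's true hematocrit equals bHct)."""
    if not blood_mask.any():
        raise ValueError("blood-spot mask is empty")
    spot = maps.thct_frac[blood_mask]
    spot = spot[np.isfinite(spot)]
    if spot.size == 0:
        raise ValueError("no defined tHct pixels in the blood spot")
    return float(spot.mean())


def percent_id_per_g(a_mbq_g: float | np.ndarray, dose_mbq: float):
    """Activity as percent of the injected dose per gram of tissue."""
    if dose_mbq <= 0:
        raise ValueError("dose must be > 0")
    return 100.0 * a_mbq_g / dose_mbq
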