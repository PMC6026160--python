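"""Synthetic phantom generation and forward rendering of the two exposures.

This is the in-silico stand-in for the animal experiment: 100 µm brain-like
cryosections carrying two decaying tracers, laid on a phosphor plate next
to a pure-¹²⁵I drop and a 1:50 diluted-blood spot, and imaged in two
exposure windows.  Ground truth (per-pixel vascular volume Vv, tissue
hematocrit tHct, and the derived RBC / plasma distribution volumes
Vrbc = tHct·Vv, Vp = (1−tHct)·Vv) is kept alongside the rendered images so
the quantification pipeline can be validated by exact recovery.

Physics of a rendered pixel: expected PSL in window w is

    sum over isotopes of  gain_iso · C_iso · mass_per_pixel · integrated_decay(iso, w)

with C_iso the local activity concentration at t = 0 (MBq/g), mass_per_pixel
the section mass under one pixel, and gain an isotope-specific plate
sensitivity in PSL per MBq·h.  Gains, section thickness and density are
deliberately unknown to the analysis pipeline — the internal reference
spots must cancel them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import (
    BloodPanelConfig,
    LayoutConfig,
    NoiseConfig,
    PhantomConfig,
    RegionSpec,
)
from .isotopes import I125, TC99M, ExposureWindow, IsotopeSpec, integrated_decay
from .rigid import warp_rigid

__all__ = [
    "PSLImage",
    "PhantomTruth",
    "BloodPanel",
    "SceneLayout",
    "make_phantom",
    "make_blood_panel",
    "make_layout",
    "expected_psl",
    "render_exposures",
    "apply_rigid_offset",
]


@dataclass
class PSLImage:
    """One exposure: photostimulated-luminescence values plus its window."""

    values: np.ndarray
    window: ExposureWindow

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PhantomTruth:
    """Region labels and per-pixel ground-truth maps (percent / fraction)."""

    labels: np.ndarray          # int, 0 = background
    vv_pct: np.ndarray          # vascular volume, mL/100g == %
    thct_frac: np.ndarray       # tissue hematocrit fraction
    vrbc_pct: np.ndarray        # = thct * vv
    vp_pct: np.ndarray          # = vv - vrbc (so vrbc + vp == vv exactly)
    pixel_size_um: float
    region_names: dict[int, str] = field(default_factory=dict)

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class BloodPanel:
    """Tracer concentrations of whole blood and its centrifuged fractions
    (MBq/g at t = 0) plus the capillary-tube whole-blood hematocrit."""

    c_tc_blood: float
    c_i_blood: float
    c_tc_rbc: float
    c_i_plasma: float
    bhct_capillary: float

    def __post_init__(self) -> None:
        for name in ("c_tc_blood", "c_i_blood", "c_tc_rbc", "c_i_plasma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.bhct_capillary < 1:
            raise ValueError("bhct_capillary must be in (0, 1)")


@dataclass
class SceneLayout:
    """Reference-spot masks, plate gains and section physics for one scene."""

    pure_i_mask: np.ndarray
    blood_mask: np.ndarray
    tissue_mask: np.ndarray
    background_mask: np.ndarray
    dilution: float
    pure_i_conc: float
    gain_tc: float
    gain_i: float
    thickness_um: float
    density_g_ml: float
    pixel_size_um: float
    bsa_leak_vp_pct: float = 0.0

    @property
    def mass_per_pixel_g(self) -> float:
        px_cm = self.pixel_size_um * 1e-4
        return self.thickness_um * 1e-4 * self.density_g_ml * px_cm * px_cm


def _region_mask(spec: RegionSpec, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r0, c0 = spec.center_rc
    if spec.shape == "disk":
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= spec.radius_px**2
    ar, ac = spec.axes_rc
    outer = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    if spec.shape == "ellipse":
        return outer
    ir, ic = spec.inner_axes_rc
    inner = ((rr - r0) / ir) ** 2 + ((cc - c0) / ic) ** 2 <= 1.0
    return outer & ~inner


def _smooth_field(shape: tuple[int, int], sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def make_phantom(config: PhantomConfig, seed: int | np.random.Generator = 0) -> PhantomTruth:
    """Build a ground-truth phantom from a region-list configuration.

    Base regions must be pairwise disjoint (overlap is a configuration
    error); overlay regions (vessel disks, lesions) are painted on top, and
    a vessel overlay without its own ``thct_frac`` inherits the hematocrit
    already present beneath it.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(config.shape_rc)
    labels = np.zeros(shape, dtype=np.int32)
    vv = np.zeros(shape, dtype=float)
    thct = np.zeros(shape, dtype=float)
    names: dict[int, str] = {}

    painted = np.zeros(shape, dtype=bool)
    base = [r for r in config.regions if not r.overlay]
    overlays = [r for r in config.regions if r.overlay]

    for spec in base:
        mask = _region_mask(spec, shape)
        if (mask & painted).any():
            raise ValueError(f"region {spec.name!r} overlaps an earlier base region")
        painted |= mask
        labels[mask] = spec.label
        vv[mask] = spec.vv_pct
        thct[mask] = spec.thct_frac
        names[spec.label] = spec.name

    het = config.heterogeneity
    tissue = labels > 0
    if het.vv_rel_sd > 0 and tissue.any():
        vv_field = _smooth_field(shape, het.sigma_px, rng)
        vv[tissue] *= np.clip(1.0 + het.vv_rel_sd * vv_field[tissue], 0.0, None)
    if het.thct_abs_sd > 0 and tissue.any():
        t_field = _smooth_field(shape, het.sigma_px, rng)
        thct[tissue] = np.clip(
            thct[tissue] + het.thct_abs_sd * t_field[tissue], 0.0, 0.95
        )

    for spec in overlays:
        mask = _region_mask(spec, shape)
        labels[mask] = spec.label
        vv[mask] = spec.vv_pct
        if spec.thct_frac is not None:
            thct[mask] = spec.thct_frac
        names[spec.label] = spec.name

    vrbc = thct * vv
    vp = vv - vrbc
    vv = vrbc + vp  # re-sum so vrbc + vp == vv holds bit-exactly
    return PhantomTruth(
        labels=labels, vv_pct=vv, thct_frac=thct, vrbc_pct=vrbc, vp_pct=vp,
        pixel_size_um=config.pixel_size_um, region_names=names,
    )


def make_blood_panel(config: BloodPanelConfig) -> BloodPanel:
    """Build a blood panel; fraction concentrations default to the
    whole-blood values split by the capillary hematocrit
    (c_tc_rbc = c_tc_blood / bHct, c_i_plasma = c_i_blood / (1 − bHct))."""
    bhct = config.bhct_capillary
    c_tc_rbc = (
        config.c_tc_rbc_mbq_g
        if config.c_tc_rbc_mbq_g is not None
        else config.c_tc_blood_mbq_g / bhct
    )
    c_i_plasma = (
        config.c_i_plasma_mbq_g
        if config.c_i_plasma_mbq_g is not None
        else config.c_i_blood_mbq_g / (1.0 - bhct)
    )
    return BloodPanel(
        c_tc_blood=config.c_tc_blood_mbq_g,
        c_i_blood=config.c_i_blood_mbq_g,
        c_tc_rbc=c_tc_rbc,
        c_i_plasma=c_i_plasma,
        bhct_capillary=bhct,
    )


def make_layout(config: LayoutConfig, truth: PhantomTruth) -> SceneLayout:
    """Place the reference spots around the tissue section.

    The pure-iodine drop, the diluted-blood spot and the tissue section
    must be mutually disjoint; everything else is background.
    """
    shape = truth.labels.shape
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)

    def disk(spec):
        r0, c0 = spec.center_rc
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= spec.radius_px**2

    pure = disk(config.pure_i_spot)
    blood = disk(config.blood_spot)
    tissue = truth.tissue_mask
    if (pure & blood).any() or (pure & tissue).any() or (blood & tissue).any():
        raise ValueError("layout masks overlap (pure spot / blood spot / tissue)")
    background = ~(pure | blood | tissue)
    return SceneLayout(
        pure_i_mask=pure,
        blood_mask=blood,
        tissue_mask=tissue,
        background_mask=background,
        dilution=config.dilution,
        pure_i_conc=config.pure_i_conc_mbq_g,
        gain_tc=config.gain_tc_psl_per_mbq_h,
        gain_i=config.gain_i_psl_per_mbq_h,
        thickness_um=config.thickness_um,
        density_g_ml=config.density_g_ml,
        pixel_size_um=truth.pixel_size_um,
        bsa_leak_vp_pct=config.bsa_leak_vp_pct,
    )


def _concentrations(truth: PhantomTruth, panel: BloodPanel,
                    layout: SceneLayout) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel t=0 activity concentrations (MBq/g) for each isotope."""
    c_tc = np.zeros(truth.labels.shape, dtype=float)
    c_i = np.zeros(truth.labels.shape, dtype=float)
    tissue = layout.tissue_mask
    vp = truth.vp_pct[tissue] + layout.bsa_leak_vp_pct
    c_tc[tissue] = truth.vrbc_pct[tissue] / 100.0 * panel.c_tc_rbc
    c_i[tissue] = vp / 100.0 * panel.c_i_plasma
    c_tc[layout.blood_mask] = panel.c_tc_blood / layout.dilution
    c_i[layout.blood_mask] = panel.c_i_blood / layout.dilution
    c_i[layout.pure_i_mask] = layout.pure_i_conc
    return c_tc, c_i


def expected_psl(truth: PhantomTruth, panel: BloodPanel, layout: SceneLayout,
                 window: ExposureWindow,
                 isotope: IsotopeSpec | None = None,
                 i125: IsotopeSpec = I125,
                 tc99m: IsotopeSpec = TC99M) -> np.ndarray:
    """Noise-free expected PSL for one window, optionally for one isotope
    alone (pass ``isotope=TC99M`` or ``isotope=I125``); no fog offset."""
    c_tc, c_i = _concentrations(truth, panel, layout)
    mass = layout.mass_per_pixel_g
    out = np.zeros_like(c_tc)
    if isotope is None or isotope.name == tc99m.name:
        out += layout.gain_tc * c_tc * mass * integrated_decay(tc99m, window)
    if isotope is None or isotope.name == i125.name:
        out += layout.gain_i * c_i * mass * integrated_decay(i125, window)
    return out


def render_exposures(truth: PhantomTruth, panel: BloodPanel, layout: SceneLayout,
                     windows: tuple[ExposureWindow, ExposureWindow],
                     noise: NoiseConfig | None = None,
                     seed: int | np.random.Generator = 0,
                     i125: IsotopeSpec = I125,
                     tc99m: IsotopeSpec = TC99M) -> tuple[PSLImage, PSLImage]:
    """Render the two exposures of one scene.

    With noise enabled, expected PSL is converted to photostimulated counts
    (PSL / ``psl_per_count``), Poisson-sampled, converted back, and Gaussian
    read noise plus the uniform fog offset are added.  With noise disabled
    only the deterministic fog offset is added.  Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise is None:
        noise = NoiseConfig(enabled=False)
    images = []
    for window in windows:
        expect = expected_psl(truth, panel, layout, window, i125=i125, tc99m=tc99m)
        if noise.enabled:
            q = noise.psl_per_count
            psl = rng.poisson(expect / q).astype(float) * q
            if noise.read_noise_psl > 0:
                psl += rng.normal(0.0, noise.read_noise_psl, size=psl.shape)
            psl += noise.background_offset_psl
        else:
            psl = expect + noise.background_offset_psl
        images.append(PSLImage(values=psl, window=window))
    return images[0], images[1]


def apply_rigid_offset(img: PSLImage, dx_px: float, dy_px: float,
                       theta_deg: float, order: int = 3) -> PSLImage:
    """Misalign an exposure by a small rigid transform (rotation about the
    image centre, then translation) — the perturbation that registration
    must undo.  Zero transform returns the input values bit-identically;
    integer pure translations are exact."""
    if not (abs(dx_px) <= 20 and abs(dy_px) <= 20):
        raise ValueError("|dx|, |dy| must be <= 20 px")
    if abs(theta_deg) > 5:
        raise ValueError("|theta| must be <= 5 degrees")
    moved = warp_rigid(img.values, dx_px, dy_px, theta_deg, order=order)
    return PSLImage(values=moved, window=img.window)
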