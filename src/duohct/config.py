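"""Run configuration: validated parameter models and built-in defaults.

A :class:`RunConfig` fully describes one simulated experiment — isotope
half-lives, the two exposure windows, phantom geometry with per-region
vascular volume and tissue hematocrit, the blood panel, the reference-spot
layout and plate gains, the noise model, and an optional rigid misalignment
between the two exposures.  Every pipeline run writes the resolved config
plus seed next to its outputs so a run directory is reproducible from its
own provenance.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IsotopeConfig(_Model):
    name: str
    half_life_h: float = Field(gt=0)


class WindowConfig(_Model):
    start_h: float = Field(ge=0)
    duration_h: float = Field(gt=0)


class IsotopesConfig(_Model):
    i125: IsotopeConfig = IsotopeConfig(name="I-125", half_life_h=59.4 * 24.0)
    tc99m: IsotopeConfig = IsotopeConfig(name="Tc-99m", half_life_h=6.0)


class ExposuresConfig(_Model):
    exp1: WindowConfig = WindowConfig(start_h=2.0, duration_h=16.0)
    exp2: WindowConfig = WindowConfig(start_h=170.0, duration_h=168.0)

    @model_validator(mode="after")
    def _no_overlap(self) -> "ExposuresConfig":
        e1_end = self.exp1.start_h + self.exp1.duration_h
        if self.exp2.start_h < e1_end:
            raise ValueError("exp2 must start after exp1 ends")
        return self


class RegionSpec(_Model):
    """One phantom region: a geometric primitive plus its ground truth.

    ``overlay`` regions (large-vessel disks, lesions) are painted on top of
    the disjoint base anatomy; a vessel overlay with ``thct_frac=None``
    inherits the hematocrit of the tissue it sits in, carrying only a
    vascular-volume hotspot.
    """

    name: str
    label: int = Field(ge=1)
    shape: Literal["ellipse", "ellipse_shell", "disk"]
    center_rc: tuple[float, float]
    axes_rc: Optional[tuple[float, float]] = None  # ellipse / shell outer
    inner_axes_rc: Optional[tuple[float, float]] = None  # shell only
    radius_px: Optional[float] = None  # disk only
    vv_pct: float = Field(ge=0)
    thct_frac: Optional[float] = None
    overlay: bool = False

    @model_validator(mode="after")
    def _geometry(self) -> "RegionSpec":
        if self.shape == "disk" and self.radius_px is None:
            raise ValueError(f"region {self.name!r}: disk needs radius_px")
        if self.shape in ("ellipse", "ellipse_shell") and self.axes_rc is None:
            raise ValueError(f"region {self.name!r}: ellipse needs axes_rc")
        if self.shape == "ellipse_shell" and self.inner_axes_rc is None:
            raise ValueError(f"region {self.name!r}: shell needs inner_axes_rc")
        if self.thct_frac is not None and not 0 <= self.thct_frac < 1:
            raise ValueError(f"region {self.name!r}: thct_frac must be in [0, 1)")
        if self.thct_frac is None and not self.overlay:
            raise ValueError(f"region {self.name!r}: base regions need thct_frac")
        return self


class HeterogeneityConfig(_Model):
    """Smooth within-region biological texture on the truth maps.

    ``vv_rel_sd`` scales vascular volume multiplicatively; ``thct_abs_sd``
    perturbs hematocrit additively.  Both fields are Gaussian random fields
    with correlation length ``sigma_px``.  Set SDs to 0 for piecewise-
    constant truth.
    """

    vv_rel_sd: float = Field(default=0.10, ge=0)
    thct_abs_sd: float = Field(default=0.005, ge=0)
    sigma_px: float = Field(default=4.0, gt=0)


class PhantomConfig(_Model):
    shape_rc: tuple[int, int] = (200, 300)
    pixel_size_um: float = Field(default=50.0, gt=0)
    regions: list[RegionSpec] = Field(default_factory=list)
    heterogeneity: HeterogeneityConfig = HeterogeneityConfig()


class DiskSpec(_Model):
    center_rc: tuple[float, float]
    radius_px: float = Field(gt=0)


class BloodPanelConfig(_Model):
    """Whole-blood tracer concentrations at t = 0 plus capillary hematocrit.

    Fraction concentrations (RBC for technetium, plasma for iodine) may be
    given explicitly — e.g. when emulating centrifuged-fraction counting —
    otherwise they are derived from whole blood and the capillary bHct.
    """

    c_tc_blood_mbq_g: float = Field(default=2.26, ge=0)
    c_i_blood_mbq_g: float = Field(default=0.195, ge=0)
    bhct_capillary: float = Field(default=0.401, gt=0, lt=1)
    c_tc_rbc_mbq_g: Optional[float] = Field(default=None, ge=0)
    c_i_plasma_mbq_g: Optional[float] = Field(default=None, ge=0)


class NoiseConfig(_Model):
    """Quantum-limited plate noise: Poisson on photostimulated counts
    (PSL / ``psl_per_count``), Gaussian read noise, uniform fog offset."""

    enabled: bool = True
    psl_per_count: float = Field(default=0.5, gt=0)
    read_noise_psl: float = Field(default=2.0, ge=0)
    background_offset_psl: float = Field(default=10.0, ge=0)


class LayoutConfig(_Model):
    """Reference-spot geometry, per-isotope plate gains and section physics."""

    pure_i_spot: DiskSpec = DiskSpec(center_rc=(40.0, 245.0), radius_px=12.0)
    blood_spot: DiskSpec = DiskSpec(center_rc=(150.0, 245.0), radius_px=14.0)
    dilution: float = Field(default=50.0, gt=0)
    pure_i_conc_mbq_g: float = Field(default=1.0, gt=0)
    gain_tc_psl_per_mbq_h: float = Field(default=2.0e9, gt=0)
    gain_i_psl_per_mbq_h: float = Field(default=1.5e9, gt=0)
    thickness_um: float = Field(default=100.0, gt=0)
    density_g_ml: float = Field(default=1.04, gt=0)
    #: optional fractional albumin leakage: extra plasma-volume percent added
    #: to every tissue pixel at render time (truth maps untouched) to
    #: demonstrate the hematocrit underestimation that tracer extravasation
    #: would cause.
    bsa_leak_vp_pct: float = Field(default=0.0, ge=0)


class MisalignmentConfig(_Model):
    dx_px: float = Field(default=0.0, ge=-20, le=20)
    dy_px: float = Field(default=0.0, ge=-20, le=20)
    theta_deg: float = Field(default=0.0, ge=-5, le=5)


class RunConfig(_Model):
    schema_version: int = SCHEMA_VERSION
    isotopes: IsotopesConfig = IsotopesConfig()
    exposures: ExposuresConfig = ExposuresConfig()
    phantom: PhantomConfig = PhantomConfig()
    panel: BloodPanelConfig = BloodPanelConfig()
    layout: LayoutConfig = LayoutConfig()
    noise: NoiseConfig = NoiseConfig()
    misalignment: MisalignmentConfig = MisalignmentConfig()
    vv_min_pct: float = Field(default=0.5, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _version(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unknown schema_version {self.schema_version}; "
                f"this package reads version {SCHEMA_VERSION}"
            )
        return self


def control_brain_regions() -> list[RegionSpec]:
    """Default healthy-brain anatomy: cortical shell, white-matter shell,
    striatal core, plus three large-vessel disks sharing the local tHct."""
    return [
        RegionSpec(
            name="cortex", label=1, shape="ellipse_shell",
            center_rc=(100.0, 95.0), axes_rc=(75.0, 70.0),
            inner_axes_rc=(54.0, 50.0), vv_pct=3.5, thct_frac=0.296,
        ),
        RegionSpec(
            name="white_matter", label=2, shape="ellipse_shell",
            center_rc=(100.0, 95.0), axes_rc=(54.0, 50.0),
            inner_axes_rc=(38.0, 35.0), vv_pct=2.0, thct_frac=0.280,
        ),
        RegionSpec(
            name="striatum", label=3, shape="ellipse",
            center_rc=(100.0, 95.0), axes_rc=(38.0, 35.0),
            vv_pct=3.0, thct_frac=0.288,
        ),
        RegionSpec(
            name="vessel_1", label=21, shape="disk",
            center_rc=(60.0, 95.0), radius_px=2.5, vv_pct=30.0,
            thct_frac=None, overlay=True,
        ),
        RegionSpec(
            name="vessel_2", label=22, shape="disk",
            center_rc=(100.0, 60.0), radius_px=2.0, vv_pct=30.0,
            thct_frac=None, overlay=True,
        ),
        RegionSpec(
            name="vessel_3", label=23, shape="disk",
            center_rc=(118.0, 108.0), radius_px=2.0, vv_pct=30.0,
            thct_frac=None, overlay=True,
        ),
    ]


def lesion_region(vv_pct: float, thct_frac: float, label: int = 10) -> RegionSpec:
    """A focal lesion disk inside the striatum (stroke or glioma core)."""
    return RegionSpec(
        name="lesion", label=label, shape="disk",
        center_rc=(100.0, 110.0), radius_px=16.0,
        vv_pct=vv_pct, thct_frac=thct_frac, overlay=True,
    )


def default_config(seed: int = 0) -> RunConfig:
    """The default control-brain run configuration."""
    cfg = RunConfig(seed=seed)
    cfg.phantom.regions = control_brain_regions()
    return cfg
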