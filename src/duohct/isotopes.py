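"""Radioactive decay law and exposure-window signal integration.

The dual-isotope protocol images the same tissue sections twice: a first
exposure shortly after euthanasia captures both tracers (short-lived
:data:`TC99M` on red blood cells plus long-lived :data:`I125` on albumin),
and a second exposure a week later captures essentially the iodine tracer
alone.  Everything downstream reduces to two numbers per isotope and
window: the instantaneous decay factor and the decay integrated over the
exposure window, which is what a phosphor plate accumulates.

All times are hours after the reference time t = 0 (euthanasia / tissue
freezing); all activity concentrations elsewhere in the package are stated
at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IsotopeSpec",
    "ExposureWindow",
    "I125",
    "TC99M",
    "DEFAULT_EXP1",
    "DEFAULT_EXP2",
    "decay_factor",
    "integrated_decay",
    "window_ratio",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class IsotopeSpec:
    """A radioisotope identified by its half-life.

    Parameters
    ----------
    name
        Human-readable label, e.g. ``"I-125"``.
    half_life_h
        Physical half-life in hours; must be positive.
    """

    name: str
    half_life_h: float

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be > 0, got {self.half_life_h}")


#: Iodine-125 (59.4 day half-life), the albumin / plasma tracer.
I125 = IsotopeSpec("I-125", 59.4 * 24.0)

#: Technetium-99m (6 hour half-life), the red-blood-cell tracer.
TC99M = IsotopeSpec("Tc-99m", 6.0)


@dataclass(frozen=True)
class ExposureWindow:
    """A phosphor-plate exposure window, in hours after t = 0.

    ``start_h`` must be non-negative and ``duration_h`` strictly positive.
    """

    start_h: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.start_h < 0:
            raise ValueError(f"start_h must be >= 0, got {self.start_h}")
        if not self.duration_h > 0:
            raise ValueError(f"duration_h must be > 0, got {self.duration_h}")

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h

    def overlaps(self, other: "ExposureWindow") -> bool:
        return self.start_h < other.end_h and other.start_h < self.end_h


#: Default first ("overnight") exposure: 2 h after euthanasia, 16 h long.
DEFAULT_EXP1 = ExposureWindow(start_h=2.0, duration_h=16.0)

#: Default second exposure: one week later, one week long.
DEFAULT_EXP2 = ExposureWindow(start_h=170.0, duration_h=168.0)


def decay_factor(iso: IsotopeSpec, dt_h: float) -> float:
    """Fraction of activity remaining after ``dt_h`` hours.

    Returns ``2 ** (-dt_h / half_life_h)``; strictly decreasing in ``dt_h``.

    Raises
    ------
    ValueError
        If ``dt_h`` is negative.
    """
    if dt_h < 0:
        raise ValueError(f"dt_h must be >= 0, got {dt_h}")
    return 2.0 ** (-dt_h / iso.half_life_h)


def integrated_decay(iso: IsotopeSpec, window: ExposureWindow) -> float:
    """Decay factor integrated over an exposure window, in effective hours.

    This is ``∫ 2**(-t/T½) dt`` over ``[start, start + duration]``:
    the number of hours of t = 0 activity that deposit the same number of
    decays as the window actually does.  A plate exposed through ``window``
    accumulates a signal proportional to ``activity_at_t0 *
    integrated_decay(iso, window)``.

    For a half-life much longer than the window this tends to the plain
    duration.  The implementation uses ``expm1`` so that limit is reached
    without catastrophic cancellation.
    """
    t_half = iso.half_life_h
    # (T/ln2) * 2^{-s/T} * (1 - 2^{-d/T}), with 1 - 2^{-x} = -expm1(-x ln2)
    lead = t_half / _LN2 * 2.0 ** (-window.start_h / t_half)
    return lead * -math.expm1(-window.duration_h * _LN2 / t_half)


def window_ratio(iso: IsotopeSpec, w1: ExposureWindow, w2: ExposureWindow) -> float:
    """Ratio of integrated decay in ``w2`` to that in ``w1``.

    For the long-lived iodine tracer this is the theoretical value of the
    empirical inter-exposure intensity correction measured on the pure-¹²⁵I
    reference spot; for the short-lived technetium tracer with default
    timing it is vanishingly small, which is what justifies treating the
    second exposure as iodine-only.
    """
    return integrated_decay(iso, w2) / integrated_decay(iso, w1)
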