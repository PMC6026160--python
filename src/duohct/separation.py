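"""Recovering the single-isotope images from the two exposures.

The first exposure (Exp1) holds both tracers; the second (Exp2), taken a
week later, holds only the long-lived ¹²⁵I signal because the 6-hour ⁹⁹ᵐTc
has decayed away.  Separation follows the experimental recipe in order:

1. subtract the plate fog level (median over the background mask),
2. scale Exp2 onto Exp1's intensity scale using the pure-¹²⁵I reference
   spot (the empirical counterpart of the theoretical window ratio),
3. rigidly co-register Exp2 onto Exp1,
4. subtract: ``psl_i = resample(Exp2)/f`` and ``psl_tc = Exp1 − psl_i``,
   clamping negative pixels to zero and reporting the clamped fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .phantom import PSLImage
from .rigid import invert_params, warp_rigid

__all__ = [
    "SeparationResult",
    "RegistrationError",
    "CalibrationError",
    "subtract_background",
    "estimate_i125_correction",
    "register_exposures",
    "separate",
]


class CalibrationError(ValueError):
    """Reference-spot signal unusable (empty, zero or negative mean)."""


class RegistrationError(RuntimeError):
    """Co-registration failed; carries diagnostic details."""


@dataclass
class SeparationResult:
    """Single-isotope PSL images on Exp1's intensity scale.

    ``f_correction`` is the Exp2→Exp1 ¹²⁵I intensity factor estimated from
    the pure-iodine spot; ``transform`` the rigid (dx, dy, theta) offset of
    Exp2 relative to Exp1; ``negatives_clamped_fraction`` the fraction of
    evaluated pixels that were negative after subtraction and clamped.
    """

    f_correction: float
    transform: tuple[float, float, float]
    psl_tc: PSLImage
    psl_i: PSLImage
    negatives_clamped_fraction: float


def _as_array(img) -> np.ndarray:
    return img.values if isinstance(img, PSLImage) else np.asarray(img, dtype=float)


def subtract_background(img: PSLImage, background_mask: np.ndarray) -> tuple[PSLImage, float]:
    """Subtract the plate fog level, estimated as the median PSL over the
    background mask. Returns the corrected image and the level removed."""
    if not background_mask.any():
        raise CalibrationError("background mask is empty")
    level = float(np.median(img.values[background_mask]))
    return PSLImage(values=img.values - level, window=img.window), level


def estimate_i125_correction(exp1, exp2, pure_i_mask: np.ndarray,
                             min_pixels: int = 25) -> float:
    """Empirical Exp2→Exp1 intensity factor from the pure-¹²⁵I spot.

    Both images must already be background-subtracted.  Returns
    ``mean(Exp2[spot]) / mean(Exp1[spot])`` — scale-invariant, and equal to
    the theoretical iodine window ratio in the absence of noise.
    """
    a1, a2 = _as_array(exp1), _as_array(exp2)
    n = int(pure_i_mask.sum())
    if n < min_pixels:
        raise CalibrationError(f"pure-I-125 mask has {n} px, needs >= {min_pixels}")
    m1 = float(a1[pure_i_mask].mean())
    m2 = float(a2[pure_i_mask].mean())
    if m1 <= 0:
        raise CalibrationError(f"pure-I-125 spot mean in Exp1 is {m1:.3g} (<= 0)")
    return m2 / m1


def _shift_and_error(ref: np.ndarray, mov: np.ndarray,
                     upsample: int) -> tuple[np.ndarray, float]:
    shift, error, _ = phase_cross_correlation(
        ref, mov, upsample_factor=upsample, normalization=None
    )
    return shift, float(error)


def register_exposures(exp1, exp2, search_rotation: bool = True,
                       max_theta_deg: float = 5.0,
                       max_error: float = 0.95) -> tuple[float, float, float]:
    """Estimate the rigid offset (dx, dy, theta) of Exp2 relative to Exp1.

    The returned parameters are those of the forward offset — applying them
    to an aligned image reproduces Exp2 — so a simulated misalignment is
    recovered directly.  Translation comes from spectral cross-correlation
    with upsampled-DFT sub-pixel refinement; rotation from a coarse-to-fine
    grid search (0.25° then 0.05° steps) over ±``max_theta_deg``.

    Raises
    ------
    RegistrationError
        If the best correlation is too poor to trust
        (normalized RMS error above ``max_error``).
    """
    # Log-compress intensities so the very bright reference spots do not
    # dominate the correlation over the (much fainter) tissue structure.
    ref = np.log1p(np.clip(_as_array(exp1), 0.0, None))
    mov = np.log1p(np.clip(_as_array(exp2), 0.0, None))
    ref = ref - ref.mean()
    mov = mov - mov.mean()

    def evaluate(theta: float, upsample: int, order: int):
        unrot = warp_rigid(mov, 0.0, 0.0, -theta, order=order) if theta else mov
        shift, err = _shift_and_error(ref, unrot, upsample)
        return shift, err

    if search_rotation:
        coarse = np.arange(-max_theta_deg, max_theta_deg + 1e-9, 0.25)
        errs = [evaluate(t, 10, 1)[1] for t in coarse]
        t0 = float(coarse[int(np.argmin(errs))])
        fine = t0 + 0.05 * np.arange(-5, 6)  # exact 0.0 stays exact
        errs = [evaluate(t, 10, 1)[1] for t in fine]
        theta = float(fine[int(np.argmin(errs))])
    else:
        theta = 0.0

    shift, err = evaluate(theta, 100, 3)
    if err > max_error:
        raise RegistrationError(
            f"registration failed: normalized error {err:.3f} > {max_error} "
            f"(theta={theta:.2f} deg, shift={tuple(shift)})"
        )
    # phase_cross_correlation returns the (row, col) shift that registers the
    # moving image; the content offset is its negation.
    t_row, t_col = -shift[0], -shift[1]
    # Un-rotating first conjugates the translation: t = R(-theta) d.
    th = np.deg2rad(theta)
    dx = np.cos(th) * t_col - np.sin(th) * t_row
    dy = np.sin(th) * t_col + np.cos(th) * t_row
    return float(dx), float(dy), theta


def separate(exp1: PSLImage, exp2: PSLImage, f: float,
             transform: tuple[float, float, float] = (0.0, 0.0, 0.0),
             evaluate_mask: np.ndarray | None = None,
             order: int = 3) -> SeparationResult:
    """Split background-subtracted exposures into single-isotope images.

    Exp2 is resampled into Exp1's frame by the inverse of ``transform``
    (an exact identity when the transform is zero), divided by ``f`` to
    reach Exp1's intensity scale (giving the ¹²⁵I image), and subtracted
    from Exp1 (giving the ⁹⁹ᵐTc image).  Negative ⁹⁹ᵐTc pixels are clamped
    to zero; the clamped fraction is computed over ``evaluate_mask``
    (default: the whole frame).
    """
    if f <= 0:
        raise ValueError(f"correction factor must be > 0, got {f}")
    dx, dy, theta = transform
    if dx == 0.0 and dy == 0.0 and theta == 0.0:
        aligned = exp2.values.copy()
    else:
        aligned = warp_rigid(
            exp2.values, dx, dy, theta, order=order,
            matrix=invert_params(dx, dy, theta, exp2.values.shape),
        )
    psl_i = aligned / f
    raw_tc = exp1.values - psl_i
    negatives = raw_tc < 0
    if evaluate_mask is not None:
        clamped = float(negatives[evaluate_mask].mean()) if evaluate_mask.any() else 0.0
    else:
        clamped = float(negatives.mean())
    psl_tc = np.where(negatives, 0.0, raw_tc)
    return SeparationResult(
        f_correction=float(f),
        transform=(float(dx), float(dy), float(theta)),
        psl_tc=PSLImage(values=psl_tc, window=exp1.window),
        psl_i=PSLImage(values=psl_i, window=exp1.window),
        negatives_clamped_fraction=clamped,
    )
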