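"""ROI summaries, agreement statistics and hematocrit histograms.

Descriptive statistics over labelled regions of the computed maps, the
Pearson/least-squares agreement fit used to compare hematocrit estimators,
and the small percent-change / ratio arithmetic used for between-condition
comparisons.  Conventions: sample SD (n−1), masked pixels are NaN and are
excluded, results quoted as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ROISummary",
    "AgreementFit",
    "roi_summary",
    "percent_change",
    "hct_ratio",
    "pooled_mean",
    "agreement_fit",
    "thct_histogram",
]


@dataclass(frozen=True)
class ROISummary:
    region_id: int
    mean: float
    sd: float
    n_pixels: int
    fraction_masked: float


@dataclass(frozen=True)
class AgreementFit:
    r: float
    r2: float
    slope: float
    intercept: float
    n: int


def roi_summary(map_values: np.ndarray, mask: np.ndarray,
                region_id: int = 0) -> ROISummary:
    """Mean / sample-SD / count of a map over one region.

    NaN pixels inside the region are treated as masked-out and excluded;
    a region with no defined pixel is an error.
    """
    if not mask.any():
        raise ValueError(f"region {region_id}: empty mask")
    vals = map_values[mask]
    defined = vals[np.isfinite(vals)]
    if defined.size == 0:
        raise ValueError(f"region {region_id}: all pixels masked")
    sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    return ROISummary(
        region_id=region_id,
        mean=float(defined.mean()),
        sd=sd,
        n_pixels=int(defined.size),
        fraction_masked=float(1.0 - defined.size / vals.size),
    )


def percent_change(x: float, ref: float) -> float:
    """Relative change of ``x`` from ``ref`` in percent: 100·(x−ref)/ref."""
    if ref == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (x - ref) / ref


def hct_ratio(organ_hct: float, blood_hct: float) -> float:
    """Ratio of an organ's hematocrit to the whole-blood hematocrit."""
    if blood_hct <= 0:
        raise ValueError("blood hematocrit must be > 0")
    return organ_hct / blood_hct


def pooled_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of per-group means (e.g. across lesion models)."""
    if len(values) == 0:
        raise ValueError("empty value list")
    return float(np.mean(values))


def agreement_fit(xs: Sequence[float], ys: Sequence[float]) -> AgreementFit:
    """Pearson correlation and ordinary-least-squares line of ys on xs.

    This is the scatter-plot agreement analysis used to compare hematocrit
    estimators (e.g. autoradiographic vs capillary bHct across animals).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in xs")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    return AgreementFit(r=r, r2=r * r, slope=float(fit.slope),
                        intercept=float(fit.intercept), n=int(x.size))


def thct_histogram(thct_map: np.ndarray, mask: np.ndarray,
                   bin_width_pct: float = 1.0,
                   range_pct: tuple[float, float] = (0.0, 60.0),
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of tHct (in hematocrit percent) over a region.

    Returns ``(bin_edges_pct, frequencies)`` with frequencies summing to 1
    over the defined (non-NaN) pixels of the region.
    """
    if not mask.any():
        raise ValueError("empty mask")
    if bin_width_pct <= 0:
        raise ValueError("bin_width_pct must be > 0")
    vals = thct_map[mask]
    vals = vals[np.isfinite(vals)] * 100.0
    if vals.size == 0:
        raise ValueError("no defined tHct pixels in mask")
    lo, hi = range_pct
    edges = np.arange(lo, hi + bin_width_pct / 2.0, bin_width_pct)
    counts, edges = np.histogram(np.clip(vals, lo, edges[-1] - 1e-12), bins=edges)
    return edges, counts / vals.size
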