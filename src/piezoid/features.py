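"""Peak-shape count and sharpness of a normalized cardiac spectrum.

The two discriminants are computed at two *power standards* derived from the
global spectral maximum P*:

* a *peak shape* at the fraction-f standard is a strict local maximum of the
  spectrum whose power exceeds theta = f * P*;
* its *region* is the maximal interval around the peak on which the linearly
  interpolated spectrum stays >= theta (bounded by the interpolated
  threshold crossings or the band edge);
* its *excess area* is the area between the spectrum and the horizontal
  threshold line over that region — the convex-upward cap the standard
  cuts off.

The peak-shape number is the average of the counts at the 1/2 and 1/4
standards.  Sharpness is that number divided by the summed excess areas at
both standards: tall narrow harmonics give small caps and hence a large
sharpness, broad humps the opposite.  Regions that coincide (several local
maxima inside one above-threshold excursion) contribute their area once,
while each qualifying maximum still counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum

__all__ = ["Peak", "PeakSet", "PeakFeatures", "find_peaks", "extract_features"]

HALF = 0.5
QUARTER = 0.25


@dataclass(frozen=True)
class Peak:
    """One qualifying local maximum and its above-threshold region."""

    peak_freq: float
    region_lo: float
    region_hi: float
    excess_area: float


@dataclass(frozen=True)
class PeakSet:
    """All peak shapes of a spectrum at one power standard."""

    threshold_fraction: float
    threshold: float
    peaks: tuple[Peak, ...]

    @property
    def count(self) -> int:
        return len(self.peaks)

    @property
    def total_area(self) -> float:
        """Summed excess area, coinciding regions counted once."""
        seen: set[tuple[float, float]] = set()
        total = 0.0
        for p in self.peaks:
            key = (p.region_lo, p.region_hi)
            if key not in seen:
                seen.add(key)
                total += p.excess_area
        return total


@dataclass(frozen=True)
class PeakFeatures:
    """The 2-D spectral descriptor: peak-shape number and sharpness."""

    n_half: int
    n_quarter: int
    area_half: float
    area_quarter: float

    @property
    def n_peaks(self) -> float:
        return (self.n_half + self.n_quarter) / 2.0

    @property
    def sharpness(self) -> float:
        return self.n_peaks / (self.area_half + self.area_quarter)


def _peak_indices(power: np.ndarray, theta: float) -> list[int]:
    """Strict local maxima above theta; plateaus credited to their leftmost
    bin; one-sided comparison at the band edges."""
    n = power.size
    out = []
    for k in range(n):
        if power[k] <= theta:
            continue
        left_ok = k == 0 or power[k] > power[k - 1]
        right_ok = k == n - 1 or power[k] >= power[k + 1]
        if left_ok and right_ok:
            out.append(k)
    return out


def _region(freqs: np.ndarray, power: np.ndarray, k: int, theta: float) -> tuple[int, int, float, float]:
    """Walk outward from peak bin ``k`` to the first interpolated crossing of
    theta (or the band edge).  Returns (i, j, x_lo, x_hi): the inclusive bin
    span of the region and its interpolated frequency bounds."""
    n = power.size
    i = k
    while i > 0 and power[i - 1] >= theta:
        i -= 1
    if i == 0:
        x_lo = freqs[0]
    else:
        # power[i-1] < theta <= power[i]
        frac = (theta - power[i - 1]) / (power[i] - power[i - 1])
        x_lo = freqs[i - 1] + frac * (freqs[i] - freqs[i - 1])
    j = k
    while j < n - 1 and power[j + 1] >= theta:
        j += 1
    if j == n - 1:
        x_hi = freqs[n - 1]
    else:
        frac = (power[j] - theta) / (power[j] - power[j + 1])
        x_hi = freqs[j] + frac * (freqs[j + 1] - freqs[j])
    return i, j, x_lo, x_hi


def _excess_area(
    freqs: np.ndarray, power: np.ndarray, i: int, j: int, x_lo: float, x_hi: float, theta: float
) -> float:
    """Trapezoid integral of (power - theta) over the region, including the
    partial boundary segments up to the interpolated crossings."""
    xs = np.concatenate(([x_lo], freqs[i : j + 1], [x_hi]))
    ys = np.concatenate(([0.0], power[i : j + 1] - theta, [0.0]))
    # boundary bins sit exactly at theta when the region reaches the band edge
    if x_lo == freqs[i]:
        ys[0] = power[i] - theta
    if x_hi == freqs[j]:
        ys[-1] = power[j] - theta
    return float(np.trapezoid(ys, xs))


def find_peaks(spec: Spectrum, fraction: float) -> PeakSet:
    """Locate peak shapes at the given power standard (1/2 or 1/4).

    The threshold is ``fraction`` times the global maximum power.  Every
    strict local maximum above the threshold is a peak; its region and
    excess area follow the interpolated-crossing construction described in
    the module docstring.
    """
    power = spec.power
    if power.size < 3:
        raise ValueError("spectrum too short for peak analysis (need >= 3 bins)")
    pmax = float(np.max(power))
    if pmax <= 0:
        raise ValueError("spectrum has zero maximum power")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction!r}")
    theta = fraction * pmax
    peaks = []
    for k in _peak_indices(power, theta):
        i, j, x_lo, x_hi = _region(spec.freqs, power, k, theta)
        area = _excess_area(spec.freqs, power, i, j, x_lo, x_hi, theta)
        peaks.append(Peak(float(spec.freqs[k]), float(x_lo), float(x_hi), area))
    return PeakSet(fraction, theta, tuple(peaks))


def extract_features(spec: Spectrum) -> PeakFeatures:
    """Compute the peak-shape number and sharpness of a spectrum.

    ``n_peaks`` is the mean of the counts at the 1/2 and 1/4 standards;
    ``sharpness`` is ``n_peaks`` divided by the total excess area at both
    standards (merged regions counted once per standard).
    """
    half = find_peaks(spec, HALF)
    quarter = find_peaks(spec, QUARTER)
    total_area = half.total_area + quarter.total_area
    if total_area <= 0:
        raise ValueError("degenerate spectrum: zero excess area at both standards")
    return PeakFeatures(
        n_half=half.count,
        n_quarter=quarter.count,
        area_half=half.total_area,
        area_quarter=quarter.total_area,
    )
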