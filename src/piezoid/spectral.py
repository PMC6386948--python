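"""Power-spectrum estimation and unit-integral normalization.

The analysis unit is one 10-s segment, so the spectrum is a single
Hann-windowed periodogram of the full segment (df = 1/duration = 0.1 Hz for
the default 10 s) restricted to the 0.6-15 Hz cardiac band.  Welch averaging
is deliberately not used: splitting 10 s into sub-blocks would destroy the
0.1 Hz resolution the heartbeat harmonic peaks require.

The spectrum is normalized so the rectangle-rule integral over the retained
band equals 1; downstream peak features are therefore independent of sensor
gain and of overall signal amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import BAND_HI_HZ, BAND_LO_HZ, Segment

__all__ = [
    "Spectrum",
    "NormalizedSpectrum",
    "power_spectrum",
    "smooth",
    "normalize",
    "write_spectrum",
    "SMOOTH_WIDTH_BINS",
]

#: Default moving-average smoothing width, bins (odd; 1 disables).
SMOOTH_WIDTH_BINS = 3


@dataclass(frozen=True)
class Spectrum:
    """Discrete one-sided power spectrum on uniformly spaced bin centres."""

    freqs: np.ndarray
    power: np.ndarray
    df: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.ndim != 1 or freqs.size != power.size or freqs.size < 1:
            raise ValueError("freqs and power must be matching 1-D arrays")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        if not self.df > 0:
            raise ValueError("df must be positive")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    def __len__(self) -> int:
        return self.freqs.size

    @property
    def integral(self) -> float:
        """Rectangle-rule integral of the power density over the band."""
        return float(np.sum(self.power) * self.df)


@dataclass(frozen=True)
class NormalizedSpectrum(Spectrum):
    """A spectrum whose rectangle-rule integral over the band equals 1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if abs(self.integral - 1.0) > 1e-9:
            raise ValueError(
                f"normalized spectrum must integrate to 1, got {self.integral!r}"
            )


def power_spectrum(
    seg: Segment, lo: float = BAND_LO_HZ, hi: float = BAND_HI_HZ
) -> Spectrum:
    """Hann-windowed periodogram of a full segment, restricted to [lo, hi] Hz.

    Power is a one-sided density (units^2/Hz) on bins spaced df = 1/duration;
    bins with centres outside the band are discarded.
    """
    if seg.duration < 10.0 - 1e-9:
        raise ValueError(
            f"segment of {seg.duration:g} s is too short: need >= 10 s for "
            "df <= 0.1 Hz frequency resolution"
        )
    if seg.rate <= 2 * hi:
        raise ValueError(f"rate {seg.rate:g} Hz cannot resolve {hi:g} Hz")
    if np.all(seg.samples == 0.0):
        warnings.warn("all-zero segment: spectrum has no power", stacklevel=2)
    freqs, pxx = sps.periodogram(
        seg.samples,
        fs=seg.rate,
        window="hann",
        detrend="constant",
        scaling="density",
    )
    df = seg.rate / len(seg)
    keep = (freqs >= lo - 1e-9 * max(lo, 1.0)) & (freqs <= hi + 1e-9 * hi)
    return Spectrum(freqs[keep], pxx[keep], df)


def smooth(spec: Spectrum, width_bins: int = SMOOTH_WIDTH_BINS) -> Spectrum:
    """Conservatively smooth a spectrum with a centred ``width_bins`` window.

    Each bin's power is spread equally over the bins of its centred window,
    clipped at the band edges (so edge windows shrink).  For interior bins
    this coincides with the ordinary moving average; unlike the plain
    moving average it conserves the integral exactly, which keeps
    normalization and smoothing commutative.
    """
    if width_bins < 1 or width_bins % 2 == 0:
        raise ValueError(f"smoothing width must be a positive odd integer, got {width_bins}")
    if width_bins == 1:
        return Spectrum(spec.freqs.copy(), spec.power.copy(), spec.df)
    n = len(spec)
    half = width_bins // 2
    idx = np.arange(n)
    # clipped window size per source bin
    m = np.minimum(idx + half, n - 1) - np.maximum(idx - half, 0) + 1
    share = spec.power / m
    out = np.zeros(n)
    for off in range(-half, half + 1):
        lo_dst = max(off, 0)
        hi_dst = n + min(off, 0)
        out[lo_dst:hi_dst] += share[lo_dst - off : hi_dst - off]
    return Spectrum(spec.freqs.copy(), out, spec.df)


def write_spectrum(spec: Spectrum, path) -> None:
    """Export a spectrum as CSV with columns ``freq_hz,power_density``."""
    lines = ["freq_hz,power_density"]
    lines += [f"{f:.17g},{p:.17g}" for f, p in zip(spec.freqs, spec.power)]
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


def normalize(spec: Spectrum) -> NormalizedSpectrum:
    """Scale power so the rectangle-rule integral over the band equals 1."""
    total = spec.integral
    if total <= 0:
        raise ValueError("no signal power in band: cannot normalize")
    return NormalizedSpectrum(spec.freqs.copy(), spec.power / total, spec.df)
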