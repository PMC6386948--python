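"""Stable-segment selection and cardiac-band filtering.

A sheet-sensor recording mixes the cardiac vibration with respiration
(< 0.6 Hz), broadband noise and large body-movement transients.  Analysis
uses a single 10-s stretch that is free of movement artifacts, band-limited
to the 0.6-15 Hz cardiac vibration band.

Segment selection is automatic: a candidate window's *stability score* is the
ratio of the maximum to the median RMS over its non-overlapping 1-s
subwindows.  A stationary biosignal scores near 1; an amplitude transient
inflates the maximum and pushes the score up, so the minimum-score window is
the most artifact-free stretch of the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_io import RawSignal

__all__ = [
    "Segment",
    "StabilityReport",
    "select_stable_segment",
    "bandpass",
    "BAND_LO_HZ",
    "BAND_HI_HZ",
]

#: Cardiac vibration band edges, Hz.
BAND_LO_HZ = 0.6
BAND_HI_HZ = 15.0
#: Width of the raised-cosine filter transition, Hz.
TRANSITION_HZ = 0.1
#: Default analysis-segment length, s.
SEGMENT_DURATION_S = 10.0
#: Default acceptance threshold on the stability score.
STABILITY_THRESHOLD = 3.0


@dataclass(frozen=True)
class Segment:
    """A contiguous slice of a recording, with its position in the parent."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    duration: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("segment must be a non-empty 1-D sequence")
        if self.rate <= 0:
            raise ValueError("segment rate must be positive")
        object.__setattr__(self, "samples", samples)
        dur = samples.size / self.rate if self.duration is None else float(self.duration)
        if abs(dur * self.rate - samples.size) > 1.0 + 1e-9:
            raise ValueError("duration inconsistent with sample count")
        object.__setattr__(self, "duration", dur)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of stable-segment selection.

    ``stability_score`` is max/median subwindow RMS (>= 1 up to degenerate
    cases); ``accepted`` is False when even the best window exceeds the
    configured threshold, i.e. the recording has no artifact-free stretch.
    """

    window_start: float
    stability_score: float
    accepted: bool


def _subwindow_rms(x: np.ndarray, sub: int) -> np.ndarray:
    nblocks = x.size // sub
    blocks = x[: nblocks * sub].reshape(nblocks, sub)
    return np.sqrt(np.mean(blocks**2, axis=1))


def select_stable_segment(
    raw: RawSignal,
    duration: float = SEGMENT_DURATION_S,
    threshold: float = STABILITY_THRESHOLD,
) -> tuple[Segment, StabilityReport]:
    """Pick the most stationary ``duration``-long window of a recording.

    Slides the window in 1-s steps; each candidate is scored by
    max/median RMS over its non-overlapping 1-s subwindows and the
    minimum-score window wins (ties to the earliest start).  The segment is
    returned even when the best score exceeds ``threshold``; the report's
    ``accepted`` flag records the verdict.
    """
    if raw.rate < 2 * BAND_HI_HZ:
        raise ValueError(
            f"sampling rate {raw.rate:g} Hz cannot resolve the "
            f"{BAND_HI_HZ:g} Hz band edge (need >= {2 * BAND_HI_HZ:g} Hz)"
        )
    win = int(round(duration * raw.rate))
    if win < 1 or len(raw) < win:
        raise ValueError(
            f"recording too short: {raw.duration:g} s < requested {duration:g} s"
        )
    step = max(int(round(raw.rate)), 1)  # 1-s slide
    sub = step  # 1-s subwindows

    x = raw.samples - np.mean(raw.samples)  # DC offset is not instability
    rms = _subwindow_rms(x, sub)
    nsub = max(win // sub, 1)

    best_score = math.inf
    best_start = 0
    for start in range(0, len(raw) - win + 1, step):
        k = start // sub
        r = rms[k : k + nsub]
        if r.size < nsub:  # tail window not block-aligned; score directly
            r = _subwindow_rms(x[start : start + win], sub)
        med = float(np.median(r))
        mx = float(np.max(r))
        score = 1.0 if mx == 0.0 else (math.inf if med == 0.0 else mx / med)
        # strict improvement beyond float noise, so exact ties keep the
        # earliest window
        if score < best_score - 1e-10:
            best_score = score
            best_start = start
    seg = Segment(
        raw.samples[best_start : best_start + win].copy(),
        raw.rate,
        start_time=best_start / raw.rate,
        duration=win / raw.rate,
    )
    report = StabilityReport(
        window_start=best_start / raw.rate,
        stability_score=best_score,
        accepted=best_score <= threshold,
    )
    return seg, report


def _band_mask(freqs: np.ndarray, lo: float, hi: float, width: float) -> np.ndarray:
    """Raised-cosine band mask.

    The transitions sit just inside the band edges (0 at the edge, 1 one
    transition-width inward), so everything outside [lo, hi] is removed
    entirely rather than merely attenuated; the cost is a soft shoulder on
    the innermost ``width`` Hz of the passband.
    """
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo + width) & (freqs <= hi - width)
    mask[inside] = 1.0
    rise = (freqs > lo) & (freqs < lo + width)
    mask[rise] = 0.5 * (1.0 - np.cos(np.pi * (freqs[rise] - lo) / width))
    fall = (freqs > hi - width) & (freqs < hi)
    mask[fall] = 0.5 * (1.0 - np.cos(np.pi * (hi - freqs[fall]) / width))
    return mask


def bandpass(
    seg: Segment, lo: float = BAND_LO_HZ, hi: float = BAND_HI_HZ
) -> Segment:
    """Zero-phase band-limit a segment to [lo, hi] Hz.

    The mean is removed, the spectrum is multiplied by a band mask with
    raised-cosine transitions of width ``TRANSITION_HZ`` just inside the
    edges, and the signal is transformed back.  Being a pure frequency-domain
    mask the filter is exactly linear and phase-free, and power outside
    [lo, hi] is removed entirely.
    """
    if lo <= 0:
        raise ValueError(f"low edge must be positive, got {lo:g}")
    if hi >= seg.rate / 2:
        raise ValueError(
            f"high edge {hi:g} Hz must lie below the Nyquist frequency "
            f"{seg.rate / 2:g} Hz"
        )
    if lo >= hi:
        raise ValueError("low edge must lie below high edge")
    x = seg.samples - np.mean(seg.samples)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / seg.rate)
    y = np.fft.irfft(spec * _band_mask(freqs, lo, hi, TRANSITION_HZ), n=x.size)
    return Segment(y, seg.rate, start_time=seg.start_time, duration=seg.duration)
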