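"""End-to-end convenience: raw recording -> spectral peak features."""

from __future__ import annotations

from dataclasses import dataclass

from .features import PeakFeatures, extract_features
from .preprocess import (
    BAND_HI_HZ,
    BAND_LO_HZ,
    SEGMENT_DURATION_S,
    STABILITY_THRESHOLD,
    Segment,
    StabilityReport,
    bandpass,
    select_stable_segment,
)
from .signal_io import RawSignal
from .spectral import (
    SMOOTH_WIDTH_BINS,
    NormalizedSpectrum,
    normalize,
    power_spectrum,
    smooth,
)

__all__ = ["AnalysisResult", "analyze"]


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the pipeline produces for one recording."""

    features: PeakFeatures
    spectrum: NormalizedSpectrum
    segment: Segment
    stability: StabilityReport


def analyze(
    raw: RawSignal,
    *,
    duration: float = SEGMENT_DURATION_S,
    lo: float = BAND_LO_HZ,
    hi: float = BAND_HI_HZ,
    stability_threshold: float = STABILITY_THRESHOLD,
    smooth_bins: int = SMOOTH_WIDTH_BINS,
) -> AnalysisResult:
    """Run the full chain: stable segment -> band-limit -> periodogram ->
    smooth -> unit-integral normalization -> peak features."""
    seg, report = select_stable_segment(raw, duration=duration, threshold=stability_threshold)
    seg = bandpass(seg, lo=lo, hi=hi)
    spec = power_spectrum(seg, lo=lo, hi=hi)
    spec = smooth(spec, smooth_bins)
    nspec = normalize(spec)
    return AnalysisResult(
        features=extract_features(nspec),
        spectrum=nspec,
        segment=seg,
        stability=report,
    )
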