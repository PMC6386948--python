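"""Seeded synthetic piezo-sensor recordings with cardiac harmonic structure.

The generator emulates what a PVDF sheet sensor records from a seated
person: a phase-locked comb of heartbeat harmonics whose instantaneous
period jitters beat to beat inside a hard +-100 ms envelope (respiratory
sinus arrhythmia), an optional amplitude modulation of the higher harmonics
at the heart rate with a suppressed ~1 Hz fundamental (observed in a subset
of subjects), a large sub-0.6 Hz respiratory oscillation, broadband sensor
noise, and occasional 2-s body-movement bursts.

Individuality lives in the harmonic amplitude envelope (how vascular
reflection shapes the blood-pressure waveform differs between people), in
the nominal heart rate, and in the modulation depth.  Repeat sessions of
the same synthetic subject perturb the harmonic amplitudes multiplicatively
(log-normal), realizing "similar but not identical" day-to-day spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .signal_io import RawSignal

__all__ = [
    "SimSubject",
    "CohortSpec",
    "make_subject",
    "synth_signal",
    "synth_cohort",
    "beat_intervals",
]

#: Hard bound on beat-interval jitter, s (respiratory sinus arrhythmia).
JITTER_MAX_S = 0.1
#: Band edge above which no deliberate harmonic is generated, Hz.
HARMONIC_CEILING_HZ = 15.0
#: Default day-to-day relative spread of harmonic amplitudes.
SESSION_VARIABILITY = 0.01
#: Default expected number of 2-s movement bursts per recording.
ARTIFACT_RATE = 1.0

ProfileKind = Literal["fundamental-rich", "am-suppressed"]


@dataclass(frozen=True)
class SimSubject:
    """Generative parameters of one synthetic person's vibration signature."""

    subject_id: str
    f0: float  # nominal heart rate, Hz
    harmonics: tuple[tuple[int, float, float], ...]  # (order, amplitude, phase)
    am_depth: float = 0.0  # AM index on harmonics of order >= 2
    jitter_max: float = JITTER_MAX_S
    resp_freq: float = 0.25  # Hz, below the 0.6 Hz band edge
    resp_amp: float = 0.0
    noise_sd: float = 0.0
    session_variability: float = SESSION_VARIABILITY

    def __post_init__(self) -> None:
        if not 0 < self.f0:
            raise ValueError("f0 must be positive")
        if not 0 <= self.jitter_max <= JITTER_MAX_S:
            raise ValueError(f"jitter_max must lie in [0, {JITTER_MAX_S}] s")
        if not self.resp_freq < 0.6:
            raise ValueError("respiration frequency must be below 0.6 Hz")
        if not 0 <= self.am_depth <= 1:
            raise ValueError("am_depth must lie in [0, 1]")
        for h, a, _ in self.harmonics:
            if a < 0:
                raise ValueError("harmonic amplitudes must be non-negative")
            if h * self.f0 > HARMONIC_CEILING_HZ + 1e-9:
                raise ValueError(
                    f"harmonic {h} at {h * self.f0:g} Hz exceeds the "
                    f"{HARMONIC_CEILING_HZ:g} Hz ceiling"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic cohort."""

    n_subjects: int = 8
    n_sessions: int = 3
    duration: float = 180.0  # one 3-min measurement per session
    rate: float = 100.0
    seed: int = 0
    artifact_rate: float = ARTIFACT_RATE
    session_variability: float = SESSION_VARIABILITY
    am_suppressed_fraction: float = 0.35  # share of subjects lacking a ~1 Hz line

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least 1 subject")
        if self.duration < 10:
            raise ValueError("recordings must be at least 10 s for analysis")


def _broadening_compensation(orders: np.ndarray, f0: float, jitter_max: float) -> np.ndarray:
    """Amplitude factor offsetting the spectral-peak attenuation of higher
    harmonics under beat jitter.

    Beat-interval jitter frequency-modulates the harmonic comb; the linewidth
    of order ``h`` grows roughly with ``h * f0 * jitter``, spreading a fixed
    harmonic power over more bins and lowering its spectral peak.  The peak
    height of order h relative to the fundamental follows
    ``exp(-0.362 z - 1.366 z**2)`` with ``z = (h - 1) * f0 * jitter``
    (calibrated against the pipeline's smoothed spectra over a grid of f0,
    jitter and order); amplitudes are boosted by the inverse square root so
    a subject's realized *peak-height* profile tracks its drawn target,
    which is what the peak-shape features respond to.
    """
    z = (orders - 1.0) * f0 * jitter_max
    return np.exp(0.5 * (0.362 * z + 1.366 * z**2))


def _effective_line_magnitudes(amps: np.ndarray, phases: np.ndarray, am_depth: float) -> np.ndarray:
    """Magnitude of each harmonic line including first-order AM sidebands.

    Amplitude modulation of harmonic h (>= 2) at the heart rate places
    sidebands of complex amplitude ``am/2 * a_h * exp(i phi_h)`` on the
    neighbouring orders h - 1 and h + 1, where they interfere coherently
    with the lines already present.
    """
    c = amps * np.exp(1j * phases)
    eff = c.astype(complex).copy()
    for k in range(1, amps.size):  # AM acts on orders >= 2 (index >= 1)
        if k - 1 >= 0:
            eff[k - 1] += 0.5 * am_depth * c[k]
        if k + 1 < amps.size:
            eff[k + 1] += 0.5 * am_depth * c[k]
    return np.abs(eff)


def _calibrate_amplitudes(amps: np.ndarray, phases: np.ndarray, am_depth: float) -> np.ndarray:
    """Rescale line amplitudes so the *effective* magnitudes (with AM
    sideband interference) match the drawn target profile."""
    if am_depth == 0.0:
        return amps
    a = amps.copy()
    for _ in range(6):
        eff = _effective_line_magnitudes(a, phases, am_depth)
        a = np.clip(a * amps / np.maximum(eff, 1e-12), 0.0, None)
    return a


def make_subject(
    seed: int,
    profile_kind: ProfileKind = "fundamental-rich",
    subject_id: str | None = None,
    target_cell: int | None = None,
) -> SimSubject:
    """Draw one synthetic subject's generative parameters.

    A subject is characterized by a bimodal target profile of spectral peak
    heights: a *dominant* harmonic set (peaks above the half-power standard),
    an optional *mid* set (above quarter- but below half-power), and a low
    floor.  ``"fundamental-rich"`` subjects anchor the dominant set at the
    ~1 Hz fundamental, which carries the largest amplitude;
    ``"am-suppressed"`` subjects centre it on a mid-order harmonic cluster,
    carry <= 5% of the dominant amplitude at the fundamental, and are
    strongly amplitude-modulated at the heart rate.  ``target_cell``
    (0-12, default random) pins the drawn target peak-shape number to one
    of the 13 half-integer cells in [1, 7]; cohort generation uses it to
    spread enrolled subjects over the feature plane.  Deterministic per
    seed.
    """
    if profile_kind not in ("fundamental-rich", "am-suppressed"):
        raise ValueError(f"unknown profile kind: {profile_kind!r}")
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(0.9, 1.3)
    h_max = int(HARMONIC_CEILING_HZ / f0)
    orders = np.arange(1, h_max + 1)

    # Spread subjects over the feature plane: draw the target peak-shape
    # number uniformly over its half-integer grid, realized as n_dom extra
    # half-standard lines plus at most one quarter-standard-only mid line
    # carrying the half step (n_peaks ~ 1 + n_dom + n_mid/2).  Structured
    # lines occupy the lowest available orders: the features are blind to
    # peak placement, and low-order lines have by far the most reproducible
    # heights under beat jitter.
    if target_cell is None:
        target_cell = int(rng.integers(0, 13))
    t = (target_cell % 13) / 2.0  # target n_peaks - 1 in {0, 0.5, ..., 6}
    n_dom = int(t)
    n_mid = int(round(2 * (t - n_dom)))

    # People differ in respiratory sinus arrhythmia magnitude; linewidths
    # (hence peak sharpness) inherit that difference.  A line's height is
    # only reproducible while its jitter-driven linewidth stays compact
    # (h*f0*jitter below ~0.25-0.45; beyond that the phase noise fragments
    # it into ragged maxima), so a subject needing many distinct lines
    # draws a proportionally calmer heartbeat.
    anchor = 1 if profile_kind == "fundamental-rich" else int(rng.integers(3, 5))
    top_order = anchor + n_dom + n_mid
    z_cap = 0.25 if top_order <= 4 else (0.15 if top_order <= 6 else 0.10)
    jitter_hi = min(0.09, z_cap / (max(top_order - 1, 1) * f0))
    jitter_max = rng.uniform(0.012, max(jitter_hi, 0.013))
    comp = _broadening_compensation(orders, f0, jitter_max)

    # target relative peak powers: low floor everywhere, then the dominant
    # block and the optional mid line
    target = rng.uniform(0.002, 0.02, orders.size)
    phases = rng.uniform(0.0, 2 * np.pi, orders.size)

    structured = list(range(anchor, top_order + 1))
    target[anchor - 1] = 1.0
    # subject-level dominant plateau: where the overtone levels sit relative
    # to the maximum is itself part of a person's signature (it sets the
    # size of the above-threshold caps and hence the sharpness residual)
    r0 = rng.uniform(0.66, 0.96)
    for h in structured[1 : 1 + n_dom]:
        target[h - 1] = np.clip(r0 + rng.uniform(-0.02, 0.02), 0.55, 0.98)
    for h in structured[1 + n_dom :]:
        target[h - 1] = rng.uniform(0.34, 0.40)

    amps = np.sqrt(target)
    in_struct = np.isin(orders, structured)
    amps[in_struct] *= comp[in_struct]  # floor lines stay uncompensated

    if profile_kind == "fundamental-rich":
        am_depth = rng.uniform(0.0, 0.25)
        amps = _calibrate_amplitudes(amps, phases, am_depth)
        amps[0] = max(amps[0], 1.001 * amps[1:].max())  # fundamental dominates
    else:
        # anchor (AM carrier) at order >= 3 so its lower sideband stays
        # away from the ~1 Hz fundamental position
        am_depth = rng.uniform(0.5, 0.7)
        amps[0] = 0.0
        amps = _calibrate_amplitudes(amps, phases, am_depth)
        amps[0] = 0.02 * rng.uniform(0.5, 1.0) * amps[1:].max()  # suppressed ~1 Hz line

    # Broadband sensor/background noise level differs between recordings of
    # different people (clothing, posture, coupling); the in-band noise
    # fraction rescales every normalized peak height, making it a stable
    # per-subject component of the sharpness feature.
    noise_coef = rng.uniform(0.02, 0.10)
    peak_amp = float(amps.max())
    return SimSubject(
        subject_id=subject_id if subject_id is not None else f"S{seed:03d}",
        f0=float(f0),
        harmonics=tuple(
            (int(h), float(a), float(p)) for h, a, p in zip(orders, amps, phases)
        ),
        am_depth=float(am_depth),
        jitter_max=float(jitter_max),
        resp_freq=float(rng.uniform(0.15, 0.35)),
        resp_amp=float(rng.uniform(1.0, 3.0) * peak_amp),
        noise_sd=float(noise_coef * np.sqrt(np.sum(amps**2) / 2.0)),
    )


def _draw_intervals(rng: np.random.Generator, f0: float, jitter_max: float, n: int) -> np.ndarray:
    """Beat-to-beat intervals: nominal period plus hard-bounded uniform jitter."""
    return 1.0 / f0 + rng.uniform(-jitter_max, jitter_max, n)


def beat_intervals(subj: SimSubject, n_beats: int, seed: int) -> np.ndarray:
    """The first ``n_beats`` beat intervals ``synth_signal`` would realize."""
    rng = np.random.default_rng(seed)
    return _draw_intervals(rng, subj.f0, subj.jitter_max, n_beats)


def synth_signal(
    subj: SimSubject,
    duration: float = 180.0,
    rate: float = 100.0,
    seed: int = 0,
    artifact_rate: float = ARTIFACT_RATE,
) -> RawSignal:
    """Render one recording of a subject.

    Beat times accumulate the jittered intervals; the instantaneous cardiac
    phase is linear between beats, so all harmonics stay phase-locked to
    the same (fluctuating) heartbeat.  Harmonics of order >= 2 are
    amplitude-modulated at the heart rate by ``am_depth``.  Respiration,
    white sensor noise, and Poisson-count 2-s movement bursts (5x signal
    RMS) are added on top.  Deterministic per (subj, seed).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 30:
        raise ValueError("rate must exceed 30 Hz to resolve the cardiac band")
    rng = np.random.default_rng(seed)

    # beats cover [-2, duration + 2] s so phase interpolation never clamps
    pad = 2.0
    n_beats = int(np.ceil((duration + 2 * pad) * subj.f0 / (1 - subj.jitter_max * subj.f0))) + 4
    intervals = _draw_intervals(rng, subj.f0, subj.jitter_max, n_beats)
    beat_times = -pad + np.concatenate(([0.0], np.cumsum(intervals)))

    t = np.arange(int(round(duration * rate))) / rate
    phase = np.interp(t, beat_times, np.arange(beat_times.size, dtype=float))

    sig = np.zeros_like(t)
    am = 1.0 + subj.am_depth * np.cos(2 * np.pi * phase)
    for h, a, phi in subj.harmonics:
        carrier = np.cos(2 * np.pi * h * phase + phi)
        sig += a * (am * carrier if h >= 2 else carrier)

    cardiac_rms = float(np.sqrt(np.mean(sig**2))) or 1.0
    sig = sig + subj.resp_amp * np.sin(2 * np.pi * subj.resp_freq * t)
    if subj.noise_sd > 0:
        sig = sig + rng.normal(0.0, subj.noise_sd, t.size)

    n_bursts = rng.poisson(artifact_rate) if artifact_rate > 0 else 0
    burst_len = int(round(2.0 * rate))
    for _ in range(n_bursts):
        if duration <= 2.0:
            break
        start = int(round(rng.uniform(0.0, duration - 2.0) * rate))
        shape = rng.normal(0.0, 1.0, burst_len)
        shape *= np.hanning(burst_len)
        shape *= 5.0 * cardiac_rms / (np.sqrt(np.mean(shape**2)) or 1.0)
        sig[start : start + burst_len] += shape[: sig.size - start]

    return RawSignal(sig, rate, meta=subj.subject_id)


def synth_cohort(spec: CohortSpec) -> tuple[list[tuple[str, str, RawSignal]], pd.DataFrame]:
    """Generate a labelled multi-subject, multi-session cohort.

    Per session, a subject's harmonic amplitudes are perturbed by a
    multiplicative log-normal factor with relative spread
    ``session_variability``, so repeat sessions yield similar but not
    identical spectra.  Deterministic per ``spec.seed``.  Returns the
    recordings and a truth table mapping each recording to its subject.
    """
    root = np.random.SeedSequence(spec.seed)
    kind_rng = np.random.default_rng(root.spawn(1)[0])
    # spread the cohort over the feature plane: distinct target peak-number
    # cells per subject (the study premise is that different people carry
    # visibly different harmonic signatures)
    spaced = np.unique(np.round(np.linspace(0, 12, min(spec.n_subjects, 13))).astype(int))
    extra = spec.n_subjects - spaced.size
    pool = np.concatenate([spaced] + [np.arange(13)] * (extra // 13 + 1))[: spec.n_subjects]
    cells = kind_rng.permutation(pool)
    recordings: list[tuple[str, str, RawSignal]] = []
    truth_rows = []
    for i in range(spec.n_subjects):
        subject_seq, *session_seqs = root.spawn(spec.n_sessions + 1)
        kind: ProfileKind = (
            "am-suppressed"
            if kind_rng.uniform() < spec.am_suppressed_fraction
            else "fundamental-rich"
        )
        subject_id = f"S{i + 1:02d}"
        subj = make_subject(
            int(subject_seq.generate_state(1)[0] % 2**31), kind,
            subject_id=subject_id, target_cell=int(cells[i])
        )
        subj = replace(subj, session_variability=spec.session_variability)
        for j, ses_seq in enumerate(session_seqs):
            ses_rng = np.random.default_rng(ses_seq)
            factors = np.exp(
                ses_rng.normal(0.0, subj.session_variability, len(subj.harmonics))
            )
            day = replace(
                subj,
                harmonics=tuple(
                    (h, a * f, p) for (h, a, p), f in zip(subj.harmonics, factors)
                ),
            )
            session_id = f"d{j + 1}"
            rec = synth_signal(
                day,
                duration=spec.duration,
                rate=spec.rate,
                seed=int(ses_seq.generate_state(2)[1] % 2**31),
                artifact_rate=spec.artifact_rate,
            )
            recordings.append((subject_id, session_id, rec))
            truth_rows.append(
                {"subject": subject_id, "session": session_id, "kind": kind}
            )
    truth = pd.DataFrame(truth_rows, columns=["subject", "session", "kind"])
    return recordings, truth
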