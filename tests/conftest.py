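import numpy as np
import pytest
from hypothesis import settings

from piezoid.spectral import Spectrum

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_spectrum(power, df=0.1, f0=0.6):
    """Build a Spectrum from raw power values on a uniform grid."""
    power = np.asarray(power, dtype=float)
    freqs = f0 + df * np.arange(power.size)
    return Spectrum(freqs, power, df)


def brute_force_peaks(spec, fraction, refine=4000):
    """Independent oracle for peak counting and merged excess area.

    Counts strict local maxima above the threshold by direct scan, and
    integrates (power - threshold)+ on a ``refine``-times-denser linear
    interpolation grid; for a piecewise-linear spectrum the above-threshold
    excursions are exactly the merged peak regions, so this total equals
    the merged excess area.
    """
    power, freqs = spec.power, spec.freqs
    theta = fraction * power.max()
    n = power.size
    count = 0
    for k in range(n):
        if power[k] <= theta:
            continue
        left = power[k] > power[k - 1] if k > 0 else True
        right = power[k] >= power[k + 1] if k < n - 1 else True
        if left and right:
            count += 1
    x = np.linspace(freqs[0], freqs[-1], refine * (n - 1) + 1)
    p = np.interp(x, freqs, power)
    area = np.trapezoid(np.clip(p - theta, 0.0, None), x)
    return count, float(area)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-subject x 3-session cohort analysed end-to-end (shared, ~2 s)."""
    from piezoid import CohortSpec, analyze, synth_cohort

    recs, truth = synth_cohort(CohortSpec(n_subjects=4, n_sessions=3, seed=11))
    feats = {
        (sid, ses): analyze(raw).features for sid, ses, raw in recs
    }
    return feats, truth
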