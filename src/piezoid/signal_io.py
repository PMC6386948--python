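"""Reading and writing signal traces and feature tables.

Raw vibration traces are exchanged as delimited text with either a single
``amplitude`` column or two columns ``time_s,amplitude`` (time in seconds).
Feature tables are CSV with the header ``subject,session,n_peaks,sharpness``.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "RawSignal",
    "FeatureRecord",
    "read_signal",
    "write_features",
    "read_features",
]

#: Relative tolerance on timestamp uniformity (fraction of the median step).
RATE_UNIFORMITY_TOL = 0.01


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled single-channel vibration trace.

    Parameters
    ----------
    samples
        Amplitudes in arbitrary sensor units.
    rate
        Sampling frequency in Hz (> 0).
    meta
        Free-text label (e.g. subject/session provenance).
    """

    samples: np.ndarray
    rate: float
    meta: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise ValueError(f"sampling rate must be positive, got {self.rate!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.rate


class FeatureRecord(NamedTuple):
    """One labelled spectral-feature measurement (a row of a feature table)."""

    subject: str
    session: str
    n_peaks: float
    sharpness: float


def read_signal(path: str | os.PathLike, rate_override: float | None = None) -> RawSignal:
    """Read a raw trace from delimited text.

    One numeric column is interpreted as amplitudes and requires
    ``rate_override``.  Two columns are interpreted as (time in seconds,
    amplitude); the rate is the reciprocal of the median time step unless
    ``rate_override`` is given.  A non-numeric first row is treated as a
    header.  Timestamps must be strictly increasing and uniform to within
    1% of the median step.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"signal file not found: {path}")

    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for raw in csv.reader(fh):
            cells = [c.strip() for c in raw if c.strip() != ""]
            if cells:
                rows.append(cells)
    if not rows:
        raise ValueError(f"empty signal file: {path}")

    def _numeric(cells: Sequence[str]) -> bool:
        try:
            [float(c) for c in cells]
            return True
        except ValueError:
            return False

    if not _numeric(rows[0]):
        rows = rows[1:]  # header row
    if not rows:
        raise ValueError(f"signal file has a header but no data: {path}")

    ncol = len(rows[0])
    if ncol not in (1, 2):
        raise ValueError(f"expected 1 or 2 columns, found {ncol} in {path}")
    for i, cells in enumerate(rows):
        if len(cells) != ncol:
            raise ValueError(f"inconsistent column count at data row {i} in {path}")
        if not _numeric(cells):
            raise ValueError(f"non-numeric value at data row {i} in {path}")

    data = np.asarray([[float(c) for c in cells] for cells in rows], dtype=float)

    if ncol == 1:
        if rate_override is None:
            raise ValueError(
                "single-column signal file requires an explicit sampling rate "
                "(rate_override)"
            )
        return RawSignal(data[:, 0], float(rate_override), meta=os.path.basename(path))

    t, x = data[:, 0], data[:, 1]
    if t.size < 2:
        raise ValueError("two-column signal file needs at least 2 rows")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("timestamps must be strictly increasing")
    med = float(np.median(steps))
    if np.any(np.abs(steps - med) > RATE_UNIFORMITY_TOL * med):
        raise ValueError(
            "non-uniform sampling: time steps deviate more than "
            f"{RATE_UNIFORMITY_TOL:.0%} from the median step {med:g} s"
        )
    rate = float(rate_override) if rate_override is not None else 1.0 / med
    return RawSignal(x, rate, meta=os.path.basename(path))


def write_features(records: Sequence[tuple], path: str | os.PathLike) -> None:
    """Write ``(subject, session, features)`` records as a feature CSV.

    ``features`` may be a :class:`~piezoid.features.PeakFeatures`, a
    :class:`FeatureRecord`, or any object with ``n_peaks`` and ``sharpness``
    attributes.  Values are written with 17 significant digits so a read-back
    reproduces them beyond 12 significant digits.
    """
    seen: set[tuple[str, str]] = set()
    lines = ["subject,session,n_peaks,sharpness"]
    for rec in records:
        if len(rec) == 3:
            subject, session, f = rec
            n_peaks, sharpness = f.n_peaks, f.sharpness
        else:
            subject, session, n_peaks, sharpness = rec
        subject, session = str(subject), str(session)
        if not subject or not session:
            raise ValueError("subject and session labels must be non-empty")
        key = (subject, session)
        if key in seen:
            raise ValueError(f"duplicate (subject, session) record: {key}")
        seen.add(key)
        lines.append(f"{subject},{session},{n_peaks:.17g},{sharpness:.17g}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


def read_features(path: str | os.PathLike) -> list[FeatureRecord]:
    """Read a feature CSV written by :func:`write_features`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"feature file not found: {path}")
    out: list[FeatureRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != [
            "subject", "session", "n_peaks", "sharpness",
        ]:
            raise ValueError(f"unrecognized feature-file header in {path}")
        for row in reader:
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"malformed feature row in {path}: {row!r}")
            out.append(
                FeatureRecord(row[0], row[1], float(row[2]), float(row[3]))
            )
    return out
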