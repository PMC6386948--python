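"""Enrollment, regression-residual discriminant, and subject matching.

The raw feature pair (peak-shape number, sharpness) is strongly correlated
by construction — sharpness divides total cap area by the peak count — so
the discriminative content along the second axis is the *deviation* of a
measurement's sharpness from the regression line of sharpness on peak
number fitted over the whole enrollment population.  Queries are matched in
the (n_peaks, residual) plane, z-scored by the population statistics, by
nearest subject centroid.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable

import numpy as np

__all__ = ["SubjectProfile", "ProfileDB", "CrossValidationReport"]


@dataclass
class SubjectProfile:
    """Feature measurements enrolled for one subject, one per session."""

    subject_id: str
    sessions: dict[str, tuple[float, float]] = field(default_factory=dict)
    # session_id -> (n_peaks, sharpness)

    def feature_matrix(self) -> np.ndarray:
        return np.array(list(self.sessions.values()), dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class CrossValidationReport:
    """Leave-one-session-out identification summary."""

    accuracy: float
    n_cases: int
    confusion: dict[str, dict[str, int]]
    median_intra_distance: float
    median_inter_distance: float
    intra_distances: tuple[float, ...]
    inter_distances: tuple[float, ...]


class ProfileDB:
    """Enrollment database with a population regression and feature scaler.

    The regression of sharpness on peak number and the per-dimension
    (n_peaks, residual) mean/std scaler are refitted over *all* enrolled
    sessions after every enrollment.  A dimension with zero spread is
    dropped from the matching distance.
    """

    def __init__(self) -> None:
        self.profiles: dict[str, SubjectProfile] = {}
        self._slope: float | None = None
        self._intercept: float | None = None
        self._means: np.ndarray | None = None
        self._stds: np.ndarray | None = None

    # -- enrollment -------------------------------------------------------

    def enroll(self, subject_id: str, session_id: str, features) -> "ProfileDB":
        """Register one session's features; refits regression and scaler.

        ``features`` is anything with ``n_peaks`` and ``sharpness``
        attributes (or a 2-tuple).  Duplicate (subject, session) pairs are
        rejected.
        """
        n_peaks, sharpness = _coerce(features)
        subject_id, session_id = str(subject_id), str(session_id)
        prof = self.profiles.setdefault(subject_id, SubjectProfile(subject_id))
        if session_id in prof.sessions:
            raise ValueError(
                f"duplicate enrollment for subject {subject_id!r}, "
                f"session {session_id!r}"
            )
        prof.sessions[session_id] = (float(n_peaks), float(sharpness))
        self._refit()
        return self

    @property
    def n_sessions(self) -> int:
        return sum(len(p.sessions) for p in self.profiles.values())

    def _all_points(self) -> np.ndarray:
        pts = [
            xy for p in sorted(self.profiles.values(), key=lambda p: p.subject_id)
            for xy in p.sessions.values()
        ]
        return np.array(pts, dtype=float).reshape(-1, 2)

    def _refit(self) -> None:
        pts = self._all_points()
        x, y = pts[:, 0], pts[:, 1]
        if np.unique(x).size >= 2:
            self._slope, self._intercept = (float(v) for v in np.polyfit(x, y, 1))
        else:
            self._slope = self._intercept = None
        res = np.array([self._residual_fallback(px, py) for px, py in pts])
        z = np.column_stack([x, res])
        self._means = z.mean(axis=0)
        self._stds = z.std(axis=0)  # population std; zero-spread dims dropped

    # -- regression discriminant -----------------------------------------

    @property
    def regression(self) -> tuple[float, float]:
        """(slope, intercept) of sharpness on n_peaks over all sessions."""
        if self._slope is None:
            raise ValueError(
                "regression undefined: need at least 2 distinct n_peaks values"
            )
        return self._slope, self._intercept

    def residual(self, features) -> float:
        """Deviation of a measurement's sharpness from the regression line."""
        n_peaks, sharpness = _coerce(features)
        slope, intercept = self.regression
        return float(sharpness - (intercept + slope * n_peaks))

    def _residual_fallback(self, n_peaks: float, sharpness: float) -> float:
        # With <2 distinct n_peaks the line is unidentifiable; deviation from
        # the mean sharpness preserves the discriminant's intent.
        if self._slope is not None:
            return sharpness - (self._intercept + self._slope * n_peaks)
        pts = self._all_points()
        return sharpness - float(pts[:, 1].mean())

    # -- matching ---------------------------------------------------------

    def _zscore(self, n_peaks: float, sharpness: float) -> np.ndarray:
        v = np.array([n_peaks, self._residual_fallback(n_peaks, sharpness)])
        z = np.zeros(2)
        for d in range(2):
            if self._stds[d] > 0:
                z[d] = (v[d] - self._means[d]) / self._stds[d]
            # zero-spread dimension contributes 0 for every point: dropped
        return z

    def _centroids(self) -> dict[str, np.ndarray]:
        return {
            sid: np.mean(
                [self._zscore(px, py) for px, py in prof.sessions.values()], axis=0
            )
            for sid, prof in self.profiles.items()
        }

    def identify(self, features, k: int = 1) -> list[tuple[str, float]]:
        """Rank enrolled subjects by distance to the query in z-space.

        Returns the ``k`` nearest (subject_id, distance) pairs, ascending by
        distance with lexical subject-id tie-break.
        """
        if not self.profiles:
            raise ValueError("cannot identify against an empty database")
        n_peaks, sharpness = _coerce(features)
        q = self._zscore(n_peaks, sharpness)
        ranked = sorted(
            (
                (sid, float(np.linalg.norm(q - c)))
                for sid, c in self._centroids().items()
            ),
            key=lambda t: (t[1], t[0]),
        )
        return ranked[: max(int(k), 1)]

    # -- evaluation -------------------------------------------------------

    def cross_validate(self) -> CrossValidationReport:
        """Leave-one-session-out identification over the whole database.

        Each session is held out in turn; the regression and scaler are
        refitted from scratch on the remainder, and the held-out features
        are identified against it.  Reports top-1 accuracy, per-subject
        confusion counts, and the median intra- vs inter-subject distance.
        """
        for prof in self.profiles.values():
            if len(prof.sessions) < 2:
                raise ValueError(
                    f"subject {prof.subject_id!r} has fewer than 2 sessions; "
                    "leave-one-session-out needs >= 2"
                )
        correct = 0
        n_cases = 0
        confusion: dict[str, dict[str, int]] = {}
        intra: list[float] = []
        inter: list[float] = []
        for sid, prof in sorted(self.profiles.items()):
            for session_id, (px, py) in sorted(prof.sessions.items()):
                held_out = ProfileDB()
                for sid2, prof2 in self.profiles.items():
                    for ses2, xy in prof2.sessions.items():
                        if (sid2, ses2) != (sid, session_id):
                            held_out.enroll(sid2, ses2, xy)
                ranked = held_out.identify((px, py), k=len(held_out.profiles))
                predicted = ranked[0][0]
                confusion.setdefault(sid, {}).setdefault(predicted, 0)
                confusion[sid][predicted] += 1
                correct += predicted == sid
                n_cases += 1
                for other, dist in ranked:
                    (intra if other == sid else inter).append(dist)
        return CrossValidationReport(
            accuracy=correct / n_cases,
            n_cases=n_cases,
            confusion=confusion,
            median_intra_distance=float(median(intra)),
            median_inter_distance=float(median(inter)),
            intra_distances=tuple(intra),
            inter_distances=tuple(inter),
        )

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {
            "subjects": {
                sid: {
                    "sessions": {
                        ses: {"n_peaks": xy[0], "sharpness": xy[1]}
                        for ses, xy in prof.sessions.items()
                    }
                }
                for sid, prof in self.profiles.items()
            }
        }
        if self.profiles:
            doc["fitted"] = {
                "slope": self._slope,
                "intercept": self._intercept,
                "means": list(self._means),
                "stds": list(self._stds),
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ProfileDB":
        db = cls()
        for sid, sub in doc.get("subjects", {}).items():
            for ses, xy in sub["sessions"].items():
                db.enroll(sid, ses, (xy["n_peaks"], xy["sharpness"]))
        return db

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ProfileDB":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _coerce(features) -> tuple[float, float]:
    if hasattr(features, "n_peaks"):
        return float(features.n_peaks), float(features.sharpness)
    n_peaks, sharpness = features
    return float(n_peaks), float(sharpness)
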