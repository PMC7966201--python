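"""Named landmark constellations (fiducial sets).

A :class:`FiducialSet` is an ordered list of labelled 3-D points in a declared
frame — ``image`` (scan-derived virtual model) or ``physical`` (the patient on
the table).  Registration estimates the rigid motion between the two frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateConfigurationError, InvalidInputError
from .transforms import RigidTransform

__all__ = ["FiducialSet", "check_noncollinear", "FRAMES"]

FRAMES = ("image", "physical")

#: below this second principal extent (mm) a constellation is treated as
#: collinear and the rigid pose is underdetermined about the line axis
COLLINEARITY_TOL = 1e-6


def check_noncollinear(points: np.ndarray, what: str = "fiducial set") -> None:
    """Raise if ``points`` (N×3) are fewer than 3 or all collinear.

    Collinearity test: second-largest singular value of the centred point
    matrix must exceed 1e-6 mm.  Coplanar sets are allowed (a plane still
    pins down the rigid pose); a line does not.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"{what} needs at least 3 points, got shape {pts.shape}"
        )
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[1] <= COLLINEARITY_TOL:
        raise DegenerateConfigurationError(
            f"{what} is collinear (second principal extent {s[1]:.2e} mm)"
        )


@dataclass(frozen=True)
class FiducialSet:
    """Ordered, labelled landmarks in one frame.

    Parameters
    ----------
    labels : sequence of str
        Unique landmark names, e.g. ``"nasal_bridge"``.
    points : (N, 3) array_like
        Coordinates in millimetres, N ≥ 3, not all collinear.
    frame : {"image", "physical"}
    """

    labels: tuple
    points: np.ndarray
    frame: str = "image"

    def __init__(self, labels: Sequence[str], points, frame: str = "image"):
        labels = tuple(str(l) for l in labels)
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError(f"points must be N×3, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("fiducial coordinates must be finite")
        if len(labels) != len(pts):
            raise InvalidInputError(
                f"{len(labels)} labels for {len(pts)} points"
            )
        if len(set(labels)) != len(labels):
            raise InvalidInputError("fiducial labels must be unique")
        if frame not in FRAMES:
            raise InvalidInputError(f"frame must be one of {FRAMES}, got {frame!r}")
        check_noncollinear(pts)
        pts = pts.copy()
        pts.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def transformed(self, t: RigidTransform, frame: str | None = None) -> "FiducialSet":
        """Return a copy with every point mapped by ``t`` (frame optionally renamed)."""
        return FiducialSet(self.labels, t.apply(self.points), frame or self.frame)

    def with_frame(self, frame: str) -> "FiducialSet":
        return FiducialSet(self.labels, self.points, frame)

    def subset(self, labels: Sequence[str]) -> "FiducialSet":
        """Select landmarks by label, in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return FiducialSet([self.labels[i] for i in idx], self.points[idx], self.frame)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)
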