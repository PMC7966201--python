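"""Rigid 3-D motion algebra.

All coordinates are millimetres in right-handed frames.  A
:class:`RigidTransform` maps points of one frame into another (for example
image space into physical space) as ``p ↦ R·p + t`` with ``R`` a proper
rotation.  Reflections are rejected at construction: anatomy must never be
mirrored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["RigidTransform", "apply", "compose", "invert"]

_ORTHO_TOL = 1e-9


def _as_points(p) -> tuple[np.ndarray, bool]:
    """Coerce a point or point list to an (N, 3) float array.

    Returns the array and whether the input was a single point.
    """
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InvalidInputError(f"expected 3-vectors, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("point coordinates must be finite")
    return arr, single


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation (3×3 orthonormal, det = +1) plus
    translation (mm).

    Parameters
    ----------
    rotation : (3, 3) array_like
        Orthonormal matrix with determinant +1 (to 1e-9).
    translation : (3,) array_like
        Offset in millimetres.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be a 3x3 matrix")
        if t.shape != (3,):
            raise InvalidInputError("translation must be a 3-vector")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise InvalidInputError("transform entries must be finite")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL, rtol=0.0):
            raise InvalidInputError("rotation is not orthonormal within 1e-9")
        if not abs(np.linalg.det(R) - 1.0) <= 1e-9:
            raise InvalidInputError(
                "rotation determinant must be +1 (reflections are forbidden)"
            )
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_rad`` about ``axis`` (Rodrigues), then translate."""
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or n == 0.0:
            raise InvalidInputError("axis must be a finite nonzero vector")
        a = a / n
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        # re-orthonormalise to keep the constructor's 1e-9 gate honest
        U, _, Vt = np.linalg.svd(R)
        return cls(U @ Vt, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        """Build from a 4×4 homogeneous matrix (row-major)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidInputError("homogeneous matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise InvalidInputError("last row of a rigid homogeneous matrix must be [0,0,0,1]")
        return cls(m[:3, :3], m[:3, 3])

    # -- serialization -----------------------------------------------------

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_json(self) -> str:
        """Serialize as a row-major 4×4 homogeneous matrix; round-trips exactly."""
        return json.dumps({"matrix": self.as_matrix().tolist()})

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(s)["matrix"])

    # -- algebra -----------------------------------------------------------

    def apply(self, p):
        """Map a point or list of points into the target frame."""
        arr, single = _as_points(p)
        out = arr @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol, rtol=0.0)
            and np.allclose(self.translation, other.translation, atol=atol, rtol=0.0)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        with np.printoptions(precision=4, suppress=True):
            return f"RigidTransform(rotation=\n{self.rotation},\n translation={self.translation})"


def apply(t: RigidTransform, p):
    """Functional alias of :meth:`RigidTransform.apply`."""
    return t.apply(p)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Functional alias: ``apply(compose(a, b), p) == apply(a, apply(b, p))``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    """Functional alias of :meth:`RigidTransform.inverse`."""
    return t.inverse()
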