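"""Probe-tip localization and reference-array patient tracking.

A :class:`MarkerArray` is any rigid body carrying ≥3 optically tracked
markers: the hand-held probe (its ``tip_offset`` is the pointer tip) and the
reference array clamped to the head fixation share the same abstraction.
Marker identity is known — each physical marker is a unique printed pattern —
so pose estimation is a paired least-squares fit, never ICP.

Patient tracking works by transform chaining.  At registration time the
virtual scene's world pose is *locked* to the reference array:
``lock = array_pose⁻¹ ∘ scene_to_world``.  After the bed (patient + clamp +
array) moves rigidly, a fresh array observation gives a new pose and the
scene is *relocked*: ``scene_to_world' = array_pose' ∘ lock``.  Because the
patient and array form one rigid body, relocking reproduces the registration
residuals exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import (
    DegenerateConfigurationError,
    InvalidInputError,
    SceneStateError,
    TrackingQualityWarning,
)
from .fiducials import check_noncollinear
from .registration import fit_rigid
from .transforms import RigidTransform

__all__ = [
    "MarkerArray",
    "PoseEstimate",
    "TrackedScene",
    "estimate_pose",
    "locate_tip",
    "lock_scene",
    "relock_scene",
]

#: marker-fit RMS (mm) above which a pose is flagged as low quality
DEFAULT_RMS_THRESHOLD = 2.0


@dataclass(frozen=True)
class MarkerArray:
    """Rigid tracked body: ≥3 markers plus a tip/reference offset, local frame.

    Parameters
    ----------
    name : str
    local_markers : (N, 3) array_like
        Marker centres in the body's local frame, mm.  Non-collinear and
        pairwise separated by more than 1 mm.
    tip_offset : (3,) array_like, optional
        Point of interest in the local frame (probe tip, or the reference
        origin).  Defaults to the marker centroid.
    """

    name: str
    local_markers: np.ndarray
    tip_offset: np.ndarray

    def __init__(self, name: str, local_markers, tip_offset=None):
        markers = np.asarray(local_markers, dtype=float)
        if markers.ndim != 2 or markers.shape[1] != 3:
            raise InvalidInputError("local_markers must be N×3")
        if not np.all(np.isfinite(markers)):
            raise InvalidInputError("marker coordinates must be finite")
        check_noncollinear(markers, f"marker array {name!r}")
        if np.min(pdist(markers)) <= 1.0:
            raise DegenerateConfigurationError(
                f"marker array {name!r} has markers closer than 1 mm"
            )
        tip = markers.mean(axis=0) if tip_offset is None else np.asarray(
            tip_offset, dtype=float
        )
        if tip.shape != (3,) or not np.all(np.isfinite(tip)):
            raise InvalidInputError("tip_offset must be a finite 3-vector")
        markers = markers.copy()
        markers.setflags(write=False)
        tip = tip.copy()
        tip.setflags(write=False)
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "local_markers", markers)
        object.__setattr__(self, "tip_offset", tip)

    @classmethod
    def from_json(cls, path) -> "MarkerArray":
        """Load a body-definition file: {name, markers, tip_offset} in mm."""
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"], d["markers"], d.get("tip_offset"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "markers": self.local_markers.tolist(),
                    "tip_offset": self.tip_offset.tolist(),
                },
                fh,
                indent=2,
            )

    def __len__(self) -> int:
        return len(self.local_markers)


@dataclass(frozen=True)
class PoseEstimate:
    """Least-squares body pose with its tracking-quality diagnostic."""

    transform: RigidTransform  # local -> world
    rms: float                 # marker-fit RMS, mm
    status: str                # "ok" or "low-quality"


def estimate_pose(
    body: MarkerArray,
    observed_markers,
    rms_threshold: float = DEFAULT_RMS_THRESHOLD,
) -> PoseEstimate:
    """Fit the body's local→world pose from observed marker positions.

    ``observed_markers`` must list the same markers in the same order as
    ``body.local_markers`` (marker identity is known).  An RMS above
    ``rms_threshold`` issues a :class:`TrackingQualityWarning` but still
    returns the pose: tracking degrades under poor conditions, it does not
    halt.
    """
    obs = np.asarray(observed_markers, dtype=float)
    if obs.shape != body.local_markers.shape:
        raise InvalidInputError(
            f"expected {len(body)} observed markers, got shape {obs.shape}"
        )
    if not np.all(np.isfinite(obs)):
        raise InvalidInputError("observed marker coordinates must be finite")
    check_noncollinear(obs, "observed markers")
    pose = fit_rigid(body.local_markers, obs)
    rms = float(np.sqrt(np.mean(np.sum((pose.apply(body.local_markers) - obs) ** 2, axis=1))))
    status = "ok"
    if rms > rms_threshold:
        status = "low-quality"
        warnings.warn(
            f"marker fit RMS {rms:.2f} mm exceeds {rms_threshold:.2f} mm",
            TrackingQualityWarning,
            stacklevel=2,
        )
    return PoseEstimate(pose, rms, status)


def locate_tip(body: MarkerArray, observed_markers, **kw) -> np.ndarray:
    """World-frame position of the body's tip/reference point."""
    est = estimate_pose(body, observed_markers, **kw)
    return est.transform.apply(body.tip_offset)


@dataclass(frozen=True)
class TrackedScene:
    """The holographic scene's world pose plus its stored array lock.

    ``scene_to_world`` maps scene (image-frame) coordinates into the world;
    after registration it *is* the image→physical transform.  ``lock`` is
    the scene expressed in the reference array's frame.
    """

    scene_to_world: RigidTransform
    lock: RigidTransform | None = None

    @property
    def locked(self) -> bool:
        return self.lock is not None

    def to_json(self, path) -> None:
        d = {
            "scene_to_world": self.scene_to_world.as_matrix().tolist(),
            "lock": self.lock.as_matrix().tolist() if self.lock else None,
            "locked": self.locked,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrackedScene":
        with open(path) as fh:
            d = json.load(fh)
        lock = d.get("lock")
        return cls(
            RigidTransform.from_matrix(d["scene_to_world"]),
            RigidTransform.from_matrix(lock) if lock is not None else None,
        )


def lock_scene(
    scene: TrackedScene, array: MarkerArray, observed_markers
) -> TrackedScene:
    """Store the scene's pose relative to the reference array.

    ``lock = array_pose⁻¹ ∘ scene_to_world`` so that
    ``array_pose ∘ lock == scene_to_world`` at lock time.
    """
    pose = estimate_pose(array, observed_markers).transform
    return replace(scene, lock=pose.inverse().compose(scene.scene_to_world))


def relock_scene(
    scene: TrackedScene, array: MarkerArray, observed_markers_after_move
) -> TrackedScene:
    """Re-derive the scene's world pose from a fresh array observation.

    If the patient and array moved rigidly by M, the new ``scene_to_world``
    equals ``M ∘ old scene_to_world`` — the hologram follows the patient.
    """
    if not scene.locked:
        raise SceneStateError("scene is not locked to a reference array")
    pose = estimate_pose(array, observed_markers_after_move).transform
    return replace(scene, scene_to_world=pose.compose(scene.lock))
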