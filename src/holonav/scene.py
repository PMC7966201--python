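"""Holographic scene handling: STL meshes plus image-frame fiducials.

A scene bundles the segmented anatomy (skin, brain, tumour, vessels — one
triangle mesh each, exported as .stl) with the registration landmarks, all
declared in the image frame.  STL carries no unit metadata: coordinates are
**assumed to be millimetres** throughout.

Meshes are loaded verbatim (no vertex merging or repair) so an identity
transform leaves coordinates bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import FormatError, InvalidInputError
from .fiducials import FiducialSet
from .transforms import RigidTransform

__all__ = ["HolographicScene", "load_scene", "transform_scene"]


@dataclass(frozen=True)
class HolographicScene:
    """Named triangle meshes (mm, image frame) with their fiducials."""

    meshes: dict
    fiducials: FiducialSet
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mesh in self.meshes.items():
            if not np.all(np.isfinite(mesh.vertices)):
                raise InvalidInputError(f"mesh {name!r} has non-finite vertices")

    def report(self) -> dict:
        """Vertex/triangle counts per mesh plus fiducial count."""
        return {
            "meshes": {
                name: {
                    "vertices": int(len(m.vertices)),
                    "triangles": int(len(m.faces)),
                    "area_mm2": float(m.area),
                }
                for name, m in self.meshes.items()
            },
            "n_fiducials": len(self.fiducials),
            "metadata": dict(self.metadata),
        }


def load_scene(mesh_paths, fiducial_file, metadata: dict | None = None) -> HolographicScene:
    """Load STL meshes (binary or ASCII) and a landmark file into a scene."""
    from .io import read_landmarks

    meshes = {}
    for path in mesh_paths:
        p = Path(path)
        if not p.exists():
            raise FormatError(f"{p}: no such file")
        try:
            mesh = trimesh.load_mesh(str(p), file_type="stl", process=False)
        except Exception as exc:
            raise FormatError(f"{p}: malformed STL ({exc})") from exc
        if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
            raise FormatError(f"{p}: STL contains no triangles")
        meshes[p.stem] = mesh
    fids = read_landmarks(fiducial_file, frame="image")
    return HolographicScene(meshes, fids, metadata or {})


def transform_scene(scene: HolographicScene, t: RigidTransform) -> HolographicScene:
    """Map every mesh vertex and fiducial by ``t``; topology unchanged."""
    moved = {
        name: trimesh.Trimesh(
            vertices=t.apply(np.asarray(m.vertices, dtype=float)),
            faces=m.faces.copy(),
            process=False,
        )
        for name, m in scene.meshes.items()
    }
    return HolographicScene(moved, scene.fiducials.transformed(t), dict(scene.metadata))
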