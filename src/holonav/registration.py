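"""Patient-to-image registration.

Two estimation paths are provided, mirroring how point-based navigation is
operated in practice:

* :class:`PairedPointRegistration` — the operator records landmarks one by
  one, so the correspondence between image and physical fiducials is known.
  The least-squares rigid motion is obtained in closed form from the SVD of
  the cross-covariance (Kabsch/Umeyama absolute orientation) with a
  determinant correction that forbids reflections.
* :class:`ICPRegistration` — iterative closest point for the case where the
  correspondence is discarded: alternate nearest-neighbour matching and the
  closed-form paired fit until the fiducial registration error (FRE) stops
  changing.

Both return a :class:`RegistrationResult` carrying the fitted transform,
per-fiducial residuals, the FRE (root-mean-square residual, mm) and a
``summary()`` table.  The FRE is the navigation field's standard report of
registration quality; the target registration error (TRE) at a point *not*
used in fitting is computed separately by :func:`compute_tre`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    ConvergenceWarning,
    CorrespondenceError,
    InvalidInputError,
)
from .fiducials import FiducialSet, check_noncollinear
from .transforms import RigidTransform

import warnings

__all__ = [
    "RegistrationResult",
    "PairedPointRegistration",
    "ICPRegistration",
    "fit_rigid",
    "register_paired",
    "register_icp",
    "compute_fre",
    "compute_tre",
    "summarize_sessions",
]


def fit_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid motion mapping ``src`` onto ``dst``.

    Minimises Σ‖R·srcᵢ + t − dstᵢ‖² over proper rotations R and translations
    t (Kabsch/Umeyama).  The singular-vector determinant is corrected so the
    solution is always a rotation, never a reflection.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape:
        raise CorrespondenceError(
            f"point sets differ in shape: {src.shape} vs {dst.shape}"
        )
    check_noncollinear(src, "source point set")
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0.0:  # pragma: no cover - requires exactly singular H
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def _paired_residuals(
    transform: RigidTransform, src: np.ndarray, dst: np.ndarray
) -> np.ndarray:
    return np.linalg.norm(transform.apply(src) - dst, axis=1)


def _rms(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(values))))


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted image→physical transform with its residual diagnostics.

    Attributes
    ----------
    transform : RigidTransform
        The image→physical rigid motion.
    residuals : (N,) ndarray
        Per-fiducial distances ‖T(imageᵢ) − physicalᵢ‖ in mm, in fiducial
        order (for ICP: distance to the matched point).
    fre : float
        Root-mean-square residual, mm.
    n_fiducials : int
    method : {"paired", "icp"}
    iterations : int
        0 for the closed-form paired fit.
    status : str
        "ok", "converged", "max_iter" or "converged-to-start".
    labels : tuple of str
    """

    transform: RigidTransform
    residuals: np.ndarray
    fre: float
    n_fiducials: int
    method: str
    iterations: int = 0
    status: str = "ok"
    labels: tuple = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.residuals, dtype=float)
        r.setflags(write=False)
        object.__setattr__(self, "residuals", r)
        assert abs(self.fre - _rms(r)) < 1e-9, "FRE must be the RMS residual"

    def tre(self, image_target, physical_target) -> float:
        """Target registration error at a point not used in the fit (mm)."""
        return compute_tre(self.transform, image_target, physical_target)

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.as_matrix().tolist(),
            "residuals_mm": self.residuals.tolist(),
            "labels": list(self.labels),
            "fre_mm": self.fre,
            "n_fiducials": self.n_fiducials,
            "method": self.method,
            "iterations": self.iterations,
            "status": self.status,
        }

    def summary(self) -> str:
        """Human-readable fit report (FRE to 0.1 mm, the field's precision)."""
        lines = [
            "Rigid point-based registration",
            "=" * 46,
            f"method:        {self.method}",
            f"fiducials:     {self.n_fiducials}",
            f"iterations:    {self.iterations}",
            f"status:        {self.status}",
            f"FRE:           {self.fre:.1f} mm",
            "-" * 46,
            f"{'fiducial':<24}{'residual (mm)':>14}",
        ]
        labels = self.labels or tuple(
            f"point_{i}" for i in range(self.n_fiducials)
        )
        for lab, res in zip(labels, self.residuals):
            lines.append(f"{lab:<24}{res:>14.3f}")
        lines.append("-" * 46)
        with np.printoptions(precision=6, suppress=True):
            lines.append("image -> physical (4x4 homogeneous):")
            lines.append(str(self.transform.as_matrix()))
        return "\n".join(lines)


def _check_pair(image_fids: FiducialSet, physical_fids: FiducialSet,
                require_labels: bool) -> None:
    if image_fids.frame != "image" or physical_fids.frame != "physical":
        raise CorrespondenceError(
            "expected an image-frame and a physical-frame fiducial set, got "
            f"{image_fids.frame!r} and {physical_fids.frame!r}"
        )
    if require_labels:
        if image_fids.labels != physical_fids.labels:
            raise CorrespondenceError(
                "paired registration needs identical labels in identical "
                f"order; got {image_fids.labels} vs {physical_fids.labels}"
            )


class PairedPointRegistration:
    """Model: rigid image→physical registration with known correspondence.

    Parameters
    ----------
    image_fids, physical_fids : FiducialSet
        Same labels in the same order; frames ``image`` and ``physical``.

    Examples
    --------
    >>> fit = PairedPointRegistration(image, physical).fit()
    >>> fit.fre
    0.0
    """

    method = "paired"

    def __init__(self, image_fids: FiducialSet, physical_fids: FiducialSet):
        _check_pair(image_fids, physical_fids, require_labels=True)
        self.image_fids = image_fids
        self.physical_fids = physical_fids

    @classmethod
    def from_files(cls, image_path, physical_path):
        """Build from two landmark files (CSV or .fcsv)."""
        from .io import read_landmarks

        return cls(
            read_landmarks(image_path, frame="image"),
            read_landmarks(physical_path, frame="physical"),
        )

    def fit(self) -> RegistrationResult:
        t = fit_rigid(self.image_fids.points, self.physical_fids.points)
        res = _paired_residuals(t, self.image_fids.points, self.physical_fids.points)
        return RegistrationResult(
            transform=t,
            residuals=res,
            fre=_rms(res),
            n_fiducials=len(res),
            method="paired",
            iterations=0,
            status="ok",
            labels=self.image_fids.labels,
        )


class ICPRegistration:
    """Model: iterative closest point registration, correspondence unknown.

    Alternates nearest-neighbour matching (each image point to its closest
    physical point; ties broken toward the lower index) with the closed-form
    paired fit, until the FRE change falls below ``tol`` or ``max_iter`` is
    reached.  The FRE is non-increasing across iterations.

    Parameters
    ----------
    image_fids, physical_fids : FiducialSet
        Labels are ignored; only geometry matters.
    max_iter : int, default 100
    tol : float, default 1e-6
        Convergence threshold on the FRE change, mm.
    init : RigidTransform, optional
        Initial image→physical guess; identity by default.
    """

    method = "icp"

    def __init__(
        self,
        image_fids: FiducialSet,
        physical_fids: FiducialSet,
        max_iter: int = 100,
        tol: float = 1e-6,
        init: RigidTransform | None = None,
    ):
        _check_pair(image_fids, physical_fids, require_labels=False)
        if max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if tol < 0:
            raise InvalidInputError("tol must be >= 0")
        self.image_fids = image_fids
        self.physical_fids = physical_fids
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.init = init or RigidTransform.identity()

    def _match(self, transform: RigidTransform) -> np.ndarray:
        """Nearest physical point for each transformed image point.

        ``argmin`` scans in index order, so equidistant candidates resolve
        deterministically to the lower index.
        """
        d = cdist(transform.apply(self.image_fids.points), self.physical_fids.points)
        return np.argmin(d, axis=1)

    def fit(self) -> RegistrationResult:
        src = self.image_fids.points
        dst = self.physical_fids.points
        t = self.init
        start_fre = _rms(np.linalg.norm(t.apply(src) - dst[self._match(t)], axis=1))
        fre_prev = start_fre
        iterations = 0
        status = "max_iter"
        corr = self._match(t)
        res = None
        for _ in range(self.max_iter):
            iterations += 1
            t = fit_rigid(src, dst[corr])
            corr = self._match(t)
            res = np.linalg.norm(t.apply(src) - dst[corr], axis=1)
            fre = _rms(res)
            if abs(fre_prev - fre) < self.tol:
                status = "converged"
                fre_prev = fre
                break
            fre_prev = fre
        if fre_prev >= start_fre - 1e-12 and start_fre > 0:
            status = "converged-to-start"
            warnings.warn(
                "ICP did not reduce the FRE below its starting value",
                ConvergenceWarning,
                stacklevel=2,
            )
        return RegistrationResult(
            transform=t,
            residuals=res,
            fre=fre_prev,
            n_fiducials=len(src),
            method="icp",
            iterations=iterations,
            status=status,
            labels=self.image_fids.labels,
        )


# -- functional surface ----------------------------------------------------

def register_paired(
    image_fids: FiducialSet, physical_fids: FiducialSet
) -> RegistrationResult:
    """Least-squares rigid registration with known correspondence."""
    return PairedPointRegistration(image_fids, physical_fids).fit()


def register_icp(
    image_fids: FiducialSet,
    physical_fids: FiducialSet,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Iterative-closest-point rigid registration, correspondence unknown."""
    return ICPRegistration(image_fids, physical_fids, max_iter, tol, init).fit()


def compute_fre(
    transform: RigidTransform,
    image_fids,
    physical_fids,
) -> tuple[float, np.ndarray]:
    """FRE of a given transform against paired fiducial sets.

    Evaluation does not refit anything, so unlike registration it is also
    defined for fewer than three points; plain (N, 3) arrays are accepted
    alongside :class:`FiducialSet`.

    Returns
    -------
    fre : float
        sqrt(mean(residuals²)), mm — the root-mean-square distance between
        mapped image fiducials and their homologous physical fiducials.
    residuals : (N,) ndarray
    """
    img = image_fids.points if isinstance(image_fids, FiducialSet) else \
        np.asarray(image_fids, dtype=float)
    phys = physical_fids.points if isinstance(physical_fids, FiducialSet) else \
        np.asarray(physical_fids, dtype=float)
    if img.shape != phys.shape or img.ndim != 2 or img.shape[1] != 3 or len(img) == 0:
        raise CorrespondenceError(
            f"paired N×3 sets required, got {img.shape} vs {phys.shape}"
        )
    if not (np.all(np.isfinite(img)) and np.all(np.isfinite(phys))):
        raise InvalidInputError("fiducial coordinates must be finite")
    res = _paired_residuals(transform, img, phys)
    return _rms(res), res


def compute_tre(transform: RigidTransform, image_target, physical_target) -> float:
    """Target registration error: ‖T(image_target) − physical_target‖ (mm).

    The targets are clinically relevant points (e.g. a tumour centroid)
    deliberately *not* used when fitting the transform.
    """
    it = np.asarray(image_target, dtype=float)
    pt = np.asarray(physical_target, dtype=float)
    if it.shape != (3,) or pt.shape != (3,):
        raise InvalidInputError("targets must be single 3-vectors")
    if not (np.all(np.isfinite(it)) and np.all(np.isfinite(pt))):
        raise InvalidInputError("target coordinates must be finite")
    return float(np.linalg.norm(transform.apply(it) - pt))


def summarize_sessions(fres: Sequence[float]) -> float:
    """Arithmetic mean FRE over registration sessions (mm)."""
    arr = np.asarray(list(fres), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("need at least one FRE value")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("FRE values must be finite and non-negative")
    return float(arr.mean())
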