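"""Synthetic head phantom and Monte-Carlo accuracy studies.

Real navigation accuracy depends on unreleased patient geometry and operator
behaviour, so the package studies its own error chain on synthetic phantoms:
a canonical constellation of head-surface landmarks (canthi, nasal bridge,
philtrum, antihelix, inion) is mapped by a known ground-truth rigid motion
into "physical space" and perturbed by fiducial localization error (FLE),
modelled as i.i.d. isotropic Gaussian noise per coordinate.  Registration on
the noisy pairs then yields FRE samples, and held-out interior targets yield
TRE samples, against the known truth.

The landmark template coordinates are invented plausible head-surface
positions (fixture geometry, not anatomy); only their geometric relations
matter to the mathematics.

For isotropic FLE with per-axis standard deviation σ applied in one space,
the classical expectation ``E[FRE²] = (1 − 2/N)·3σ²`` links FRE to FLE for N
fiducials; the Monte-Carlo machinery here reproduces it and also illustrates
that FRE does not certify TRE for an individual registration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InvalidInputError
from .fiducials import FiducialSet
from .registration import register_paired
from .tracking import MarkerArray, TrackedScene, estimate_pose, lock_scene, relock_scene
from .transforms import RigidTransform

__all__ = [
    "HEAD_LANDMARKS",
    "HEAD_TARGETS",
    "DEFAULT_REFERENCE_ARRAY",
    "PhantomSpec",
    "SimulationReport",
    "generate_phantom",
    "run_fre_study",
    "simulate_bed_movement",
    "run_tracking_study",
    "random_rigid",
]

#: canonical head-surface landmark template, mm.  Frame: origin mid-head,
#: x to the patient's right, y anterior, z superior.
HEAD_LANDMARKS: dict[str, tuple[float, float, float]] = {
    "nasal_bridge": (0.0, 95.0, 30.0),
    "medial_canthus_right": (16.0, 88.0, 28.0),
    "medial_canthus_left": (-16.0, 88.0, 28.0),
    "lateral_canthus_right": (45.0, 75.0, 26.0),
    "lateral_canthus_left": (-45.0, 75.0, 26.0),
    "philtrum": (0.0, 100.0, -25.0),
    "antihelix_right": (70.0, -5.0, 5.0),
    "antihelix_left": (-70.0, -5.0, 5.0),
    "inion": (0.0, -95.0, 10.0),
}

#: interior points of surgical interest (never used in fitting), mm
HEAD_TARGETS: dict[str, tuple[float, float, float]] = {
    "frontal_lesion": (15.0, 55.0, 45.0),
    "deep_target": (0.0, 0.0, 20.0),
}

#: reference array clamped to the head fixation: three markers in a
#: triangular formation, local frame, mm
DEFAULT_REFERENCE_ARRAY = MarkerArray(
    "reference_array",
    [[0.0, 0.0, 0.0], [80.0, 0.0, 0.0], [40.0, 70.0, 0.0]],
)

#: default world placement of the reference array: beside the head clamp
DEFAULT_ARRAY_PLACEMENT = RigidTransform.from_axis_angle(
    (0.0, 0.0, 1.0), np.pi / 6.0, translation=(140.0, -90.0, 60.0)
)


def random_rigid(
    rng: np.random.Generator,
    max_translation: float = 100.0,
) -> RigidTransform:
    """Uniformly random rotation plus uniform translation in a cube (mm)."""
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions for one synthetic phantom.

    Parameters
    ----------
    subset : tuple of str
        Landmark labels to use (≥3, non-collinear); defaults to all nine
        template sites.
    true_motion : RigidTransform
        Ground-truth image→physical motion.
    fle_sigma : float
        Per-coordinate standard deviation of the fiducial localization
        error, mm.  Default 2.0 mm, a realistic figure for anatomical
        landmarks (which localize far worse than adhesive fiducials).
    seed : int
    targets : tuple of str
        Target labels from the target template.
    """

    subset: tuple = tuple(HEAD_LANDMARKS)
    true_motion: RigidTransform = field(default_factory=RigidTransform.identity)
    fle_sigma: float = 2.0
    seed: int = 0
    targets: tuple = tuple(HEAD_TARGETS)

    def __post_init__(self) -> None:
        if self.fle_sigma < 0:
            raise InvalidInputError("fle_sigma must be >= 0")
        unknown = [l for l in self.subset if l not in HEAD_LANDMARKS]
        if unknown:
            raise InvalidInputError(f"unknown landmark labels: {unknown}")
        unknown_t = [l for l in self.targets if l not in HEAD_TARGETS]
        if unknown_t:
            raise InvalidInputError(f"unknown target labels: {unknown_t}")
        object.__setattr__(self, "subset", tuple(self.subset))
        object.__setattr__(self, "targets", tuple(self.targets))


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[FiducialSet, FiducialSet, tuple[np.ndarray, np.ndarray]]:
    """Generate one noisy phantom realisation.

    Returns
    -------
    image_fids : FiducialSet
        The template subset (virtual scene landmarks).
    physical_fids : FiducialSet
        ``true_motion`` applied to the template, plus i.i.d. Gaussian FLE of
        std ``fle_sigma`` per coordinate.
    targets : (image_targets, physical_targets)
        Interior points mapped by the *noiseless* true motion.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = list(spec.subset)
    pts = np.array([HEAD_LANDMARKS[l] for l in labels], dtype=float)
    image_fids = FiducialSet(labels, pts, frame="image")
    noise = rng.normal(0.0, spec.fle_sigma, size=pts.shape) if spec.fle_sigma > 0 \
        else np.zeros_like(pts)
    physical_fids = FiducialSet(
        labels, spec.true_motion.apply(pts) + noise, frame="physical"
    )
    tgt_img = np.array([HEAD_TARGETS[l] for l in spec.targets], dtype=float)
    tgt_phys = spec.true_motion.apply(tgt_img)
    return image_fids, physical_fids, (tgt_img, tgt_phys)


def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "rms": float(np.sqrt(np.mean(np.square(values)))),
    }


@dataclass(frozen=True)
class SimulationReport:
    """Per-trial FRE/TRE samples from a Monte-Carlo study, mm."""

    n_trials: int
    fre_values: np.ndarray
    tre_values: np.ndarray
    fle_sigma: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fre = np.asarray(self.fre_values, dtype=float)
        tre = np.asarray(self.tre_values, dtype=float)
        assert len(fre) == self.n_trials and len(tre) == self.n_trials
        assert np.all(fre >= 0) and np.all(tre >= 0)
        fre.setflags(write=False)
        tre.setflags(write=False)
        object.__setattr__(self, "fre_values", fre)
        object.__setattr__(self, "tre_values", tre)

    @property
    def summary(self) -> dict:
        return {
            "fre_mm": _summary(self.fre_values),
            "tre_mm": _summary(self.tre_values),
        }

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "fle_sigma_mm": self.fle_sigma,
            "summary": self.summary,
            "fre_values_mm": self.fre_values.tolist(),
            "tre_values_mm": self.tre_values.tolist(),
            "extras": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.extras.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """Per-trial values as CSV (trial, fre_mm, tre_mm)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "fre_mm", "tre_mm"])
            for i, (f, t) in enumerate(zip(self.fre_values, self.tre_values)):
                w.writerow([i, repr(float(f)), repr(float(t))])

    def plot_fre_hist(self, ax=None):
        """Histogram of per-trial FRE values (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.fre_values, bins=40)
        ax.set_xlabel("FRE (mm)")
        ax.set_ylabel("trials")
        ax.set_title(f"FRE over {self.n_trials} trials, FLE σ={self.fle_sigma} mm")
        return ax


def run_fre_study(spec: PhantomSpec, n_trials: int) -> SimulationReport:
    """Monte-Carlo FRE/TRE study of paired registration under FLE.

    Each trial redraws the fiducial noise from its own deterministic
    substream, registers, and records the FRE plus the TRE at the held-out
    targets (RMS over targets when several are declared).
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    streams = np.random.SeedSequence(spec.seed).spawn(n_trials)
    fre = np.empty(n_trials)
    tre = np.empty(n_trials)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        image_fids, physical_fids, (tgt_img, tgt_phys) = generate_phantom(spec, rng)
        fit = register_paired(image_fids, physical_fids)
        fre[i] = fit.fre
        err = np.linalg.norm(fit.transform.apply(tgt_img) - tgt_phys, axis=1)
        tre[i] = float(np.sqrt(np.mean(err**2)))
    return SimulationReport(n_trials, fre, tre, spec.fle_sigma)


def simulate_bed_movement(
    physical_fids: FiducialSet,
    array_obs,
    motion: RigidTransform,
) -> tuple[FiducialSet, np.ndarray]:
    """Apply one rigid bed motion jointly to patient and reference array.

    The array is fixed on the head clamp, so fiducials and array markers
    move as a single rigid body; all pairwise distances are preserved.
    """
    obs = np.asarray(array_obs, dtype=float)
    moved_fids = physical_fids.transformed(motion)
    return moved_fids, motion.apply(obs)


def run_tracking_study(
    spec: PhantomSpec,
    motion: RigidTransform,
    marker_noise_sigma: float,
    n_trials: int,
) -> SimulationReport:
    """Monte-Carlo lock → bed move → relock study.

    Per trial: generate a phantom, register, lock the scene to the reference
    array, move the bed by ``motion`` (patient and array together), observe
    the array markers with i.i.d. Gaussian noise of std
    ``marker_noise_sigma`` mm, relock, and record the post-relock TRE at the
    held-out targets against the moved truth.  Pre-move TREs are kept in
    ``extras["pre_move_tre_values"]``.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    if marker_noise_sigma < 0:
        raise InvalidInputError("marker_noise_sigma must be >= 0")
    array = DEFAULT_REFERENCE_ARRAY
    obs0 = DEFAULT_ARRAY_PLACEMENT.apply(array.local_markers)
    streams = np.random.SeedSequence(spec.seed).spawn(n_trials)
    fre = np.empty(n_trials)
    tre_post = np.empty(n_trials)
    tre_pre = np.empty(n_trials)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        image_fids, physical_fids, (tgt_img, tgt_phys) = generate_phantom(spec, rng)
        fit = register_paired(image_fids, physical_fids)
        fre[i] = fit.fre
        pre = np.linalg.norm(fit.transform.apply(tgt_img) - tgt_phys, axis=1)
        tre_pre[i] = float(np.sqrt(np.mean(pre**2)))

        scene = TrackedScene(scene_to_world=fit.transform)
        lock_obs = obs0 + rng.normal(0.0, marker_noise_sigma, size=obs0.shape)
        scene = lock_scene(scene, array, lock_obs)

        _, moved_obs = simulate_bed_movement(physical_fids, obs0, motion)
        relock_obs = moved_obs + rng.normal(0.0, marker_noise_sigma, size=obs0.shape)
        scene = relock_scene(scene, array, relock_obs)

        moved_tgt_phys = motion.apply(tgt_phys)
        post = np.linalg.norm(scene.scene_to_world.apply(tgt_img) - moved_tgt_phys, axis=1)
        tre_post[i] = float(np.sqrt(np.mean(post**2)))
    return SimulationReport(
        n_trials,
        fre,
        tre_post,
        spec.fle_sigma,
        extras={
            "marker_noise_sigma_mm": marker_noise_sigma,
            "pre_move_tre_values": tre_pre.tolist(),
        },
    )
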