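import numpy as np
import pytest

from holonav import FiducialSet, RigidTransform, random_rigid
from holonav.simulation import HEAD_LANDMARKS


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def rot90z():
    """90° rotation about z."""
    return RigidTransform(np.array([[0.0, -1.0, 0.0],
                                    [1.0, 0.0, 0.0],
                                    [0.0, 0.0, 1.0]]), np.zeros(3))


@pytest.fixture
def head_image_fids():
    """The full nine-landmark template in the image frame."""
    labels = list(HEAD_LANDMARKS)
    return FiducialSet(labels, [HEAD_LANDMARKS[l] for l in labels], frame="image")


def random_fiducial_pair(rng, n, sigma=0.0):
    """A random non-collinear image set, a random true motion, and the
    physical set = motion(image) + Gaussian noise.  Returns (img, phys, motion)."""
    while True:
        pts = rng.uniform(-100, 100, size=(n, 3))
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] > 1.0:  # stay well clear of collinearity
            break
    motion = random_rigid(rng)
    labels = [f"f{i}" for i in range(n)]
    img = FiducialSet(labels, pts, frame="image")
    phys_pts = motion.apply(pts)
    if sigma > 0:
        phys_pts = phys_pts + rng.normal(0, sigma, size=pts.shape)
    phys = FiducialSet(labels, phys_pts, frame="physical")
    return img, phys, motion
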