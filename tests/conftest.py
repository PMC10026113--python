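import numpy as np
import pytest
from skimage.morphology import disk


@pytest.fixture(scope="session")
def disk50():
    """Label mask holding a single filled digital disk of radius 50."""
    mask = np.pad(disk(50), 5).astype(np.int32)
    return mask


def rectangle_mask(w: int, h: int, pad: int = 5) -> np.ndarray:
    """Label mask with one axis-aligned w x h rectangle (label 1)."""
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=np.int32)
    m[pad : pad + h, pad : pad + w] = 1
    return m


def random_blob(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A connected random blob: union of a few overlapping ellipses."""
    from myoshape.synthetic import _ellipse_mask  # noqa: PLC0415

    m = np.zeros((size, size), dtype=bool)
    r0, c0 = rng.uniform(size * 0.35, size * 0.65, 2)
    for _ in range(rng.integers(1, 4)):
        a = rng.uniform(6, size * 0.22)
        b = rng.uniform(4, a)
        theta = rng.uniform(0, np.pi)
        dr, dc = rng.uniform(-5, 5, 2)
        m |= _ellipse_mask((size, size), (r0 + dr, c0 + dc), a, b, theta)
    return m.astype(np.int32)


def sweep_feret(coords: np.ndarray, step_deg: float = 0.1):
    """Exhaustive-rotation Feret oracle on pixel corner points.

    Projects the corner points on a dense fan of directions; the calliper
    width at angle theta is the projection range.  Independent of the
    rotating-calipers implementation.
    """
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    proj = pts @ dirs.T  # (npts, nthetas)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), float(widths.max())
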