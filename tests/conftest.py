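import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_convex_polygon(rng, n_points: int = 12, stretch: float | None = None):
    """Convex polygon from the hull of random points, optionally stretched."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 2)) * 10.0
    if stretch is not None:
        pts[:, 0] *= stretch
    ang = rng.uniform(0, np.pi)
    rot = np.array(
        [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
    )
    pts = pts @ rot.T + rng.uniform(-5, 5, size=2)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def raster_aspect_ratio(vertices: np.ndarray, scale: float = 20.0) -> float:
    """Aspect ratio from dense-rasterization image moments (test oracle)."""
    from skimage.draw import polygon as draw_polygon

    v = (vertices - vertices.min(axis=0)) * scale + 2.0
    rr, cc = draw_polygon(v[:, 1], v[:, 0])
    y = rr.astype(float)
    x = cc.astype(float)
    cx, cy = x.mean(), y.mean()
    mxx = np.mean((x - cx) ** 2)
    myy = np.mean((y - cy) ** 2)
    mxy = np.mean((x - cx) * (y - cy))
    vals = np.linalg.eigvalsh(np.array([[mxx, mxy], [mxy, myy]]))
    return float(np.sqrt(vals[1] / vals[0]))
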