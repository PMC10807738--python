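"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kneequant.io import ImageData
from kneequant.phantom import PHANTOM_SUITE, PhantomParams, generate_phantom
from kneequant.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def parallel_phantom():
    """Noiseless parallel-plate phantom: gap 10 px at 0.2 mm/px everywhere."""
    return generate_phantom(PHANTOM_SUITE["parallel"])


@pytest.fixture(scope="session")
def tilted_phantom():
    return generate_phantom(PHANTOM_SUITE["tilted_femoral"])


def phantom_config(p: PhantomParams) -> RunConfig:
    """Run configuration matching a phantom's own wedge and spacing."""
    roi = p.wedge_spec(mirrored=(p.laterality == "left")).roi
    return RunConfig(pixel_spacing=p.pixel_spacing,
                     wedge_thicknesses=p.wedge_thicknesses,
                     wedge_roi=roi)


def run_phantom(p: PhantomParams, cfg: RunConfig | None = None):
    """Generate a phantom and run the full pipeline on it in memory."""
    img, ls, gt = generate_phantom(p)
    cfg = cfg or phantom_config(p)
    data = ImageData(img.astype(float), p.pixel_spacing, p.laterality, False,
                     "phantom")
    return run_pipeline(data, ls, cfg), gt


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; no pipeline code reuse)

def brute_force_point_polyline(point, poly, n_samples=20001):
    """Min distance to a densely sampled polyline (sampling-based oracle)."""
    point = np.asarray(point, float)
    best = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        t = np.linspace(0.0, 1.0, n_samples)[:, None]
        pts = a + t * (b - a)
        best = min(best, float(np.linalg.norm(pts - point, axis=1).min()))
    return best


def grid_inscribed_radius(p0, axis, upper, lower, t_lo, t_hi, step=5e-4):
    """Dense 1-D grid search for the maximal inscribed radius on an axis."""
    p0 = np.asarray(p0, float)
    n = np.asarray(axis, float)
    n = n / np.linalg.norm(n)
    ts = np.arange(t_lo, t_hi + step, step)
    centers = p0 + ts[:, None] * n

    def dist_to(poly):
        a, b = poly[:-1], poly[1:]
        d = b - a
        len2 = np.einsum("ij,ij->i", d, d)
        diff = centers[:, None, :] - a[None]
        t = np.clip(np.einsum("nij,ij->ni", diff, d) / len2, 0, 1)
        proj = a[None] + t[:, :, None] * d[None]
        return np.linalg.norm(centers[:, None, :] - proj, axis=2).min(axis=1)

    r = np.minimum(dist_to(np.asarray(upper, float)), dist_to(np.asarray(lower, float)))
    return float(r.max())


def anova_icc_a1(x1, x2):
    """ICC(A,1) from a naive cell-by-cell two-way ANOVA table."""
    x = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_convex_gap(rng, width=40.0):
    """A random convex joint-gap fixture: concave-up lower and concave-down
    upper polyline with strictly positive separation."""
    m = int(rng.integers(4, 9))
    xs = np.sort(rng.uniform(0, width, m))
    xs[0], xs[-1] = 0.0, width
    slopes_lo = np.sort(rng.uniform(-0.4, 0.4, m - 1))          # convex (up)
    slopes_up = np.sort(rng.uniform(-0.4, 0.4, m - 1))[::-1]    # concave (down)
    y_lo = np.concatenate([[0.0], np.cumsum(slopes_lo * np.diff(xs))])
    gap0 = rng.uniform(4.0, 15.0)
    y_up = y_lo[0] - gap0 + np.concatenate([[0.0], np.cumsum(slopes_up * np.diff(xs))])
    # enforce separation (y-down frame: upper polyline has smaller y)
    shift = (y_lo - y_up).min()
    if shift < 2.0:
        y_up = y_up - (2.0 - shift)
    lower = np.column_stack([xs, y_lo])
    upper = np.column_stack([xs, y_up])
    return upper, lower
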