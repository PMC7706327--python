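"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the analytic code paths they check: subdivision
instead of quadratic solving, rasterization instead of polygon clipping,
dense cumulative scanning instead of interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def subdivision_cylinder_length(start, end, cx, cy, radius, z_lo, z_hi, n=10_000) -> float:
    """Midpoint in/out test over n sub-segments of a straight segment."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = (np.arange(n) + 0.5) / n
    mids = start[None, :] + t[:, None] * (end - start)[None, :]
    r2 = (mids[:, 0] - cx) ** 2 + (mids[:, 1] - cy) ** 2
    inside = (r2 <= radius**2) & (mids[:, 2] >= z_lo) & (mids[:, 2] < z_hi)
    return float(inside.sum()) / n * float(np.linalg.norm(end - start))


def raster_voronoi_weights(expanded_points: dict, R: float, P: float, pixel: float = 0.1) -> dict:
    """Assign a 1 mm pixel grid of the unit cell to the nearest expanded point.

    ``expanded_points`` maps location_id -> (k, 2) image coordinates inside
    the cell [-R/2, R/2] x [-P/2, P/2]; distances are toroidal (points are
    tiled over the 3x3 neighborhood).
    """
    pts = []
    owner = []
    for loc, imgs in expanded_points.items():
        for p in np.atleast_2d(imgs):
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    pts.append([p[0] + ix * R, p[1] + iy * P])
                    owner.append(loc)
    tree = cKDTree(np.asarray(pts))
    xs = np.arange(-R / 2 + pixel / 2, R / 2, pixel)
    ys = np.arange(-P / 2 + pixel / 2, P / 2, pixel)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    _, idx = tree.query(grid, workers=-1)
    owner = np.asarray(owner, dtype=object)
    counts = {}
    for loc in expanded_points:
        counts[loc] = int(np.sum(owner[idx] == loc))
    total = sum(counts.values())
    return {loc: c / total for loc, c in counts.items()}


def raster_depth_quantile(bin_masses, depth_bins, p: float, resolution: float = 0.01) -> float:
    """Scan a dense rasterization of the profile's cumulative mass."""
    bin_masses = np.asarray(bin_masses, dtype=float)
    depth_bins = np.asarray(depth_bins, dtype=float)
    zs = []
    dens = []
    for k, m in enumerate(bin_masses):
        lo, hi = depth_bins[k], depth_bins[k + 1]
        n = int(round((hi - lo) / resolution))
        zs.append(np.linspace(lo, hi, n, endpoint=False) + resolution / 2)
        dens.append(np.full(n, m / n))
    z = np.concatenate(zs)
    cum = np.cumsum(np.concatenate(dens))
    target = (p / 100.0) * bin_masses.sum()
    i = int(np.searchsorted(cum, target))
    return float(z[min(i, len(z) - 1)])


def qda_score_by_formula(x, mean, cov, prior) -> float:
    """Term-by-term evaluation of the quadratic discriminant score."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    dev = x - mean
    return float(
        -0.5 * np.log(np.linalg.det(cov))
        - 0.5 * dev @ np.linalg.solve(cov, dev)
        + np.log(prior)
    )
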