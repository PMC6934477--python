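"""Shape statistics of a binary sub-lesion mask.

All quantities are in physical units derived from the voxel size. Surface
area comes from a marching-cubes mesh of the (zero-padded) mask; volume is
the voxel count times voxel volume. Elongation and flatness follow the
usual principal-component definitions sqrt(l2/l1) and sqrt(l3/l1) with
l1 >= l2 >= l3 the eigenvalues of the voxel-coordinate covariance.
Convexity is the ratio of mask volume to convex-hull volume (hull of voxel
centres); flat or collinear masks, for which a 3D hull does not exist, are
flagged degenerate.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .names import GEOMETRIC_STATS


def geometric_features(mask: np.ndarray, voxel_mm: tuple[float, float, float]) -> dict[str, float]:
    """The 8 shape statistics of a binary mask; all-NaN when degenerate."""
    mask = np.asarray(mask, dtype=bool)
    nan = {s: np.nan for s in GEOMETRIC_STATS}
    n_vox = int(mask.sum())
    if n_vox == 0:
        return nan
    voxel_mm = tuple(float(v) for v in voxel_mm)
    voxvol = voxel_mm[0] * voxel_mm[1] * voxel_mm[2]
    volume = n_vox * voxvol

    coords = np.argwhere(mask).astype(np.float64) * np.asarray(voxel_mm)

    # surface area from a marching-cubes mesh on the padded mask
    try:
        padded = np.pad(mask.astype(np.float64), 1)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=voxel_mm)
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return nan

    # maximum 3D diameter: max pairwise distance between hull vertices;
    # convexity: voxel-count ratio of the mask to its rasterized convex hull
    # (voxel centres inside or on the hull), so a solid convex mask gives 1
    try:
        hull = ConvexHull(coords)
        hull_pts = coords[hull.vertices]
        max_diam = float(pdist(hull_pts).max())
        tri = Delaunay(hull_pts)
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        grids = np.meshgrid(
            *[
                np.arange(l, h + 0.5 * v, v)
                for l, h, v in zip(lo, hi, voxel_mm)
            ],
            indexing="ij",
        )
        pts = np.stack([g.ravel() for g in grids], axis=1)
        n_hull = int((tri.find_simplex(pts) >= 0).sum())
        convexity = float(n_vox / n_hull) if n_hull else np.nan
    except (QhullError, ValueError):
        # coplanar/collinear mask: no 3D hull
        if n_vox == 1:
            max_diam = 0.0
        else:
            max_diam = float(pdist(coords).max())
        convexity = np.nan

    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    compactness = float(volume / (np.sqrt(np.pi) * area ** 1.5))

    if n_vox > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan
    else:
        elongation = np.nan
        flatness = np.nan

    return {
        "Volume": float(volume),
        "SurfaceArea": area,
        "Maximum3DDiameter": max_diam,
        "Sphericity": sphericity,
        "Compactness": compactness,
        "Convexity": convexity,
        "Elongation": elongation,
        "Flatness": flatness,
    }
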