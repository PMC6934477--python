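"""Grey-level co-occurrence matrix (GLCM) texture statistics.

Intensities are quantized to ``n_levels`` equal-width bins over the in-mask
range; co-occurrences are accumulated over the 13 unique 3D direction offsets
at distance 1 voxel, symmetrized, pooled into a single matrix and normalized
to sum to 1. Statistics follow the standard Haralick-style catalog with
grey levels indexed 1..n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .names import GLCM_STATS

#: the 13 unique direction offsets of the 26-neighbourhood
#: (lexicographically positive half; the other half is covered by symmetry)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class GLCMSpec:
    """Parameters of the co-occurrence computation."""

    n_grey_levels: int = 32
    distance_voxels: int = 1
    directions: tuple[tuple[int, int, int], ...] = field(default=DIRECTIONS_13)
    symmetric: bool = True
    normalized: bool = True


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of in-mask intensities to levels 1..n.

    Out-of-mask voxels are 0. Returns an int array of the image shape.
    A constant in-mask image maps every in-mask voxel to level 1.
    """
    q = np.zeros(image.shape, dtype=np.int32)
    vals = image[mask]
    if vals.size == 0:
        return q
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        q[mask] = 1
        return q
    lev = np.floor((image[mask] - lo) / (hi - lo) * n_levels).astype(np.int32)
    q[mask] = np.clip(lev, 0, n_levels - 1) + 1
    return q


def glcm_matrix(
    image: np.ndarray, mask: np.ndarray, spec: GLCMSpec = GLCMSpec()
) -> np.ndarray:
    """Pooled, symmetrized, normalized co-occurrence matrix (n × n).

    Raises ``ValueError`` when fewer than 2 distinct quantized levels occur
    in the mask (degenerate texture) or when no co-occurring pair exists.
    """
    mask = np.asarray(mask, dtype=bool)
    n = spec.n_grey_levels
    q = quantize(np.asarray(image, dtype=np.float64), mask, n)
    if np.unique(q[mask]).size < 2:
        raise ValueError("degenerate region: fewer than 2 quantized grey levels")
    d = spec.distance_voxels
    counts = np.zeros(n * n, dtype=np.int64)
    for dx, dy, dz in spec.directions:
        sl_a, sl_b = [], []
        for delta, size in zip((dx * d, dy * d, dz * d), q.shape):
            if delta >= 0:
                sl_a.append(slice(0, size - delta))
                sl_b.append(slice(delta, size))
            else:
                sl_a.append(slice(-delta, size))
                sl_b.append(slice(0, size + delta))
        a = q[tuple(sl_a)]
        b = q[tuple(sl_b)]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pair = (a[valid] - 1) * n + (b[valid] - 1)
        counts += np.bincount(pair, minlength=n * n)
    mat = counts.reshape(n, n).astype(np.float64)
    if spec.symmetric:
        mat = mat + mat.T
    total = mat.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs in mask")
    if spec.normalized:
        mat /= total
    return mat


from functools import lru_cache


@lru_cache(maxsize=8)
def _level_grids(n: int):
    i = np.arange(1, n + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    diff = I - J
    absdiff = np.abs(diff)
    return i, I, J, diff, absdiff, (I + J).astype(np.int64).ravel(), absdiff.astype(np.int64).ravel()


def glcm_statistics_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The 24-statistic catalog from a normalized co-occurrence matrix."""
    n = P.shape[0]
    i, I, J, diff, absdiff, ksum_flat, kdiff_flat = _level_grids(n)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    nz = P > 0
    joint_entropy = float(-(P[nz] * np.log2(P[nz])).sum())

    # p_{x+y}(k), k = 2..2n and p_{x-y}(k), k = 0..n-1
    p_sum = np.bincount(ksum_flat, weights=P.ravel(), minlength=2 * n + 1)[2:]
    p_diff = np.bincount(kdiff_flat, weights=P.ravel(), minlength=n)
    ks = np.arange(2, 2 * n + 1, dtype=np.float64)
    kd = np.arange(0, n, dtype=np.float64)
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nzs = p_sum > 0
    sum_ent = float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum())
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    nzd = p_diff > 0
    diff_ent = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())

    if var_x > 0 and var_y > 0:
        correlation = float(((I * J * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0

    # information measures of correlation
    nx = px > 0
    ny = py > 0
    hx = float(-(px[nx] * np.log2(px[nx])).sum())
    hy = float(-(py[ny] * np.log2(py[ny])).sum())
    pxy = np.outer(px, py)
    nzo = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[nzo] * np.log2(pxy[nzo])).sum())
    nzp = pxy > 0
    hxy2 = float(-(pxy[nzp] * np.log2(pxy[nzp])).sum())
    imc1 = (joint_entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    cplus = I + J - mu_x - mu_y
    return {
        "MaximumProbability": float(P.max()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": joint_entropy,
        "Contrast": float((diff**2 * P).sum()),
        "Dissimilarity": float((absdiff * P).sum()),
        "InverseDifferenceMoment": float((P / (1.0 + diff**2)).sum()),
        "InverseDifference": float((P / (1.0 + absdiff)).sum()),
        "Correlation": correlation,
        "Autocorrelation": float((I * J * P).sum()),
        "ClusterShade": float((cplus**3 * P).sum()),
        "ClusterProminence": float((cplus**4 * P).sum()),
        "ClusterTendency": float((cplus**2 * P).sum()),
        "JointAverage": mu_x,
        "JointVariance": float(((I - mu_x) ** 2 * P).sum()),
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": sum_ent,
        "DifferenceAverage": diff_avg,
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": diff_ent,
        "IMC1": float(imc1),
        "IMC2": imc2,
        "IDMN": float((P / (1.0 + (diff / n) ** 2)).sum()),
        "IDN": float((P / (1.0 + absdiff / n)).sum()),
    }


def glcm_features(
    image: np.ndarray, mask: np.ndarray, spec: GLCMSpec = GLCMSpec()
) -> dict[str, float]:
    """GLCM statistics of an image within a mask; NaN-valued on degenerate input."""
    try:
        P = glcm_matrix(image, mask, spec)
    except ValueError:
        return {s: np.nan for s in GLCM_STATS}
    return glcm_statistics_from_matrix(P)


def region_pair_indices(
    mask: np.ndarray, spec: GLCMSpec = GLCMSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed co-occurrence geometry of one mask.

    Returns ``(voxel_idx, ra, rb)``: the flat indices of the in-mask voxels
    and, pooled over all direction offsets, the index pairs *into that
    voxel list* of every co-occurring pair. Because the pair geometry is a
    property of the mask alone, it can be reused across every image/filter
    combination, which is what makes whole-cohort extraction cheap.
    """
    mask = np.asarray(mask, dtype=bool)
    voxel_idx = np.flatnonzero(mask.ravel())
    pos = np.full(mask.size, -1, dtype=np.int64)
    pos[voxel_idx] = np.arange(voxel_idx.size)
    flat = np.arange(mask.size).reshape(mask.shape)
    d = spec.distance_voxels
    ras, rbs = [], []
    for dx, dy, dz in spec.directions:
        sl_a, sl_b = [], []
        for delta, size in zip((dx * d, dy * d, dz * d), mask.shape):
            if delta >= 0:
                sl_a.append(slice(0, size - delta))
                sl_b.append(slice(delta, size))
            else:
                sl_a.append(slice(-delta, size))
                sl_b.append(slice(0, size + delta))
        ma = mask[tuple(sl_a)]
        mb = mask[tuple(sl_b)]
        valid = ma & mb
        ras.append(pos[flat[tuple(sl_a)][valid]])
        rbs.append(pos[flat[tuple(sl_b)][valid]])
    ra = np.concatenate(ras).astype(np.int32) if ras else np.empty(0, dtype=np.int32)
    rb = np.concatenate(rbs).astype(np.int32) if rbs else np.empty(0, dtype=np.int32)
    return voxel_idx, ra, rb


def quantize_values(values: np.ndarray, n_levels: int) -> np.ndarray | None:
    """Equal-width quantization of a value vector to 0..n-1; None if degenerate."""
    lo = values.min()
    hi = values.max()
    if hi == lo:
        return None
    lev = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(lev, 0, n_levels - 1)


def glcm_features_from_pairs(
    values: np.ndarray,
    ra: np.ndarray,
    rb: np.ndarray,
    n_levels: int = 32,
) -> dict[str, float]:
    """GLCM statistics from in-mask values and precomputed pair indices.

    Equivalent to :func:`glcm_features` with the symmetric pooled 13-direction
    spec (asserted by tests), but reusing the mask geometry.
    """
    if ra.size == 0:
        return {s: np.nan for s in GLCM_STATS}
    codes = quantize_values(np.asarray(values, dtype=np.float64), n_levels)
    if codes is None:
        return {s: np.nan for s in GLCM_STATS}
    counts = np.bincount(codes[ra] * n_levels + codes[rb], minlength=n_levels**2)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    mat = mat + mat.T
    mat /= mat.sum()
    return glcm_statistics_from_matrix(mat)


def glcm_features_from_pairs_multi(
    V: np.ndarray,
    ra: np.ndarray,
    rb: np.ndarray,
    n_levels: int = 32,
) -> dict[str, np.ndarray]:
    """Column-wise GLCM statistics for an (n_voxels, n_filters) value matrix.

    Identical, column by column, to :func:`glcm_features_from_pairs`;
    degenerate columns (constant values or no pairs) yield NaN.
    """
    V = np.asarray(V)
    m = V.shape[1]
    out = {s: np.full(m, np.nan) for s in GLCM_STATS}
    if ra.size == 0 or V.shape[0] == 0:
        return out
    n = n_levels
    lo = V.min(axis=0)
    hi = V.max(axis=0)
    live = np.flatnonzero(hi > lo)
    if live.size == 0:
        return out
    Vl = V[:, live]
    codes = np.floor(
        (Vl - lo[live]) / (hi[live] - lo[live]) * n
    ).astype(np.int32)
    np.clip(codes, 0, n - 1, out=codes)
    if _pair_counts_jit is not None:
        counts = _pair_counts_jit(np.ascontiguousarray(codes), ra, rb, n)
    else:
        A = codes[ra]
        B = codes[rb]
        combined = A * n + B + (np.arange(live.size, dtype=np.int32) * n * n)
        counts = np.bincount(combined.ravel(), minlength=live.size * n * n)
        counts = counts.reshape(live.size, n, n)
    P = counts.astype(np.float64)
    P = P + P.transpose(0, 2, 1)
    P /= P.sum(axis=(1, 2), keepdims=True)
    stats = glcm_statistics_tensor(P)
    for s in GLCM_STATS:
        out[s][live] = stats[s]
    return out


try:  # fused pair counting; the numpy bincount path is the fallback
    import numba as _numba

    @_numba.njit(cache=False)
    def _pair_counts_numba(codes, ra, rb, n):  # pragma: no cover - jitted
        m = codes.shape[1]
        out = np.zeros((m, n, n), dtype=np.int64)
        for t in range(ra.shape[0]):
            i = ra[t]
            j = rb[t]
            for k in range(m):
                out[k, codes[i, k], codes[j, k]] += 1
        return out

    _pair_counts_jit = _pair_counts_numba
except ImportError:  # pragma: no cover
    _pair_counts_jit = None


@lru_cache(maxsize=8)
def _sum_diff_maps(n: int):
    _, I, J, _, absdiff, _, _ = _level_grids(n)
    ksum = (I + J).astype(np.int64).ravel() - 2          # 0 .. 2n-2
    kdiff = absdiff.astype(np.int64).ravel()             # 0 .. n-1
    S_sum = np.zeros((n * n, 2 * n - 1))
    S_sum[np.arange(n * n), ksum] = 1.0
    S_diff = np.zeros((n * n, n))
    S_diff[np.arange(n * n), kdiff] = 1.0
    return S_sum, S_diff


def _entropy2(p: np.ndarray, axis) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=axis)


def glcm_statistics_tensor(P: np.ndarray) -> dict[str, np.ndarray]:
    """The 24-statistic catalog for a stack of normalized matrices (m, n, n)."""
    m, n, _ = P.shape
    i, I, J, diff, absdiff, _, _ = _level_grids(n)
    S_sum, S_diff = _sum_diff_maps(n)
    px = P.sum(axis=2)
    py = P.sum(axis=1)
    mu_x = px @ i
    mu_y = py @ i
    var_x = ((i[None, :] - mu_x[:, None]) ** 2 * px).sum(axis=1)
    var_y = ((i[None, :] - mu_y[:, None]) ** 2 * py).sum(axis=1)
    joint_entropy = _entropy2(P, axis=(1, 2))

    Pf = P.reshape(m, n * n)
    p_sum = Pf @ S_sum
    p_diff = Pf @ S_diff
    ks = np.arange(2, 2 * n + 1, dtype=np.float64)
    kd = np.arange(0, n, dtype=np.float64)
    sum_avg = p_sum @ ks
    sum_var = ((ks[None, :] - sum_avg[:, None]) ** 2 * p_sum).sum(axis=1)
    sum_ent = _entropy2(p_sum, axis=1)
    diff_avg = p_diff @ kd
    diff_var = ((kd[None, :] - diff_avg[:, None]) ** 2 * p_diff).sum(axis=1)
    diff_ent = _entropy2(p_diff, axis=1)

    cross = (P * (I * J)[None]).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        correlation = np.where(
            (var_x > 0) & (var_y > 0),
            (cross - mu_x * mu_y) / np.sqrt(var_x * var_y),
            1.0,
        )

    hx = _entropy2(px, axis=1)
    hy = _entropy2(py, axis=1)
    pxy = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logpxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = -(np.where(pxy > 0, P, 0.0) * logpxy).sum(axis=(1, 2))
    hxy2 = -(pxy * logpxy).sum(axis=(1, 2))
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > 0, (joint_entropy - hxy1) / np.where(hmax > 0, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))

    c = (I + J)[None] - (mu_x + mu_y)[:, None, None]
    return {
        "MaximumProbability": P.max(axis=(1, 2)),
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": joint_entropy,
        "Contrast": (P * (diff**2)[None]).sum(axis=(1, 2)),
        "Dissimilarity": (P * absdiff[None]).sum(axis=(1, 2)),
        "InverseDifferenceMoment": (P / (1.0 + diff**2)[None]).sum(axis=(1, 2)),
        "InverseDifference": (P / (1.0 + absdiff)[None]).sum(axis=(1, 2)),
        "Correlation": correlation,
        "Autocorrelation": cross,
        "ClusterShade": (c**3 * P).sum(axis=(1, 2)),
        "ClusterProminence": (c**4 * P).sum(axis=(1, 2)),
        "ClusterTendency": (c**2 * P).sum(axis=(1, 2)),
        "JointAverage": mu_x,
        "JointVariance": (((I[None] - mu_x[:, None, None]) ** 2) * P).sum(axis=(1, 2)),
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": sum_ent,
        "DifferenceAverage": diff_avg,
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": diff_ent,
        "IMC1": imc1,
        "IMC2": imc2,
        "IDMN": (P / (1.0 + (diff / n) ** 2)[None]).sum(axis=(1, 2)),
        "IDN": (P / (1.0 + absdiff / n)[None]).sum(axis=(1, 2)),
    }
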