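"""First-order (histogram) statistics of in-mask intensities."""

from __future__ import annotations

import numpy as np

from .names import HISTOGRAM_STATS

_N_ENTROPY_BINS = 32


def histogram_statistics_matrix(V: np.ndarray) -> dict[str, np.ndarray]:
    """Column-wise first-order statistics of an (n_voxels, n_filters) matrix.

    Identical, column by column, to :func:`histogram_statistics` for
    float64 input; the vectorized form exists because whole-cohort
    extraction evaluates the same region under nine filtered images (and
    feeds float32 there, trading the last few digits for speed).
    """
    V = np.asarray(V)
    N, m = V.shape
    if N == 0:
        return {s: np.full(m, np.nan) for s in HISTOGRAM_STATS}
    srt = np.sort(V, axis=0)

    def pct(q: float) -> np.ndarray:
        pos = q / 100.0 * (N - 1)
        lo = int(pos)
        hi = min(lo + 1, N - 1)
        frac = pos - lo
        return srt[lo] + (srt[hi] - srt[lo]) * frac

    mean = V.mean(axis=0)
    vmin, vmax = srt[0], srt[-1]
    var = V.var(axis=0)
    std = np.sqrt(var)
    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    rng_ = vmax - vmin
    centred = V - mean
    live_z = (rng_ > 0) & (std > 0)
    safe = np.where(std > 0, std, 1.0)
    z = centred / safe
    skew = np.where(live_z, (z**3).mean(axis=0), 0.0)
    kurt = np.where(live_z, (z**4).mean(axis=0), 0.0)
    entropy = np.zeros(m)
    live = rng_ > 0
    if live.any():
        Vl = V[:, live]
        idx = np.minimum(
            ((Vl - vmin[live]) * (_N_ENTROPY_BINS / rng_[live])).astype(np.int64),
            _N_ENTROPY_BINS - 1,
        )
        idx += np.arange(live.sum()) * _N_ENTROPY_BINS
        counts = np.bincount(
            idx.ravel(), minlength=int(live.sum()) * _N_ENTROPY_BINS
        ).reshape(-1, _N_ENTROPY_BINS)
        p = counts / N
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
        entropy[live] = h

    robust = (V >= p10) & (V <= p90)
    n_rob = robust.sum(axis=0)
    n_rob_safe = np.where(n_rob > 0, n_rob, 1)
    mu_rob = np.where(robust, V, 0.0).sum(axis=0) / n_rob_safe
    rmad = np.where(robust, np.abs(V - mu_rob), 0.0).sum(axis=0) / n_rob_safe

    return {
        "Mean": mean,
        "Median": pct(50),
        "Minimum": vmin,
        "Maximum": vmax,
        "Range": rng_,
        "Variance": var,
        "StandardDeviation": std,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": (V**2).sum(axis=0),
        "Entropy": entropy,
        "MeanAbsoluteDeviation": np.abs(centred).mean(axis=0),
        "RobustMeanAbsoluteDeviation": rmad,
        "Percentile10": p10,
        "Percentile90": p90,
        "InterquartileRange": p75 - p25,
    }


def histogram_statistics(values: np.ndarray) -> dict[str, float]:
    """The 16 first-order statistics of a 1-D array of in-mask intensities.

    Skewness and kurtosis use the biased moment estimators (kurtosis is the
    plain fourth standardized moment, 3 for a Gaussian). Entropy is the
    Shannon entropy (bits) of a 32-bin equal-width histogram over the value
    range; a constant sample has entropy 0. Energy is the sum of squared
    intensities. Degenerate inputs (empty) yield all-NaN.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        return {s: np.nan for s in HISTOGRAM_STATS}
    srt = np.sort(values)

    def _pct(q: float) -> float:
        # linear-interpolation quantile on the pre-sorted sample
        # (identical to numpy's default percentile method)
        pos = q / 100.0 * (srt.size - 1)
        lo = int(pos)
        hi = min(lo + 1, srt.size - 1)
        frac = pos - lo
        return float(srt[lo] + (srt[hi] - srt[lo]) * frac)

    mean = float(values.mean())
    vmin = float(srt[0])
    vmax = float(srt[-1])
    var = float(values.var())
    std = float(np.sqrt(var))
    median = _pct(50)
    p10, p25, p75, p90 = _pct(10), _pct(25), _pct(75), _pct(90)
    if vmax > vmin and std > 0:
        z = (values - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = 0.0
        kurt = 0.0
    if vmax > vmin:
        idx = np.minimum(
            ((values - vmin) * (_N_ENTROPY_BINS / (vmax - vmin))).astype(np.int64),
            _N_ENTROPY_BINS - 1,
        )
        counts = np.bincount(idx, minlength=_N_ENTROPY_BINS)
        p = counts[counts > 0] / values.size
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    robust = values[(values >= p10) & (values <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return {
        "Mean": mean,
        "Median": median,
        "Minimum": vmin,
        "Maximum": vmax,
        "Range": vmax - vmin,
        "Variance": var,
        "StandardDeviation": std,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(values**2)),
        "Entropy": entropy,
        "MeanAbsoluteDeviation": float(np.abs(values - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "Percentile10": p10,
        "Percentile90": p90,
        "InterquartileRange": p75 - p25,
    }
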