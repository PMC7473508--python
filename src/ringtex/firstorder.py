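"""First-order statistical features of a quantized ROI.

Six scalars: mean, sample standard deviation, histogram entropy (bits),
Pearson (non-excess) kurtosis, skewness, and lag-1 spatial autocorrelation.

Conventions, since several of these admit more than one definition:

* std uses the sample (n-1) denominator;
* skewness = m3 / m2^1.5 and kurtosis = m4 / m2^2 from population central
  moments, so a Gaussian patch gives kurtosis ~ 3;
* entropy is Shannon entropy in bits of the L-bin level histogram;
* "correlation" is the Pearson correlation over adjacent pixel pairs
  (horizontal by default), i.e. lag-1 spatial autocorrelation;
* a constant patch gives skewness 0, kurtosis 0, correlation 0.
"""

from __future__ import annotations

import numpy as np

from .io_roi import QuantizedPatch

FIRSTORDER_NAMES = ("Mean", "Std", "Entropy", "Kurtosis", "Skewness", "Correlation")


def shannon_entropy_bits(p: np.ndarray) -> float:
    """-sum p log2 p with the 0*log0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def neighbor_correlation(levels: np.ndarray, direction: str = "horizontal") -> float:
    """Pearson correlation of adjacent pixel pairs; 0 when degenerate."""
    a = np.asarray(levels, dtype=float)
    if direction == "horizontal":
        x, y = a[:, :-1].ravel(), a[:, 1:].ravel()
    elif direction == "vertical":
        x, y = a[:-1, :].ravel(), a[1:, :].ravel()
    else:
        raise ValueError(f"unknown direction: {direction!r}")
    if x.size < 2:
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def first_order_features(patch: QuantizedPatch,
                         correlation_direction: str = "horizontal") -> dict[str, float]:
    """Compute the six first-order features of a patch.

    Returns a name -> value mapping using the canonical feature names.
    """
    x = patch.levels.astype(float)
    if x.size == 0:
        raise ValueError("empty patch")
    mean = float(x.mean())
    std = float(x.std(ddof=1)) if x.size > 1 else 0.0

    counts = np.bincount(patch.levels.ravel(), minlength=patch.L)
    entropy = shannon_entropy_bits(counts / counts.sum())

    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 > 0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2
    else:
        skew = 0.0
        kurt = 0.0

    corr = neighbor_correlation(x, correlation_direction)
    return {
        "Mean": mean,
        "Std": std,
        "Entropy": entropy,
        "Kurtosis": kurt,
        "Skewness": skew,
        "Correlation": corr,
    }
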