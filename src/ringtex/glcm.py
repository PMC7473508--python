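"""Gray-level co-occurrence matrices and the 22 Haralick-style features.

A GLCM counts ordered pixel pairs separated by a fixed offset.  Four
directions are used at distance 1 — 0°, 45°, 90° and 135° — with row/col
offsets (0,1), (-1,1), (-1,0), (-1,-1) in image coordinates (row increases
downward, so 45° points up-and-right).  The symmetric form adds the
transpose, which makes 0° and 180° equivalent.

Feature formulas follow the classical Haralick / Soh / Clausi definitions.
Gray levels enter the weighted sums as 1-based indices 1..L; logarithms are
base 2 with 0*log0 = 0.  Kurtosis and skewness — unusual members of a GLCM
set — are computed on the gray-level marginal distribution p_x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_roi import QuantizedPatch
from .firstorder import shannon_entropy_bits

#: direction name -> (row offset, col offset) at distance 1
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

GLCM_NAMES = (
    "Entropy", "Kurtosis", "Skewness", "Correlation", "Contrast", "Variance",
    "SumAverage", "SumVariance", "SumEntropy", "DifferenceVariance",
    "DifferenceEntropy", "IMC1", "IMC2", "Autocorrelation", "Dissimilarity",
    "Homogeneity", "ClusterProminence", "ClusterShade", "MaximumProbability",
    "InverseDifference", "InverseDifferenceNormalized",
    "InverseDifferenceMomentNormalized",
)


class DegenerateInputError(ValueError):
    """Raised when a patch admits no pixel pair at the requested offset."""


@dataclass
class GLCMatrix:
    """Pair counts and derived probability distributions for one offset."""

    counts: np.ndarray          # L x L, integer pair counts
    L: int
    direction: int
    distance: int = 1
    symmetric: bool = True

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        return p.sum(axis=1), p.sum(axis=0)

    def sum_distribution(self) -> np.ndarray:
        """p_{x+y}(k) for k = 2..2L on 1-based indices; returned as length 2L-1."""
        p = self.p
        out = np.zeros(2 * self.L - 1)
        i, j = np.indices(p.shape)
        np.add.at(out, (i + j).ravel(), p.ravel())
        return out

    def diff_distribution(self) -> np.ndarray:
        """p_{x-y}(k) for k = 0..L-1."""
        p = self.p
        out = np.zeros(self.L)
        i, j = np.indices(p.shape)
        np.add.at(out, np.abs(i - j).ravel(), p.ravel())
        return out


def compute_glcm(patch: QuantizedPatch, direction: int, distance: int = 1,
                 symmetric: bool = True) -> GLCMatrix:
    """Count all ordered pixel pairs at the given offset.

    Raises :class:`DegenerateInputError` if the patch contains no pair at
    that offset (e.g. a 1x1 patch).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    dr, dc = DIRECTIONS[direction]
    dr, dc = dr * distance, dc * distance
    a = patch.levels
    h, w = a.shape

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = a[r0:r1, c0:c1]
    dst = a[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if src.size == 0:
        raise DegenerateInputError(
            f"no pixel pair at offset ({dr},{dc}) in a {h}x{w} patch"
        )
    counts = np.zeros((patch.L, patch.L), dtype=np.int64)
    np.add.at(counts, (src.ravel(), dst.ravel()), 1)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts=counts, L=patch.L, direction=direction,
                     distance=distance, symmetric=symmetric)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 22 scalar features of one normalized GLCM.

    Sums run over the nonzero cells only — for a 10x10 ROI at L=256 the
    matrix has at most ~180 of 65k cells occupied, and every weighted sum
    below is unchanged by dropping the zero cells.
    """
    L = m.L
    total = m.counts.sum()
    ii, jj = np.nonzero(m.counts)
    pv = m.counts[ii, jj] / total      # probabilities of occupied cells
    I = ii + 1.0                       # 1-based gray-level indices
    J = jj + 1.0

    px = np.bincount(ii, weights=pv, minlength=L)
    py = np.bincount(jj, weights=pv, minlength=L)
    lev = np.arange(1, L + 1, dtype=float)

    mu_x = float(np.sum(lev * px))
    mu_y = float(np.sum(lev * py))
    var_x = float(np.sum((lev - mu_x) ** 2 * px))
    var_y = float(np.sum((lev - mu_y) ** 2 * py))

    entropy = shannon_entropy_bits(pv)

    # marginal shape statistics (p_x), zero-variance convention -> 0
    if var_x > 0:
        m3 = float(np.sum((lev - mu_x) ** 3 * px))
        m4 = float(np.sum((lev - mu_x) ** 4 * px))
        skewness = m3 / var_x**1.5
        kurtosis = m4 / var_x**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    autocorr = float(np.sum(I * J * pv))
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0

    diff = I - J
    adiff = np.abs(diff)
    contrast = float(np.sum(diff**2 * pv))
    dissimilarity = float(np.sum(adiff * pv))
    homogeneity = float(np.sum(pv / (1.0 + diff**2)))
    inv_diff = float(np.sum(pv / (1.0 + adiff)))
    idn = float(np.sum(pv / (1.0 + adiff / L)))
    idmn = float(np.sum(pv / (1.0 + diff**2 / L**2)))
    variance = float(np.sum((I - mu_x) ** 2 * pv))
    cluster = I + J - mu_x - mu_y
    cluster_shade = float(np.sum(cluster**3 * pv))
    cluster_prom = float(np.sum(cluster**4 * pv))
    max_prob = float(pv.max())

    # p_{x+y}(k), k = 2..2L held at index k-2
    p_sum = np.bincount(ii + jj, weights=pv, minlength=2 * L - 1)
    ks = np.arange(2, 2 * L + 1, dtype=float)
    sum_avg = float(np.sum(ks * p_sum))
    sum_var = float(np.sum((ks - sum_avg) ** 2 * p_sum))
    sum_ent = shannon_entropy_bits(p_sum)

    # p_{x-y}(k), k = 0..L-1
    p_diff = np.bincount(np.abs(ii - jj), weights=pv, minlength=L)
    kd = np.arange(L, dtype=float)
    mu_d = float(np.sum(kd * p_diff))
    diff_var = float(np.sum((kd - mu_d) ** 2 * p_diff))
    diff_ent = shannon_entropy_bits(p_diff)

    # information measures of correlation
    hx = shannon_entropy_bits(px)
    hy = shannon_entropy_bits(py)
    hxy1 = float(-np.sum(pv * np.log2(px[ii] * py[jj])))
    pxnz, pynz = px[px > 0], py[py > 0]
    outer = np.outer(pxnz, pynz)
    hxy2 = float(-np.sum(outer * np.log2(outer)))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, 1.0)))

    return {
        "Entropy": entropy,
        "Kurtosis": kurtosis,
        "Skewness": skewness,
        "Correlation": correlation,
        "Contrast": contrast,
        "Variance": variance,
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": sum_ent,
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": diff_ent,
        "IMC1": imc1,
        "IMC2": imc2,
        "Autocorrelation": autocorr,
        "Dissimilarity": dissimilarity,
        "Homogeneity": homogeneity,
        "ClusterProminence": cluster_prom,
        "ClusterShade": cluster_shade,
        "MaximumProbability": max_prob,
        "InverseDifference": inv_diff,
        "InverseDifferenceNormalized": idn,
        "InverseDifferenceMomentNormalized": idmn,
    }


def glcm_directional_average(patch: QuantizedPatch, distance: int = 1,
                             symmetric: bool = True) -> dict[str, float]:
    """Features per direction, arithmetically averaged over the four directions."""
    per_dir = [
        glcm_features(compute_glcm(patch, d, distance=distance, symmetric=symmetric))
        for d in DIRECTIONS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}
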