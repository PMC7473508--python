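"""Two-level 2-D wavelet energy features and a wavelet entropy.

Each ROI is decomposed with three wavelet families (haar, sym4, bior3.3)
to two levels using the separable DWT with symmetric boundary extension.
For each family the features are percentage sub-band energies: Ea (final
approximation), Eh/Ev/Ed at levels 1 and 2, and E_soma (the per-level sum
of the three detail energies).  Percentages are relative to the total
coefficient energy of that family's pyramid and sum to 100 by
construction; for the orthogonal families (haar, sym4) the coefficient
total also equals the pixel-domain energy, for bior3.3 it does not.

EntropyWv is a single scalar: the Shannon entropy (bits) of the
normalized squared coefficients of the haar level-2 pyramid,
q_i = s_i^2 / sum(s^2).  An unnormalized variant
(-sum s^2 log2 s^2) is available via ``style="unnormalized"``.

Canonical set: EntropyWv + 3 families x 9 energies = 28 features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from .io_roi import QuantizedPatch

WAVELET_FAMILIES = ("haar", "sym4", "bior3.3")


def decompose2d(patch: QuantizedPatch | np.ndarray, family: str,
                levels: int = 2) -> list:
    """Separable 2-D DWT pyramid: [cA_n, (cH_n,cV_n,cD_n), ..., (cH_1,cV_1,cD_1)]."""
    if family not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet family: {family!r}")
    x = patch.levels if isinstance(patch, QuantizedPatch) else np.asarray(patch)
    x = x.astype(float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("patch must be at least 2x2")
    with warnings.catch_warnings():
        # long filters (sym4, bior3.3) on a 10x10 patch run entirely in the
        # boundary-extended regime; that is the intended use here
        warnings.filterwarnings("ignore", message="Level value .* too high")
        return pywt.wavedec2(x, family, mode="symmetric", level=levels)


def _band_energies(pyramid: list) -> dict[str, float]:
    """Raw (unnormalized) energy of each band; keys a, h1, v1, d1, h2, v2, d2."""
    n_detail = len(pyramid) - 1
    out = {"a": float(np.sum(np.asarray(pyramid[0]) ** 2))}
    for i, (ch, cv, cd) in enumerate(pyramid[1:]):
        level = n_detail - i  # pywt lists coarsest detail first
        out[f"h{level}"] = float(np.sum(np.asarray(ch) ** 2))
        out[f"v{level}"] = float(np.sum(np.asarray(cv) ** 2))
        out[f"d{level}"] = float(np.sum(np.asarray(cd) ** 2))
    return out


def wavelet_energy_features(pyramid: list, family: str) -> dict[str, float]:
    """Percentage sub-band energies of one family's 2-level pyramid."""
    raw = _band_energies(pyramid)
    total = sum(raw.values())
    if total == 0:
        pct = {k: 0.0 for k in raw}
        pct["a"] = 100.0  # all-zero patch convention
    else:
        pct = {k: 100.0 * v / total for k, v in raw.items()}
    feats = {f"Ea_{family}": pct["a"]}
    for level in (1, 2):
        eh, ev, ed = pct[f"h{level}"], pct[f"v{level}"], pct[f"d{level}"]
        feats[f"Eh_{family}_{level}"] = eh
        feats[f"Ev_{family}_{level}"] = ev
        feats[f"Ed_{family}_{level}"] = ed
        feats[f"E_soma_{family}_{level}"] = eh + ev + ed
    return feats


def wavelet_entropy(patch: QuantizedPatch | np.ndarray,
                    style: str = "normalized") -> float:
    """Shannon energy entropy of the haar level-2 coefficient set (EntropyWv)."""
    pyramid = decompose2d(patch, "haar", levels=2)
    coeffs = [np.asarray(pyramid[0]).ravel()]
    for bands in pyramid[1:]:
        coeffs.extend(np.asarray(b).ravel() for b in bands)
    s2 = np.concatenate(coeffs) ** 2
    total = s2.sum()
    if total == 0:
        return 0.0
    if style == "normalized":
        q = s2 / total
        nz = q[q > 0]
        return float(-np.sum(nz * np.log2(nz)))
    if style == "unnormalized":
        nz = s2[s2 > 0]
        return float(-np.sum(nz * np.log2(nz)))
    raise ValueError(f"unknown wentropy style: {style!r}")


def wavelet_features(patch: QuantizedPatch,
                     wentropy_style: str = "normalized") -> dict[str, float]:
    """The 28 canonical wavelet features (EntropyWv + 9 per family)."""
    feats: dict[str, float] = {"EntropyWv": wavelet_entropy(patch, wentropy_style)}
    for family in WAVELET_FAMILIES:
        feats.update(wavelet_energy_features(decompose2d(patch, family), family))
    return feats


WAVELET_NAMES = tuple(
    ["EntropyWv"]
    + [
        name
        for family in WAVELET_FAMILIES
        for name in (
            [f"Ea_{family}"]
            + [f"{b}_{family}_{lv}" for lv in (1, 2) for b in ("Eh", "Ev", "Ed", "E_soma")]
        )
    ]
)
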