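"""Synthetic ring-enhancing-lesion phantoms with ROI manifests.

The generator emulates the statistical structure that the texture
pipeline assumes in real contrast MRI of ring-enhancing lesions: a bright
annulus (the enhancing ring) around a darker core whose *texture*, not
its mean brightness, differs between the two diagnostic classes
(inflammatory vs tumoral).  Class contrast is carried by the core's
correlated random field — a Gaussian white-noise field smoothed with a
Gaussian kernel of class-specific correlation length and rescaled to a
class-specific standard deviation — plus additive acquisition noise
(Gaussian by default, Rician optionally).

The ``separation`` knob in [0, 1] linearly scales the between-class
difference of the core parameters around their midpoint: at 0 the two
class-conditional generating distributions are identical (a null cohort),
at 1 they take the configured values.

Images are written as 16-bit grayscale PNG so that downstream 16-bit to
8-bit rescaling is exercised; the manifest is a TSV with 0-based ROI
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy.ndimage import gaussian_filter

CLASSES = ("inflammatory", "tumor")

MANIFEST_COLUMNS = ("lesion_id", "label", "image", "roi_x", "roi_y", "roi_size")


class InvalidSpecError(ValueError):
    pass


class ROIPlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a two-class phantom cohort.

    Intensities are on an arbitrary scanner-like scale that fits
    comfortably in 16 bits after noise.
    """

    image_size: tuple[int, int] = (240, 240)
    background_mean: float = 60.0
    background_sd: float = 8.0
    ring_radius_range: tuple[float, float] = (25.0, 45.0)
    ring_width: float = 5.0
    ring_contrast: float = 160.0
    core_mean: float = 120.0
    core_corr_length_by_class: dict[str, float] = field(
        default_factory=lambda: {"inflammatory": 8.0, "tumor": 2.0})
    core_sd_by_class: dict[str, float] = field(
        default_factory=lambda: {"inflammatory": 12.0, "tumor": 20.0})
    separation: float = 1.0
    noise_sd: float = 3.0
    noise_model: str = "gaussian"  # or "rician"
    n_per_class: tuple[int, int] = (30, 37)  # (inflammatory, tumor)
    rois_per_lesion_range: tuple[int, int] = (1, 5)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.ring_radius_range[1] + self.ring_width / 2 > min(h, w) / 2:
            raise InvalidSpecError(
                "ring radius + half width exceeds half the image size")
        if not 0.0 <= self.separation <= 1.0:
            raise InvalidSpecError("separation must be in [0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise InvalidSpecError(f"unknown noise model {self.noise_model!r}")
        lo, hi = self.rois_per_lesion_range
        if not 1 <= lo <= hi:
            raise InvalidSpecError("rois_per_lesion_range must satisfy 1 <= lo <= hi")

    def class_core_params(self, class_label: str) -> tuple[float, float]:
        """(correlation length, sd) after applying the separation knob."""
        if class_label not in CLASSES:
            raise InvalidSpecError(f"unknown class {class_label!r}")
        cl = self.core_corr_length_by_class
        sd = self.core_sd_by_class
        cl_mid = (cl[CLASSES[0]] + cl[CLASSES[1]]) / 2.0
        sd_mid = (sd[CLASSES[0]] + sd[CLASSES[1]]) / 2.0
        eff_cl = cl_mid + self.separation * (cl[class_label] - cl_mid)
        eff_sd = sd_mid + self.separation * (sd[class_label] - sd_mid)
        return eff_cl, eff_sd


def correlated_field(shape: tuple[int, int], corr_length: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian field: white noise smoothed with a Gaussian
    kernel of sigma = corr_length, renormalized to the target sd."""
    white = rng.standard_normal(shape)
    if corr_length <= 0 or sd == 0:
        return white * sd
    smooth = gaussian_filter(white, sigma=corr_length, mode="wrap")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (sd / s)


def generate_lesion_image(spec: PhantomSpec, class_label: str,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One phantom image and its core mask.

    Returns ``(image, core_mask)``: a float image of ``spec.image_size``
    with background noise, a bright annulus at a sampled radius, and a
    core filled with the class's correlated texture; the boolean mask
    marks core pixels (strictly inside the ring's inner edge).
    """
    spec.validate()
    h, w = spec.image_size
    radius = rng.uniform(*spec.ring_radius_range)
    # lesion centre jittered but keeping the ring inside the frame
    margin = radius + spec.ring_width / 2 + 2
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)

    yy, xx = np.indices((h, w))
    dist = np.hypot(yy - cy, xx - cx)

    img = np.full((h, w), spec.background_mean, dtype=float)
    img += correlated_field((h, w), 0.0, spec.background_sd, rng)

    ring = np.abs(dist - radius) <= spec.ring_width / 2
    core = dist < radius - spec.ring_width / 2

    corr_len, core_sd = spec.class_core_params(class_label)
    texture = correlated_field((h, w), corr_len, core_sd, rng)
    img[core] = spec.core_mean + texture[core]
    img[ring] = spec.background_mean + spec.ring_contrast

    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sd, (h, w))
        else:  # Rician magnitude noise
            re = img + rng.normal(0.0, spec.noise_sd, (h, w))
            im = rng.normal(0.0, spec.noise_sd, (h, w))
            img = np.hypot(re, im)
    return np.clip(img, 0.0, 65535.0), core


def place_rois(core_mask: np.ndarray, k: int, roi_size: int = 10,
               rng: np.random.Generator | None = None,
               lesion_id: str = "?") -> list[tuple[int, int]]:
    """Sample k ROI top-left corners uniformly over all-core windows.

    Windows may overlap.  Raises :class:`ROIPlacementError` when the core
    contains no fully-interior window.
    """
    rng = rng or np.random.default_rng()
    h, w = core_mask.shape
    s = roi_size
    if h < s or w < s:
        raise ROIPlacementError(
            f"lesion {lesion_id}: mask smaller than the {s}x{s} window")
    # integral image: window is valid iff all s*s pixels are core
    ii = np.pad(np.cumsum(np.cumsum(core_mask.astype(np.int64), 0), 1),
                ((1, 0), (1, 0)))
    win = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    rows, cols = np.nonzero(win == s * s)
    if rows.size == 0:
        raise ROIPlacementError(
            f"lesion {lesion_id}: no {roi_size}x{roi_size} window fits in the core")
    idx = rng.integers(0, rows.size, size=k)
    return [(int(rows[i]), int(cols[i])) for i in idx]


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort's images and manifest; return the manifest.

    Fully reproducible from ``spec.seed``: images are 16-bit PNG, the
    manifest a TSV with columns lesion_id, label, image, roi_x (col),
    roi_y (row), roi_size — one row per ROI, 0-based coordinates.
    """
    spec.validate()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, n in zip(CLASSES, spec.n_per_class):
        for i in range(n):
            lesion_id = f"{label[:3]}_{i:03d}"
            img, core = generate_lesion_image(spec, label, rng)
            k = int(rng.integers(spec.rois_per_lesion_range[0],
                                 spec.rois_per_lesion_range[1] + 1))
            rois = place_rois(core, k, rng=rng, lesion_id=lesion_id)
            fname = f"{lesion_id}.png"
            iio.imwrite(out_dir / fname,
                        np.round(img).astype(np.uint16), extension=".png")
            for (r, c) in rois:
                rows.append({"lesion_id": lesion_id, "label": label,
                             "image": fname, "roi_x": c, "roi_y": r,
                             "roi_size": 10})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


def generate_cohort_arrays(spec: PhantomSpec
                           ) -> list[tuple[str, str, np.ndarray, list[tuple[int, int]]]]:
    """In-memory cohort: (lesion_id, label, image, roi corners) per lesion.

    Draws follow the same stream order as :func:`generate_cohort`, so the
    pixel data and ROI placements match the on-disk cohort up to PNG
    rounding of intensities.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = []
    for label, n in zip(CLASSES, spec.n_per_class):
        for i in range(n):
            lesion_id = f"{label[:3]}_{i:03d}"
            img, core = generate_lesion_image(spec, label, rng)
            k = int(rng.integers(spec.rois_per_lesion_range[0],
                                 spec.rois_per_lesion_range[1] + 1))
            rois = place_rois(core, k, rng=rng, lesion_id=lesion_id)
            out.append((lesion_id, label, img, rois))
    return out


def synthetic_feature_table(n_per_class: tuple[int, int] = (30, 37),
                            n_features: int = 63, n_informative: int = 5,
                            shift_sd: float = 2.0, seed: int = 0,
                            feature_names: list[str] | None = None
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Labelled Gaussian feature table with a known informative subset.

    The informative features get a between-class mean shift of
    ``shift_sd`` standard deviations; the rest are class-independent
    noise.  Returns ``(table, informative_names)`` where the table has
    lesion_id, label and the feature columns.  Used to validate ranking
    recovery.
    """
    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = [f"f{j:02d}" for j in range(n_features)]
    if len(feature_names) != n_features:
        raise ValueError("feature_names length mismatch")
    informative = list(rng.choice(n_features, size=n_informative, replace=False))
    n_total = sum(n_per_class)
    X = rng.standard_normal((n_total, n_features))
    labels = np.array([CLASSES[0]] * n_per_class[0] + [CLASSES[1]] * n_per_class[1])
    for j in informative:
        X[labels == CLASSES[1], j] += shift_sd
    table = pd.DataFrame(X, columns=feature_names)
    table.insert(0, "label", labels)
    table.insert(0, "lesion_id", [f"s_{i:03d}" for i in range(n_total)])
    return table, sorted(feature_names[j] for j in informative)
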