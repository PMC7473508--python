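"""Per-ROI feature vectors and the lesion-level labelled table.

The canonical feature set has 63 entries: 6 first-order, 22 GLCM
(prefixed ``GLCM_``), 7 run-length (prefixed ``GLRL_``) and 28 wavelet
features.  The order is fixed — families in that sequence, alphabetical
within each family — so that emitted CSVs are diffable; the header is
the contract.

Lesions with several ROIs are represented by the element-wise mean of
their ROI feature vectors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import firstorder, glcm, glrl, wavelet
from .io_roi import GrayImage, QuantizedPatch, ROISpec, extract_roi, \
    read_image, rescale_to_8bit, resize_image

CANONICAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    sorted(firstorder.FIRSTORDER_NAMES)
    + sorted(f"GLCM_{n}" for n in glcm.GLCM_NAMES)
    + sorted(f"GLRL_{n}" for n in glrl.GLRL_NAMES)
    + sorted(wavelet.WAVELET_NAMES)
)

assert len(CANONICAL_FEATURE_NAMES) == 63


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunables of the feature-extraction stage."""

    levels: int = 256               # gray levels L after quantization
    glcm_distance: int = 1
    glcm_symmetric: bool = True
    wentropy_style: str = "normalized"
    rescale_mode: str = "minmax"
    target_size: tuple[int, int] = (240, 240)
    correlation_direction: str = "horizontal"

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_feature_vector(patch: QuantizedPatch,
                           config: ExtractionConfig | None = None
                           ) -> dict[str, float]:
    """All 63 features of one quantized ROI, in canonical order."""
    config = config or ExtractionConfig()
    feats: dict[str, float] = {}
    try:
        feats.update(firstorder.first_order_features(
            patch, config.correlation_direction))
    except Exception as e:
        raise RuntimeError(f"first-order features failed: {e}") from e
    try:
        feats.update({f"GLCM_{k}": v for k, v in glcm.glcm_directional_average(
            patch, distance=config.glcm_distance,
            symmetric=config.glcm_symmetric).items()})
    except Exception as e:
        raise RuntimeError(f"GLCM features failed: {e}") from e
    try:
        feats.update({f"GLRL_{k}": v
                      for k, v in glrl.glrl_directional_average(patch).items()})
    except Exception as e:
        raise RuntimeError(f"GLRL features failed: {e}") from e
    try:
        feats.update(wavelet.wavelet_features(patch, config.wentropy_style))
    except Exception as e:
        raise RuntimeError(f"wavelet features failed: {e}") from e
    return {name: feats[name] for name in CANONICAL_FEATURE_NAMES}


def aggregate_lesion(vectors: list[dict[str, float]]) -> dict[str, float]:
    """Element-wise mean of a lesion's ROI feature vectors."""
    if not vectors:
        raise ValueError("no feature vectors to aggregate")
    names = set(vectors[0])
    for v in vectors[1:]:
        if set(v) != names:
            raise ValueError("feature vectors have mismatched name sets")
    return {name: float(np.mean([v[name] for v in vectors]))
            for name in vectors[0]}


def image_to_patches(img: GrayImage, rois: list[tuple[int, int]],
                     config: ExtractionConfig) -> list[QuantizedPatch]:
    """Resize, rescale to 8 bits, and cut the quantized ROIs of one image."""
    img = resize_image(img, config.target_size)
    img8 = rescale_to_8bit(img, config.rescale_mode)
    return [extract_roi(img8, ROISpec((r, c)), L=config.levels)
            for (r, c) in rois]


def lesion_features_from_array(pixels: np.ndarray,
                               rois: list[tuple[int, int]],
                               config: ExtractionConfig | None = None,
                               bit_depth: int = 16) -> dict[str, float]:
    """Lesion-level feature vector straight from an in-memory image."""
    config = config or ExtractionConfig()
    img = GrayImage(np.round(pixels), bit_depth=bit_depth)
    patches = image_to_patches(img, rois, config)
    return aggregate_lesion([extract_feature_vector(p, config) for p in patches])


def phantom_feature_table(spec, config: ExtractionConfig | None = None
                          ) -> pd.DataFrame:
    """Lesion-level feature table straight from an in-memory phantom cohort.

    Equivalent to ``generate_cohort`` + ``build_table`` without touching
    disk (pixel values differ only by PNG integer rounding, which the
    8-bit rescale applies here too).
    """
    from .phantom import generate_cohort_arrays

    config = config or ExtractionConfig()
    rows = []
    for lesion_id, label, img, rois in generate_cohort_arrays(spec):
        vec = lesion_features_from_array(img, rois, config)
        rows.append({"lesion_id": lesion_id, "label": label, **vec})
    table = pd.DataFrame(rows, columns=["lesion_id", "label",
                                        *CANONICAL_FEATURE_NAMES])
    return table.sort_values("lesion_id", ignore_index=True)


def build_table(manifest: pd.DataFrame | str | Path,
                config: ExtractionConfig | None = None,
                image_dir: str | Path | None = None,
                allow_partial: bool = False) -> pd.DataFrame:
    """Lesion-level labelled feature table from a cohort manifest.

    The manifest (DataFrame or TSV path) has one row per ROI with columns
    lesion_id, label, image, roi_x, roi_y, roi_size.  Rows of the output
    are sorted by lesion_id, so the table does not depend on manifest
    order.  Per-lesion failures abort with a collected report unless
    ``allow_partial`` is set.
    """
    config = config or ExtractionConfig()
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if image_dir is None:
            image_dir = path.parent
        manifest = pd.read_csv(path, sep="\t")
    image_dir = Path(image_dir) if image_dir is not None else Path(".")

    rows, failures = [], []
    for lesion_id, group in manifest.groupby("lesion_id", sort=True):
        labels = group["label"].unique()
        if len(labels) != 1:
            failures.append((lesion_id, "inconsistent labels"))
            continue
        try:
            img = read_image(image_dir / group["image"].iloc[0])
            rois = [(int(r.roi_y), int(r.roi_x)) for r in group.itertuples()]
            patches = image_to_patches(img, rois, config)
            vec = aggregate_lesion(
                [extract_feature_vector(p, config) for p in patches])
        except Exception as e:
            failures.append((lesion_id, str(e)))
            continue
        rows.append({"lesion_id": lesion_id, "label": labels[0], **vec})
    if failures and not allow_partial:
        detail = "; ".join(f"{lid}: {msg}" for lid, msg in failures)
        raise RuntimeError(f"feature extraction failed for {detail}")
    table = pd.DataFrame(rows,
                         columns=["lesion_id", "label",
                                  *CANONICAL_FEATURE_NAMES])
    table.attrs["config_digest"] = config.digest()
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a provenance comment carrying the config digest."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        digest = table.attrs.get("config_digest", "unknown")
        fh.write(f"# extraction_config_digest={digest}\n")
        table.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
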