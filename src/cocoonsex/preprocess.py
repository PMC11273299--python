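"""Image and manifest loading for the cocoon classification pipeline.

Specimens arrive as one image per cocoon plus a CSV manifest carrying the
cocoon weight (grams) and the sex label (0 = female, 1 = male).  Images are
converted to grayscale (ITU-R 601 luma) and resized to the canonical
128 (rows) x 64 (columns) geometry that the HOG descriptor expects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

#: canonical HOG input geometry: 128 rows (height) x 64 columns (width)
CANONICAL_SHAPE = (128, 64)

#: ITU-R 601 luma coefficients for R, G, B
_LUMA = np.array([0.299, 0.587, 0.114])


class ManifestSchemaError(ValueError):
    """A required manifest column is missing."""


class ManifestValidationError(ValueError):
    """A manifest row violates an invariant (e.g. non-positive weight)."""


@dataclass(frozen=True)
class RawSpecimen:
    """One cocoon specimen: image location, weight in grams, sex label."""

    image_path: str
    weight: float
    label: int
    variety: str | None = None

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ManifestValidationError(f"weight must be > 0, got {self.weight}")
        if self.label not in (0, 1):
            raise ManifestValidationError(f"label must be 0 or 1, got {self.label}")


def load_manifest(path: str | os.PathLike) -> list[RawSpecimen]:
    """Read a specimen manifest CSV into a list of :class:`RawSpecimen`.

    The CSV must have columns ``image,weight,label`` (``variety`` optional).
    Rows are returned in file order.  Image paths are resolved relative to
    the manifest's directory when not absolute.
    """
    df = pd.read_csv(path)
    for col in ("image", "weight", "label"):
        if col not in df.columns:
            raise ManifestSchemaError(f"manifest is missing required column '{col}'")
    base = os.path.dirname(os.fspath(path))
    specimens = []
    for i, row in enumerate(df.itertuples(index=False)):
        weight = float(row.weight)
        if not weight > 0:
            # 1-based data row number, matching how a user reads the file
            raise ManifestValidationError(
                f"row {i + 1}: weight must be > 0, got {weight}"
            )
        img = os.fspath(row.image)
        if base and not os.path.isabs(img):
            img = os.path.join(base, img)
        variety = getattr(row, "variety", None)
        specimens.append(
            RawSpecimen(
                image_path=img,
                weight=weight,
                label=int(row.label),
                variety=None if variety is None else str(variety),
            )
        )
    return specimens


def write_manifest(specimens: list[RawSpecimen], path: str | os.PathLike) -> None:
    """Write specimens back to a manifest CSV (round-trips with load_manifest)."""
    df = pd.DataFrame(
        {
            "image": [s.image_path for s in specimens],
            "weight": [s.weight for s in specimens],
            "label": [s.label for s in specimens],
        }
    )
    if any(s.variety is not None for s in specimens):
        df["variety"] = [s.variety for s in specimens]
    df.to_csv(path, index=False)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luminance; pass grayscale through unchanged.

    Uses the ITU-R 601 combination 0.299 R + 0.587 G + 0.114 B.  An RGBA or
    other >3-channel input is rejected rather than silently dropped.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise ValueError(
        f"unsupported image format: expected HxW or HxWx3, got shape {image.shape}"
    )


def resize_canonical(img: np.ndarray) -> np.ndarray:
    """Bilinearly resize a grayscale image to the canonical 128x64 grid.

    The aspect ratio is not preserved: the image is stretched directly onto
    the target grid.  Values stay within the input's [min, max] range.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {img.shape}")
    if img.shape == CANONICAL_SHAPE:
        return img.copy()
    out = resize(
        img, CANONICAL_SHAPE, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, img.min(), img.max())


def load_gray_image(path: str | os.PathLike) -> np.ndarray:
    """Load an image file (PNG/TIFF/JPEG), grayscale it and resize to 128x64."""
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]  # drop alpha from PNGs
    return resize_canonical(to_gray(raw))
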