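"""Histogram-of-oriented-gradients descriptor with FFT-accelerated cell pooling.

The descriptor follows the classic 128x64 pedestrian-window layout: 8x8-pixel
cells, 9 unsigned orientation bins, 2x2-cell blocks slid with a 1-cell stride
and L2-normalized, giving (16-1) x (8-1) = 105 blocks x 36 values = 3780
features.

The accelerated path replaces per-pixel histogram accumulation with
frequency-domain convolution: for each orientation bin the gradient-magnitude
image is masked to the pixels voting for that bin and convolved (via FFT) with
a cell-sized all-ones box filter; sampling the result at cell anchors yields
exactly the per-cell histogram entries.  A direct spatial-domain reference
implementation with the identical contract serves as the numerical oracle.

Two deliberate departures from Dalal-Triggs: orientation votes are hard-assigned
to a single bin (no bilinear vote between neighbouring bins), and block
normalization is plain L2 with an epsilon guard rather than L2-Hys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import fft as sp_fft

from .preprocess import CANONICAL_SHAPE

_EPS = 1e-10


@dataclass(frozen=True)
class HOGParams:
    """Descriptor geometry and binning parameters.

    cell_size is in pixels; block_size and block_stride are in cells.
    Unsigned orientations fold gradient directions into [0, 180) degrees.
    """

    cell_size: int = 8
    block_size: int = 2
    block_stride: int = 1
    num_bins: int = 9
    signed: bool = False
    norm: str = "L2"

    def __post_init__(self) -> None:
        h, w = CANONICAL_SHAPE
        if self.cell_size <= 0 or h % self.cell_size or w % self.cell_size:
            raise ValueError(
                f"cell_size {self.cell_size} must divide {h}x{w} evenly"
            )
        if self.num_bins < 2:
            raise ValueError("num_bins must be >= 2")
        if self.block_size < 1 or self.block_stride < 1:
            raise ValueError("block_size and block_stride must be >= 1")
        if self.norm != "L2":
            raise ValueError(f"unsupported block norm {self.norm!r}")

    @property
    def cells_shape(self) -> tuple[int, int]:
        return (CANONICAL_SHAPE[0] // self.cell_size,
                CANONICAL_SHAPE[1] // self.cell_size)

    @property
    def blocks_shape(self) -> tuple[int, int]:
        cy, cx = self.cells_shape
        return ((cy - self.block_size) // self.block_stride + 1,
                (cx - self.block_size) // self.block_stride + 1)

    @property
    def n_blocks(self) -> int:
        by, bx = self.blocks_shape
        return by * bx

    @property
    def block_width(self) -> int:
        """Features per block (36 with defaults)."""
        return self.block_size ** 2 * self.num_bins

    @property
    def descriptor_length(self) -> int:
        return self.n_blocks * self.block_width

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "HOGParams":
        return cls(**json.loads(s))

    def digest(self) -> str:
        """Stable hash used to check descriptor/model layout compatibility."""
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradients: components, magnitude and folded orientation."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # degrees, [0, 180) unsigned / [0, 360) signed


def compute_gradients(img: np.ndarray, signed: bool = False) -> GradientField:
    """Central-difference gradients with replicate border padding.

    The [-1, 0, 1] kernel is correlated along columns (gx) and rows (gy), so
    an interior column ramp I(r,c)=c has gx = 2.  Zero-magnitude pixels get
    orientation 0 by convention.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    padded = np.pad(img, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.hypot(gx, gy)
    orientation = np.degrees(np.arctan2(gy, gx))
    if signed:
        orientation = np.mod(orientation, 360.0)
    else:
        orientation = np.mod(orientation, 180.0)
    orientation[magnitude == 0] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, orientation=orientation)


@dataclass(frozen=True)
class OrientationFilterBank:
    """One cell-sized all-ones box filter per orientation bin.

    Convolving the bin-masked magnitude image with its filter puts, at each
    cell anchor, the sum of magnitudes of that cell's pixels voting for the
    bin — i.e. the cell's histogram entry for hard-assigned votes.
    """

    filters: tuple[np.ndarray, ...]
    bin_width: float  # degrees per bin

    @property
    def num_bins(self) -> int:
        return len(self.filters)


def build_filter_bank(params: HOGParams) -> OrientationFilterBank:
    full_range = 360.0 if params.signed else 180.0
    kernel = np.ones((params.cell_size, params.cell_size))
    return OrientationFilterBank(
        filters=tuple(kernel.copy() for _ in range(params.num_bins)),
        bin_width=full_range / params.num_bins,
    )


def fft_convolve(g: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Linear 2-D convolution via the frequency domain, cropped to 'same'.

    Both operands are zero-padded to the full linear-convolution size (no
    circular wrap-around), transformed, multiplied pointwise and inverted.
    The output is centred on the kernel anchor (kh//2, kw//2 offset into the
    full result), matching a spatial 'same' convolution.
    """
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.shape[0] > g.shape[0] or f.shape[1] > g.shape[1]:
        raise ValueError(
            f"kernel {f.shape} larger than image {g.shape}"
        )
    full = (g.shape[0] + f.shape[0] - 1, g.shape[1] + f.shape[1] - 1)
    fast = [sp_fft.next_fast_len(n) for n in full]
    G = sp_fft.rfft2(g, fast)
    F = sp_fft.rfft2(f, fast)
    conv = sp_fft.irfft2(G * F, fast)[: full[0], : full[1]]
    # 'same' crop centred on the kernel anchor
    r0 = (f.shape[0] - 1) // 2
    c0 = (f.shape[1] - 1) // 2
    return conv[r0 : r0 + g.shape[0], c0 : c0 + g.shape[1]]


def _bin_index(orientation: np.ndarray, bank: OrientationFilterBank) -> np.ndarray:
    idx = np.floor(orientation / bank.bin_width).astype(int)
    return np.clip(idx, 0, bank.num_bins - 1)


def fft_cell_histograms(grad: GradientField, params: HOGParams) -> np.ndarray:
    """Per-cell orientation histograms via frequency-domain box filtering.

    Returns an array of shape (cells_y, cells_x, num_bins); with defaults on
    a 128x64 image that is (16, 8, 9).
    """
    bank = build_filter_bank(params)
    cs = params.cell_size
    cy, cx = params.cells_shape
    bins = _bin_index(grad.orientation, bank)
    hist = np.empty((cy, cx, params.num_bins))
    # sample positions where the 'same'-cropped conv holds a full-cell sum:
    # cell (i,j) covers rows i*cs..i*cs+cs-1; its box sum sits at
    # full-conv index (i*cs + cs - 1) which after the 'same' crop of
    # (cs-1)//2 lands at i*cs + cs - 1 - (cs-1)//2 = i*cs + cs//2.
    rows = np.arange(cy) * cs + cs // 2
    cols = np.arange(cx) * cs + cs // 2
    for k, f_k in enumerate(bank.filters):
        masked = np.where(bins == k, grad.magnitude, 0.0)
        conv = fft_convolve(masked, f_k)
        hist[:, :, k] = conv[np.ix_(rows, cols)]
    return hist


def _cell_histograms_direct(grad: GradientField, params: HOGParams) -> np.ndarray:
    """Spatial-domain cell histograms by direct per-pixel accumulation."""
    bank = build_filter_bank(params)
    cs = params.cell_size
    cy, cx = params.cells_shape
    bins = _bin_index(grad.orientation, bank)
    hist = np.zeros((cy, cx, params.num_bins))
    mag = grad.magnitude
    for i in range(cy):
        for j in range(cx):
            b = bins[i * cs : (i + 1) * cs, j * cs : (j + 1) * cs].ravel()
            m = mag[i * cs : (i + 1) * cs, j * cs : (j + 1) * cs].ravel()
            np.add.at(hist[i, j], b, m)
    return hist


def normalize_and_flatten(cells: np.ndarray, params: HOGParams) -> np.ndarray:
    """Slide block windows over the cell grid, L2-normalize, concatenate.

    Each block vector v is divided by sqrt(||v||^2 + eps^2), so an all-zero
    block maps to zeros instead of NaN.  Layout: blocks in row-major order,
    cells row-major within a block, the histogram contiguous within a cell.
    """
    bs, stride = params.block_size, params.block_stride
    by, bx = params.blocks_shape
    out = np.empty((by, bx, params.block_width))
    for i in range(by):
        for j in range(bx):
            block = cells[i * stride : i * stride + bs, j * stride : j * stride + bs]
            v = block.reshape(-1)
            out[i, j] = v / np.sqrt(v @ v + _EPS**2)
    return out.reshape(-1)


def fast_hog(img: np.ndarray, params: HOGParams | None = None) -> np.ndarray:
    """FFT-accelerated HOG descriptor of a canonical 128x64 grayscale image."""
    params = params or HOGParams()
    _check_canonical(img)
    grad = compute_gradients(img, signed=params.signed)
    cells = fft_cell_histograms(grad, params)
    return normalize_and_flatten(cells, params)


def hog_reference(img: np.ndarray, params: HOGParams | None = None) -> np.ndarray:
    """Direct spatial-domain HOG with the identical contract to fast_hog.

    Used as the equivalence oracle for the FFT path; the two agree to within
    floating-point round-off (~1e-12 in practice).
    """
    params = params or HOGParams()
    _check_canonical(img)
    grad = compute_gradients(img, signed=params.signed)
    cells = _cell_histograms_direct(grad, params)
    return normalize_and_flatten(cells, params)


def _check_canonical(img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.shape != CANONICAL_SHAPE:
        raise ValueError(
            f"expected canonical {CANONICAL_SHAPE} image, got {img.shape}"
        )


def descriptors_to_csv(descriptors: np.ndarray, path, params: HOGParams) -> None:
    """Export a descriptor matrix as CSV plus a sidecar JSON of HOGParams."""
    import pandas as pd

    d = descriptors.shape[1]
    df = pd.DataFrame(descriptors, columns=[f"h{i:04d}" for i in range(d)])
    df.to_csv(path, index=False)
    with open(str(path) + ".params.json", "w") as fh:
        fh.write(params.to_json())
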