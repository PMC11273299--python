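"""Block-wise Fisher-discriminant compression of HOG descriptors.

The 3780-feature descriptor is a concatenation of 105 blocks of 36 features.
Each block is compressed independently to a single Fisher-discriminant
coordinate: with binary labels LDA admits exactly one discriminant direction
w proportional to (S_W + lambda*I)^-1 (mu_male - mu_female), where S_W is the
within-class scatter with a small ridge for singular blocks.  This takes
3780 -> 105 features; the standardized cocoon weight is then appended as the
106th feature.

Fitting uses training data only (call sites fit per CV training fold); the
projection sign is fixed so the male class mean projects at or above the
female mean, making the compressed features comparable across refits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

#: ridge coefficient applied to S_W as lam * trace(S_W) / d
RIDGE = 1e-6


@dataclass(frozen=True)
class WeightStats:
    """Training-split mean and standard deviation of cocoon weights (grams)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"degenerate training weights: sd = {self.sd}")

    @classmethod
    def fit(cls, weights: np.ndarray) -> "WeightStats":
        w = np.asarray(weights, dtype=float)
        # sample (ddof=1) standard deviation: the usual estimator when the
        # statistics come from a training split
        return cls(mean=float(w.mean()), sd=float(w.std(ddof=1)))

    def standardize(self, weight: float) -> float:
        return (weight - self.mean) / self.sd


def class_scatter(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means, within-class scatter S_W and between-class scatter S_B.

    S_W = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)^T
    S_B = sum_c n_c (mu_c - mu)(mu_c - mu)^T

    and the total scatter about the grand mean decomposes as S_W + S_B.
    Returns (means, S_W, S_B) with means[c] the mean of class c in {0, 1}.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute scatter")
    n, d = X.shape
    if n <= d:
        warnings.warn(
            f"n={n} <= d={d}: scatter matrices will be singular", stacklevel=2
        )
    mu = X.mean(axis=0)
    means = np.empty((2, d))
    S_W = np.zeros((d, d))
    S_B = np.zeros((d, d))
    for c in (0, 1):
        Xc = X[y == c]
        means[c] = Xc.mean(axis=0)
        centered = Xc - means[c]
        S_W += centered.T @ centered
        dm = (means[c] - mu)[:, None]
        S_B += len(Xc) * (dm @ dm.T)
    return means, S_W, S_B


def _fisher_direction(Xb: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unit-norm ridge-regularized Fisher direction for one block.

    Returns (w, degenerate).  A block with no usable scatter or identical
    class means falls back to the first canonical basis vector.
    """
    d = Xb.shape[1]
    means, S_W, _ = class_scatter(Xb, y)
    delta = means[1] - means[0]
    if not np.any(delta) and not np.any(S_W):
        return np.eye(d)[0], True
    lam = RIDGE * np.trace(S_W) / d
    if lam == 0:
        lam = RIDGE  # all-zero scatter but distinct means
    try:
        w = np.linalg.solve(S_W + lam * np.eye(d), delta)
    except np.linalg.LinAlgError:
        return np.eye(d)[0], True
    norm = np.linalg.norm(w)
    if norm == 0 or not np.all(np.isfinite(w)):
        return np.eye(d)[0], True
    w = w / norm
    # sign convention: male (label 1) mean projects >= female mean
    if w @ delta < 0:
        w = -w
    return w, False


@dataclass(frozen=True)
class BlockLDAModel:
    """Per-block unit projection vectors and centering offsets.

    projections: (n_blocks, block_width); offsets: (n_blocks, block_width)
    holding the training grand mean of each block.  params_digest ties the
    model to the HOG layout it was fitted on.
    """

    projections: np.ndarray
    offsets: np.ndarray
    params_digest: str
    n_samples: int
    class_counts: tuple[int, int]

    @property
    def n_blocks(self) -> int:
        return self.projections.shape[0]

    @property
    def block_width(self) -> int:
        return self.projections.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "projections": self.projections.tolist(),
                "offsets": self.offsets.tolist(),
                "params_digest": self.params_digest,
                "n_samples": self.n_samples,
                "class_counts": list(self.class_counts),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BlockLDAModel":
        d = json.loads(s)
        return cls(
            projections=np.asarray(d["projections"], dtype=float),
            offsets=np.asarray(d["offsets"], dtype=float),
            params_digest=d["params_digest"],
            n_samples=int(d["n_samples"]),
            class_counts=tuple(d["class_counts"]),
        )


def fit_block_lda(
    descriptors: np.ndarray,
    y: np.ndarray,
    params=None,
    block_width: int | None = None,
) -> BlockLDAModel:
    """Fit one Fisher discriminant per contiguous descriptor block.

    ``params`` is the HOGParams the descriptors were extracted with (used for
    block width and the layout digest); pass ``block_width`` directly for
    non-HOG feature matrices in tests.
    """
    X = np.asarray(descriptors, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit block LDA")
    if params is not None:
        bw = params.block_width
        digest = params.digest()
    else:
        bw = block_width or 36
        digest = "none"
    d = X.shape[1]
    if d % bw:
        raise ValueError(f"descriptor length {d} not divisible by block width {bw}")
    n_blocks = d // bw
    projections = np.empty((n_blocks, bw))
    offsets = np.empty((n_blocks, bw))
    degenerate = []
    with warnings.catch_warnings():
        # per-block n<=d warnings would fire 105 times; surface them once below
        warnings.simplefilter("ignore")
        for b in range(n_blocks):
            Xb = X[:, b * bw : (b + 1) * bw]
            offsets[b] = Xb.mean(axis=0)
            projections[b], degen = _fisher_direction(Xb, y)
            if degen:
                degenerate.append(b)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} degenerate block(s) fell back to a canonical "
            f"basis direction: {degenerate[:10]}",
            stacklevel=2,
        )
    counts = (int(np.sum(y == 0)), int(np.sum(y == 1)))
    return BlockLDAModel(
        projections=projections,
        offsets=offsets,
        params_digest=digest,
        n_samples=len(y),
        class_counts=counts,
    )


def transform_block_lda(model: BlockLDAModel, descriptors: np.ndarray) -> np.ndarray:
    """Project descriptors onto the per-block Fisher directions.

    Accepts one descriptor (1-D) or a matrix (2-D); returns 105 coordinates
    per specimen with default HOG geometry.
    """
    X = np.asarray(descriptors, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    expected = model.n_blocks * model.block_width
    if X.shape[1] != expected:
        raise ValueError(
            f"descriptor length mismatch: expected {expected}, got {X.shape[1]}"
        )
    blocks = X.reshape(X.shape[0], model.n_blocks, model.block_width)
    out = np.einsum("nbd,bd->nb", blocks - model.offsets[None], model.projections)
    return out[0] if single else out


def fuse_weight(
    features: np.ndarray, weight: float | np.ndarray, weight_stats: WeightStats
) -> np.ndarray:
    """Append the standardized cocoon weight to the compressed feature vector.

    The z-score uses training-split statistics only, so test weights never
    leak into the standardization.  105 features in -> 106 out.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        w = float(weight)
        if not w > 0:
            raise ValueError(f"weight must be > 0, got {w}")
        return np.concatenate([F, [weight_stats.standardize(w)]])
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    z = (w - weight_stats.mean) / weight_stats.sd
    return np.hstack([F, z[:, None]])
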