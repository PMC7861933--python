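"""Texture and gradient descriptors plus PCA reduction.

The image representation is the concatenation of

* a 256-bin local binary pattern (LBP) histogram: at every interior pixel
  the 8 neighbors are thresholded against the center (neighbor >= center
  -> 1, ties toward 1) and read row-major (TL, T, TR, L, R, BL, B, BR as
  bits 7..0) into a code in 0..255.  The normalized code histogram is
  invariant to any strictly monotone intensity transform of the image.

* a histogram-of-oriented-gradients (HOG) descriptor: central-difference
  gradients, unsigned orientation in [0, 180) hard-assigned to `bins`
  equal sectors, magnitude-weighted per-cell histograms, and sliding
  block-wise L2 normalization (block of `block`x`block` cells, stride one
  cell, epsilon-guarded), concatenated row-major.  For a 128x128 image
  with 8-px cells, 2x2 blocks and 9 bins the length is (16-1)^2*4*9 = 8100.

The combined vectors are decorrelated and reduced with PCA keeping the
smallest number of components whose explained-variance fractions reach
`variance_retained`.  The PCA fit is deterministic, with the sign of each
component fixed so its largest-magnitude loading is positive; when
samples are fewer than features the fit goes through the Gram matrix,
which is exact and much cheaper in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import validate_image

__all__ = [
    "LBPPattern",
    "FeatureVector",
    "PCAModel",
    "lbp_code",
    "lbp_histogram",
    "hog_features",
    "hog_length",
    "combine_features",
    "fit_pca",
    "transform_pca",
    "inverse_transform_pca",
]

# (drow, dcol) of the 8 neighbors in row-major order; index i contributes
# bit (7 - i) of the code.
_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1),
                     (0, -1), (0, 1),
                     (1, -1), (1, 0), (1, 1)]


@dataclass
class LBPPattern:
    """3×3 binary pattern (center fixed to 0) and its 8-bit code."""

    bits: np.ndarray
    code: int


def lbp_code(patch) -> LBPPattern:
    """LBP of a single 3×3 patch (neighbor >= center rule)."""
    arr = np.asarray(patch, dtype=float)
    if arr.shape != (3, 3):
        raise ValueError(f"LBP patch must be 3x3, got {arr.shape}")
    center = arr[1, 1]
    bits = np.zeros((3, 3), dtype=int)
    code = 0
    for i, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        bit = 1 if arr[1 + dr, 1 + dc] >= center else 0
        bits[1 + dr, 1 + dc] = bit
        code |= bit << (7 - i)
    return LBPPattern(bits=bits, code=code)


def lbp_histogram(image) -> np.ndarray:
    """Normalized 256-bin histogram of LBP codes over all interior pixels."""
    arr = validate_image(image)
    center = arr[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for i, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        neigh = arr[1 + dr: arr.shape[0] - 1 + dr,
                    1 + dc: arr.shape[1] - 1 + dc]
        codes |= (neigh >= center).astype(np.int64) << (7 - i)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def hog_length(size: int, cell: int = 8, block: int = 2, bins: int = 9) -> int:
    """Descriptor length for a square ``size``×``size`` image."""
    n_cells = size // cell
    n_blocks = n_cells - block + 1
    return n_blocks * n_blocks * block * block * bins


def hog_features(image, cell: int = 8, block: int = 2, bins: int = 9,
                 eps: float = 1e-9) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor (see module docstring)."""
    arr = validate_image(image)
    h, w = arr.shape
    if h % cell or w % cell:
        raise ValueError(
            f"image dimensions {arr.shape} must be divisible by cell={cell}")
    gy, gx = np.gradient(arr)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bin_idx = np.minimum((ang / (180.0 / bins)).astype(int), bins - 1)

    cy, cx = h // cell, w // cell
    # accumulate magnitude into (cell_row, cell_col, bin)
    flat = ((np.arange(h)[:, None] // cell) * cx * bins
            + (np.arange(w)[None, :] // cell) * bins
            + bin_idx)
    cell_hist = np.bincount(flat.ravel(), weights=mag.ravel(),
                            minlength=cy * cx * bins).reshape(cy, cx, bins)

    nby, nbx = cy - block + 1, cx - block + 1
    if nby < 1 or nbx < 1:
        raise ValueError("image has fewer cells than the block size")
    out = np.empty((nby, nbx, block * block * bins))
    for by in range(nby):
        for bx in range(nbx):
            v = cell_hist[by:by + block, bx:bx + block].ravel()
            out[by, bx] = v / np.sqrt(v @ v + eps * eps)
    return out.ravel()


@dataclass
class FeatureVector:
    """Concatenated LBP histogram + HOG descriptor for one image."""

    values: np.ndarray
    lbp_bins: int
    hog_dims: int
    source_image: str | None = None

    def __post_init__(self):
        if len(self.values) != self.lbp_bins + self.hog_dims:
            raise ValueError("feature layout does not match vector length")


def combine_features(lbp, hog, source_image: str | None = None) -> FeatureVector:
    """Concatenate LBP (first) and HOG into one feature vector."""
    lbp = np.asarray(lbp, dtype=float).ravel()
    hog = np.asarray(hog, dtype=float).ravel()
    values = np.concatenate([lbp, hog])
    if not np.isfinite(values).all():
        raise ValueError("feature vectors must be finite")
    return FeatureVector(values=values, lbp_bins=len(lbp), hog_dims=len(hog),
                         source_image=source_image)


@dataclass
class PCAModel:
    """Fitted PCA: centering mean, orthonormal components, variance ratios."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int


def fit_pca(matrix, variance_retained: float = 0.95) -> PCAModel:
    """Fit PCA keeping the fewest components reaching ``variance_retained``.

    ``variance_retained >= 1`` keeps every component with nonzero singular
    value (full-rank round trip).  Deterministic; component signs fixed so
    the largest-magnitude loading of each component is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("PCA input must be a 2-D (samples x features) matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {n}")
    if not np.isfinite(X).all():
        raise ValueError("PCA input must be finite")
    if not 0.0 < variance_retained <= 1.0:
        raise ValueError(
            f"variance_retained must be in (0, 1], got {variance_retained}")

    mean = X.mean(axis=0)
    Xc = X - mean
    if p <= n:
        _, svals, components = np.linalg.svd(Xc, full_matrices=False)
    else:
        # Gram trick: exact economy SVD via the n x n sample Gram matrix
        gram = Xc @ Xc.T
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        svals = np.sqrt(np.clip(evals, 0.0, None))
        safe = np.where(svals > 0, svals, 1.0)
        components = (evecs.T @ Xc) / safe[:, None]

    # components below numerical rank are noise (Gram path divides by svals)
    tol = svals[0] * 1e-6 if svals.size and svals[0] > 0 else 0.0
    rank = int(np.sum(svals > tol))
    svals, components = svals[:rank], components[:rank]
    explained = svals ** 2 / (n - 1)
    total = explained.sum()
    ratios = explained / total if total > 0 else np.zeros_like(explained)

    if variance_retained >= 1.0:
        k = rank
    else:
        k = int(np.searchsorted(np.cumsum(ratios), variance_retained) + 1)
        k = min(max(k, 1), rank)

    components = components[:k].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=mean, components=components,
                    explained_variance_ratio=ratios[:k], n_components=k)


def transform_pca(model: PCAModel, vec) -> np.ndarray:
    """Project (vec − mean) onto the principal components."""
    x = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec, float)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: vector has {x.shape[-1]} features, "
            f"model expects {model.mean.shape[0]}")
    return (x - model.mean) @ model.components.T


def inverse_transform_pca(model: PCAModel, reduced) -> np.ndarray:
    """Map reduced coordinates back to the original feature space."""
    z = np.asarray(reduced, dtype=float)
    if z.shape[-1] != model.n_components:
        raise ValueError(
            f"dimension mismatch: got {z.shape[-1]} coordinates, "
            f"model has {model.n_components} components")
    return z @ model.components + model.mean
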