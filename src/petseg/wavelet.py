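"""Haar multiresolution analysis of 2-D slices with exact reconstruction.

The 2x2 Haar block transform used throughout is O = H^T I H with

    H = 1/2 * [[1, 1], [1, -1]],

so H is symmetric, H*H = I/2, and H^{-1} = 2H.  With this 1/2 normalisation
the approximation coefficient of a 2x2 block is exactly the block mean,
which keeps wavelet-domain features on the same intensity scale as spatial
voxels (a constant slice has a constant approximation and zero details at
every level).

Two decomposition orders are provided:

* ``nonstandard``: alternate row/column 1-D transforms, recursing on the
  approximation quadrant only (the classic pyramid; each level yields
  approximation + horizontal/vertical/diagonal detail subbands of half the
  previous in-plane size);
* ``standard``: the full multi-level 1-D transform applied to every row,
  then to every column of the result.

The two orders coincide at one level and differ from two levels on.
Coefficients are stored packed in a single matrix (approximation in the
top-left corner, quadtree detail layout); both orders reconstruct the input
exactly.  Slices whose dimensions are not divisible by 2^levels are
reflect-padded once up front and cropped back after reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HAAR_H",
    "WaveletDecomposition",
    "haar_block_forward",
    "haar_block_inverse",
    "decompose_nonstandard",
    "decompose_standard",
    "reconstruct",
]

#: The 2x2 Haar coefficient block (1/2 normalisation).
HAAR_H = 0.5 * np.array([[1.0, 1.0], [1.0, -1.0]])


def haar_block_forward(block: np.ndarray) -> np.ndarray:
    """Transform one 2x2 block: O = H^T I H."""
    block = np.asarray(block, dtype=np.float64)
    if block.shape != (2, 2):
        raise ValueError(f"expected a 2x2 block, got shape {block.shape}")
    return HAAR_H.T @ block @ HAAR_H


def haar_block_inverse(coeffs: np.ndarray) -> np.ndarray:
    """Invert one 2x2 block: I = (H^-1)^T O H^-1 with H^-1 = 2H."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 block, got shape {coeffs.shape}")
    h_inv = 2.0 * HAAR_H
    return h_inv.T @ coeffs @ h_inv


@dataclass
class WaveletDecomposition:
    """Packed Haar coefficients of one slice.

    ``coeffs`` holds the padded slice's coefficients with the level-
    ``levels`` approximation in the top-left ``(r/2^L, c/2^L)`` corner and
    detail quadrants tiled around it; ``original_shape`` records the
    pre-padding slice size for exact cropping on reconstruction.
    """

    coeffs: np.ndarray
    levels: int
    mode: str  # "standard" | "nonstandard"
    original_shape: tuple[int, int]

    @property
    def approximation(self) -> np.ndarray:
        """Final-level approximation subband (half size per level)."""
        r, c = self.coeffs.shape
        f = 2 ** self.levels
        return self.coeffs[: r // f, : c // f]

    def details(self, level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(horizontal, vertical, diagonal) detail quadrants at ``level``.

        For the nonstandard mode these are the pyramid subbands; for the
        standard mode they are the corresponding packed-layout regions.
        """
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}")
        r, c = self.coeffs.shape
        m, n = r // 2 ** level, c // 2 ** level
        h = self.coeffs[:m, n: 2 * n]
        v = self.coeffs[m: 2 * m, :n]
        d = self.coeffs[m: 2 * m, n: 2 * n]
        return h, v, d


def _pad_to_multiple(slice_2d: np.ndarray, factor: int) -> np.ndarray:
    r, c = slice_2d.shape
    pr = (-r) % factor
    pc = (-c) % factor
    if pr or pc:
        slice_2d = np.pad(slice_2d, ((0, pr), (0, pc)), mode="symmetric")
    return slice_2d


def _check(slice_2d: np.ndarray, levels: int) -> np.ndarray:
    a = np.asarray(slice_2d, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got {a.ndim} dimensions")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(a.shape) < 2 ** levels:
        raise ValueError(f"{levels} levels too deep for slice of shape {a.shape}")
    return a


def _level_forward(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One 2-D Haar level on an even-sized array, vectorised over blocks."""
    p, q = A[0::2, 0::2], A[0::2, 1::2]
    r, s = A[1::2, 0::2], A[1::2, 1::2]
    a = (p + q + r + s) / 4.0
    h = (p - q + r - s) / 4.0
    v = (p + q - r - s) / 4.0
    d = (p - q - r + s) / 4.0
    return a, h, v, d


def _level_inverse(a, h, v, d) -> np.ndarray:
    out = np.empty((2 * a.shape[0], 2 * a.shape[1]), dtype=np.float64)
    out[0::2, 0::2] = a + h + v + d
    out[0::2, 1::2] = a - h + v - d
    out[1::2, 0::2] = a + h - v - d
    out[1::2, 1::2] = a - h - v + d
    return out


def decompose_nonstandard(slice_2d: np.ndarray, levels: int = 1) -> WaveletDecomposition:
    """Pyramid decomposition: each level transforms the previous approximation."""
    a0 = _check(slice_2d, levels)
    original_shape = a0.shape
    A = _pad_to_multiple(a0, 2 ** levels)
    coeffs = A.copy()
    m, n = A.shape
    for _ in range(levels):
        a, h, v, d = _level_forward(coeffs[:m, :n])
        m, n = m // 2, n // 2
        coeffs[:m, n: 2 * n] = h
        coeffs[m: 2 * m, :n] = v
        coeffs[m: 2 * m, n: 2 * n] = d
        coeffs[:m, :n] = a
    return WaveletDecomposition(coeffs, levels, "nonstandard", original_shape)


def _haar1d_multilevel(M: np.ndarray, levels: int, axis: int) -> np.ndarray:
    """Full multi-level 1-D Haar along ``axis`` of every line of M."""
    M = np.swapaxes(M, axis, 1).copy()
    n = M.shape[1]
    for k in range(levels):
        m = n // 2 ** k
        seg = M[:, :m]
        a = (seg[:, 0::2] + seg[:, 1::2]) / 2.0
        d = (seg[:, 0::2] - seg[:, 1::2]) / 2.0
        M[:, : m // 2] = a
        M[:, m // 2: m] = d
    return np.swapaxes(M, axis, 1)


def _haar1d_multilevel_inverse(M: np.ndarray, levels: int, axis: int) -> np.ndarray:
    M = np.swapaxes(M, axis, 1).copy()
    n = M.shape[1]
    for k in range(levels - 1, -1, -1):
        m = n // 2 ** k
        a = M[:, : m // 2].copy()
        d = M[:, m // 2: m].copy()
        M[:, 0:m:2] = a + d
        M[:, 1:m:2] = a - d
    return np.swapaxes(M, axis, 1)


def decompose_standard(slice_2d: np.ndarray, levels: int = 1) -> WaveletDecomposition:
    """Standard decomposition: multi-level 1-D transform on rows, then columns."""
    a0 = _check(slice_2d, levels)
    original_shape = a0.shape
    A = _pad_to_multiple(a0, 2 ** levels)
    coeffs = _haar1d_multilevel(A, levels, axis=1)
    coeffs = _haar1d_multilevel(coeffs, levels, axis=0)
    return WaveletDecomposition(coeffs, levels, "standard", original_shape)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert a decomposition, reproducing the original slice exactly."""
    coeffs = np.asarray(dec.coeffs, dtype=np.float64)
    R, C = coeffs.shape
    f = 2 ** dec.levels
    if R % f or C % f:
        raise ValueError(f"coefficient shape {coeffs.shape} inconsistent with "
                         f"{dec.levels} levels")
    if dec.mode == "nonstandard":
        out = coeffs.copy()
        for k in range(dec.levels, 0, -1):
            m, n = R // 2 ** k, C // 2 ** k
            a = out[:m, :n].copy()
            h = out[:m, n: 2 * n].copy()
            v = out[m: 2 * m, :n].copy()
            d = out[m: 2 * m, n: 2 * n].copy()
            out[: 2 * m, : 2 * n] = _level_inverse(a, h, v, d)
    elif dec.mode == "standard":
        out = _haar1d_multilevel_inverse(coeffs, dec.levels, axis=0)
        out = _haar1d_multilevel_inverse(out, dec.levels, axis=1)
    else:
        raise ValueError(f"unknown decomposition mode {dec.mode!r}")
    r, c = dec.original_shape
    return out[:r, :c]
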