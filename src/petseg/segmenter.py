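"""Window-based ANN segmentation in the spatial and wavelet domains.

Each slice is scanned with a 12x12 voxel window whose 144 values form the
network's feature vector.  Two scanning modes are used:

* tiling (stride = window, reflect-padded to fit): the window counts match
  the slice geometry (a 168x168 slice yields 14x14 = 196 tiles, an 84x84
  approximation 7x7 = 49);
* dense centred scanning (stride 1, reflect padding): one window per voxel,
  centred on it, giving a per-voxel score map.

Training windows are sampled densely and labelled by the class of the
window's *centre* voxel, so the per-voxel score map answers "is this voxel
tumour given its 12x12 context"; the any-tumour-in-window rule remains
available in :func:`label_windows` for window-level detection targets.  For
the wavelet route the slice is first decomposed (Haar, nonstandard) and the
approximation subband is scanned instead, with the ground truth
down-sampled to the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .volume_io import LabelVolume, PETVolume
from .wavelet import decompose_nonstandard
from . import neural

__all__ = [
    "WindowSet",
    "SegmentationResult",
    "extract_windows",
    "label_windows",
    "downsample_truth",
    "build_training_set",
    "segment_spatial",
    "segment_wavelet",
    "select_best",
]

WINDOW_DEFAULT = 12
_CENTER_OFFSET = (WINDOW_DEFAULT - 1) // 2  # centre voxel sits at (5, 5) in the window


@dataclass
class WindowSet:
    """Flattened scan windows of one slice plus their provenance."""

    windows: np.ndarray  # (n, window*window), row-major flattening
    origins: np.ndarray  # (n, 3) of (slice, row, col); top-left for tiles, centre voxel for dense scans
    window: int
    stride: int
    source_domain: str  # "spatial" | "wavelet"
    slice_shape: tuple[int, int]
    centered: bool = False


@dataclass
class SegmentationResult:
    labels: LabelVolume
    raw_scores: np.ndarray  # per-voxel network output, same shape as labels
    pipeline_tag: str  # spatial | wavelet | threshold | kmeans

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.raw_scores)):
            raise ValueError("segmentation scores must be finite")


def _pad_for_tiling(slice_2d: np.ndarray, window: int, stride: int) -> np.ndarray:
    r, c = slice_2d.shape
    n_r = max(1, -(-(r - window) // stride) + 1)
    n_c = max(1, -(-(c - window) // stride) + 1)
    pr = (n_r - 1) * stride + window - r
    pc = (n_c - 1) * stride + window - c
    if pr or pc:
        slice_2d = np.pad(slice_2d, ((0, pr), (0, pc)), mode="symmetric")
    return slice_2d


def _pad_centered(slice_2d: np.ndarray, window: int) -> np.ndarray:
    before = _CENTER_OFFSET if window == WINDOW_DEFAULT else (window - 1) // 2
    after = window - 1 - before
    return np.pad(slice_2d, ((before, after), (before, after)), mode="symmetric")


def extract_windows(slice_2d: np.ndarray, window: int = WINDOW_DEFAULT,
                    stride: int | None = None, slice_index: int = 0,
                    source_domain: str = "spatial",
                    centered: bool = False) -> WindowSet:
    """Scan a slice with a square window.

    With ``centered=True`` the slice is reflect-padded and scanned at
    stride 1 with one window centred on every voxel (origins are voxel
    coordinates).  Otherwise windows tile the (padded) slice at ``stride``
    (default: the window size, i.e. non-overlapping tiles) and origins are
    the top-left corners.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    if slice_2d.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if window < 1:
        raise ValueError("window must be >= 1")
    r, c = slice_2d.shape
    if centered:
        stride = 1
        padded = _pad_centered(slice_2d, window)
        view = sliding_window_view(padded, (window, window))
        rows, cols = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    else:
        stride = int(stride or window)
        if stride < 1:
            raise ValueError("stride must be >= 1")
        padded = _pad_for_tiling(slice_2d, window, stride)
        if window > min(padded.shape):
            raise ValueError(f"window {window} larger than padded slice {padded.shape}")
        view = sliding_window_view(padded, (window, window))[::stride, ::stride]
        rows, cols = np.meshgrid(np.arange(view.shape[0]) * stride,
                                 np.arange(view.shape[1]) * stride, indexing="ij")
    n = view.shape[0] * view.shape[1]
    windows = view.reshape(n, window * window)
    origins = np.column_stack([np.full(n, slice_index), rows.ravel(), cols.ravel()])
    return WindowSet(windows, origins, window, stride, source_domain,
                     (r, c), centered)


def label_windows(window_set: WindowSet, truth_2d: np.ndarray,
                  rule: str = "any") -> np.ndarray:
    """Per-window training target from an aligned ground-truth slice.

    ``truth_2d`` lives on the same grid the windows were extracted from
    (for the wavelet domain, down-sample it first with
    :func:`downsample_truth`); it may be binary or fractional.

    rule:
      * ``any``      - 1.0 if any foreground value falls inside the window;
      * ``center``   - the truth value at the window's centre voxel
        (dense scans only);
      * ``fraction`` - mean truth value over the window.
    """
    truth_2d = np.asarray(truth_2d, dtype=np.float64)
    if truth_2d.shape != window_set.slice_shape:
        raise ValueError(f"ground truth shape {truth_2d.shape} does not match "
                         f"window source slice {window_set.slice_shape}")
    w = window_set.window
    if rule == "center":
        if not window_set.centered:
            raise ValueError("the 'center' rule requires a centred dense scan")
        return truth_2d[window_set.origins[:, 1], window_set.origins[:, 2]].astype(np.float64)
    padded = (_pad_centered(truth_2d, w) if window_set.centered
              else _pad_for_tiling(truth_2d, w, window_set.stride))
    view = sliding_window_view(padded, (w, w))
    if window_set.centered:
        patches = view.reshape(-1, w * w)
    else:
        patches = view[::window_set.stride, ::window_set.stride].reshape(-1, w * w)
    if rule == "any":
        return (patches > 0).any(axis=1).astype(np.float64)
    if rule == "fraction":
        return patches.mean(axis=1)
    raise ValueError(f"unknown labelling rule {rule!r}")


def downsample_truth(truth_2d: np.ndarray, factor: int, rule: str = "any") -> np.ndarray:
    """Reduce a spatial ground-truth slice to the wavelet grid.

    Blocks of ``factor x factor`` spatial voxels map to one cell:
    ``any`` marks the cell if any constituent voxel is foreground,
    ``majority`` if at least half are, ``fraction`` returns the mean
    foreground occupancy (the occupancy-regression target; binary input is
    treated as 0/1, continuous occupancy in [0, 1] is averaged as is).
    """
    t = np.asarray(truth_2d, dtype=np.float64)
    r, c = t.shape
    pr, pc = (-r) % factor, (-c) % factor
    if pr or pc:
        t = np.pad(t, ((0, pr), (0, pc)))
    occ = np.clip(t, 0.0, 1.0) if np.issubdtype(np.asarray(truth_2d).dtype, np.floating) \
        else (t > 0).astype(np.float64)
    frac = occ.reshape(t.shape[0] // factor, factor,
                       t.shape[1] // factor, factor).mean(axis=(1, 3))
    if rule == "fraction":
        return frac
    if rule == "any":
        return (frac > 0).astype(np.float64)
    if rule == "majority":
        return (frac >= 0.5).astype(np.float64)
    raise ValueError(f"unknown down-sampling rule {rule!r}")


def _domain_slice(volume_2d: np.ndarray, truth_2d: np.ndarray, domain: str,
                  levels: int, occupancy_2d: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(feature slice, binary truth, fractional truth) in the working domain.

    The fractional truth comes from the continuous occupancy map when the
    ground truth carries one, otherwise from the binary mask.
    """
    frac_src = truth_2d if occupancy_2d is None else occupancy_2d
    if domain == "spatial":
        binary = (np.asarray(truth_2d) > 0).astype(np.float64)
        frac = np.clip(np.asarray(frac_src, dtype=np.float64), 0.0, 1.0) \
            if occupancy_2d is not None else binary
        return volume_2d, binary, frac
    if domain == "wavelet":
        approx = decompose_nonstandard(volume_2d, levels).approximation
        f = 2 ** levels
        return (approx, downsample_truth(truth_2d, f, "any"),
                downsample_truth(frac_src, f, "fraction"))
    raise ValueError(f"unknown domain {domain!r}")


def build_training_set(volume: PETVolume, truth: LabelVolume,
                       slice_indices, domain: str = "wavelet", levels: int = 1,
                       target: str = "presence", window: int = WINDOW_DEFAULT,
                       n_background_per_slice: int = 40,
                       hard_negative_radius: int = 2,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balanced window sample for training a per-voxel classifier.

    From every selected slice, the sample takes all windows centred on a
    foreground cell, every background cell within ``hard_negative_radius``
    of the foreground (the blur halo around a lesion, where the classifier
    must learn to say no), and ``n_background_per_slice`` randomly chosen
    far-background windows.  ``target="presence"`` gives binary centre
    labels (any-rule down-sampling in the wavelet domain);
    ``target="occupancy"`` gives the tumour fraction of the centre cell,
    for partial-volume-aware quantification.
    """
    if target not in ("presence", "occupancy"):
        raise ValueError(f"unknown target {target!r}")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for s in slice_indices:
        occ = None if truth.occupancy is None else truth.occupancy[:, :, s]
        feats, truth_bin, truth_frac = _domain_slice(
            volume.voxels[:, :, s], truth.labels[:, :, s], domain, levels, occ)
        t = truth_bin if target == "presence" else truth_frac
        ws = extract_windows(feats, window=window, slice_index=s,
                             source_domain=domain, centered=True)
        targets = label_windows(ws, t, rule="center")
        fg_2d = targets.reshape(ws.slice_shape) > 0
        pos = np.flatnonzero(targets > 0)
        if hard_negative_radius > 0 and fg_2d.any():
            halo_2d = ndimage.binary_dilation(
                fg_2d, iterations=hard_negative_radius) & ~fg_2d
        else:
            halo_2d = np.zeros_like(fg_2d)
        halo = np.flatnonzero(halo_2d.ravel())
        bg = np.flatnonzero((targets == 0) & ~halo_2d.ravel())
        take = min(n_background_per_slice, bg.size)
        chosen = np.concatenate([pos, halo, rng.choice(bg, size=take, replace=False)])
        X_parts.append(ws.windows[chosen])
        y_parts.append(targets[chosen])
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts)
    return X, y


def _check_model(model: neural.MLPModel, window: int) -> None:
    if model.layer_sizes[0] != window * window:
        raise ValueError(f"model expects {model.layer_sizes[0]} inputs, "
                         f"window {window} provides {window * window}")
    for w in model.weights:
        if not np.all(np.isfinite(w)):
            raise ValueError("model weights are not finite (untrained or diverged?)")


def segment_spatial(volume: PETVolume, model: neural.MLPModel,
                    threshold: float = 0.5,
                    window: int = WINDOW_DEFAULT) -> SegmentationResult:
    """Per-voxel segmentation by dense centred window scanning of each slice."""
    _check_model(model, window)
    scores = np.empty(volume.shape, dtype=np.float64)
    for s in range(volume.shape[2]):
        ws = extract_windows(volume.voxels[:, :, s], window=window,
                             slice_index=s, centered=True)
        scores[:, :, s] = neural.forward_batch(model, ws.windows).reshape(ws.slice_shape)
    labels = LabelVolume((scores > threshold).astype(np.int16), "spatial", 1)
    return SegmentationResult(labels, scores, "spatial")


def segment_wavelet(volume: PETVolume, model: neural.MLPModel,
                    levels: int = 1, threshold: float = 0.5,
                    window: int = WINDOW_DEFAULT) -> SegmentationResult:
    """Segmentation on the Haar approximation grid (half in-plane size per level).

    The returned label map has in-plane shape ``ceil(n / 2**levels)`` and
    ``scale_factor = 2**levels`` so quantification can map cell counts back
    to physical volume.
    """
    _check_model(model, window)
    f = 2 ** levels
    nx, ny, nz = volume.shape
    wx, wy = -(-nx // f), -(-ny // f)
    scores = np.empty((wx, wy, nz), dtype=np.float64)
    for s in range(nz):
        approx = decompose_nonstandard(volume.voxels[:, :, s], levels).approximation
        ws = extract_windows(approx, window=window, slice_index=s,
                             source_domain="wavelet", centered=True)
        scores[:, :, s] = neural.forward_batch(model, ws.windows).reshape(ws.slice_shape)
    labels = LabelVolume((scores > threshold).astype(np.int16), "wavelet", f)
    return SegmentationResult(labels, scores, "wavelet")


def _upsampled_binary(result: SegmentationResult, shape: tuple[int, int, int]) -> np.ndarray:
    lab = result.labels.binary()
    s = result.labels.scale_factor
    if s > 1:
        lab = np.repeat(np.repeat(lab, s, axis=0), s, axis=1)
    return lab[: shape[0], : shape[1], : shape[2]]


def select_best(results: list[SegmentationResult],
                truth: LabelVolume) -> SegmentationResult:
    """Pick the result with the fewest misclassified voxels against the
    validation ground truth (compared in spatial coordinates); ties go to
    the wavelet ANN route."""
    if not results:
        raise ValueError("no segmentation results to select from")
    truth_bin = truth.binary()
    errors = []
    for res in results:
        up = _upsampled_binary(res, truth_bin.shape)
        errors.append(int(np.sum(up != truth_bin)))
    best = int(np.argmin(errors))
    best_err = errors[best]
    for i, (res, err) in enumerate(zip(results, errors)):
        if err == best_err and res.pipeline_tag == "wavelet":
            best = i
            break
    return results[best]
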