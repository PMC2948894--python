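"""End-to-end studies on the synthetic phantoms.

These functions wire the stages together the way the tool's subcommands and
the reproduction scripts use them: simulate a phantom, enhance it, train a
window classifier, produce per-voxel label maps, and quantify/evaluate.

Problem sizes here are deliberately desk-scale: Levenberg-Marquardt runs for
tens of outer iterations on a balanced sample of a few hundred windows,
which is ample for the separable synthetic tasks (the trainers themselves
accept any budget).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import metrics, neural, segmenter
from .phantom import (PhantomSpec, generate_lung, generate_nema,
                      lung_default_spec, nema_default_spec, true_sphere_volume)
from .preprocess import denoise, normalize
from .volume_io import LabelVolume, PETVolume

log = logging.getLogger(__name__)

__all__ = [
    "prepare",
    "train_window_model",
    "nema_wavelet_quantification",
    "lung_confusion_study",
    "compare_trainers",
]

#: Detection threshold on occupancy-regression scores: half the smallest
#: nonzero block occupancy (one spatial voxel in a 2x2 block = 0.25).
OCCUPANCY_DETECTION_THRESHOLD = 0.125


def prepare(volume: PETVolume, method: str = "none", size: int = 3) -> PETVolume:
    """Denoise (optional) then min-max normalise to [0, 1]."""
    return normalize(denoise(volume, method=method, size=size))


def train_window_model(volume: PETVolume, truth: LabelVolume, train_slices,
                       val_slices=None, domain: str = "wavelet", levels: int = 1,
                       target: str = "presence", algorithm: str = "lm",
                       epochs: int = 30, hidden: int = 70, seed: int = 0,
                       n_background_per_slice: int = 20,
                       ) -> tuple[neural.MLPModel, neural.TrainingRecord]:
    """Train the 144-``hidden``-1 network on sampled slice windows."""
    X, y = segmenter.build_training_set(
        volume, truth, train_slices, domain=domain, levels=levels,
        target=target, n_background_per_slice=n_background_per_slice, seed=seed)
    data = (X, y)
    if val_slices:
        Xv, yv = segmenter.build_training_set(
            volume, truth, val_slices, domain=domain, levels=levels,
            target=target, n_background_per_slice=n_background_per_slice,
            seed=seed + 1)
        data = (X, y, Xv, yv)
    model = neural.init_mlp((144, hidden, 1), seed=seed)
    config = neural.TrainingConfig(algorithm=algorithm, max_epochs=epochs, seed=seed)
    model, record = neural.train(model, data, config)
    log.info("trained %s %s-domain model: %d samples, final MSE %.3g",
             algorithm, domain, X.shape[0],
             record.train_mse[-1] if record.train_mse else float("nan"))
    return model, record


@dataclass
class SphereReport:
    sphere_id: int
    tv_ml: float
    cv_ml: float
    are_percent: float
    detected: bool


def nema_wavelet_quantification(seed: int = 0, epochs: int = 25,
                                spec: PhantomSpec | None = None,
                                n_background_per_slice: int = 8,
                                ) -> dict:
    """Sphere quantification through the wavelet-domain ANN route.

    Simulates the NEMA phantom, trains an occupancy-regression network
    (targets = tumour fraction per 2x2 block) on the 70/15/15 slice split,
    scans every slice densely, and reports per-sphere computed volume from
    the clipped score sum over each detected component (partial-volume-aware
    CV) together with the ARE% against the analytic sphere volume.
    """
    spec = spec or nema_default_spec(seed=seed)
    volume, truth = generate_nema(spec)
    pre = prepare(volume, method="none")
    train_slices, val_slices, test_slices = neural.split_data(
        range(volume.shape[2]), seed=seed)
    model, record = train_window_model(
        pre, truth, train_slices, val_slices, domain="wavelet", levels=1,
        target="occupancy", algorithm="lm", epochs=epochs, seed=seed,
        n_background_per_slice=n_background_per_slice)
    result = segmenter.segment_wavelet(pre, model, levels=1,
                                       threshold=OCCUPANCY_DETECTION_THRESHOLD)
    comp, _ = ndimage.label(result.labels.binary(),
                            ndimage.generate_binary_structure(3, 1))
    reports: list[SphereReport] = []
    for i, sphere in enumerate(spec.spheres):
        sid = i + 1
        truth_cells = np.stack(
            [segmenter.downsample_truth(truth.labels[:, :, s] == sid, 2, "any")
             for s in range(volume.shape[2])], axis=2) > 0
        overlap_ids = np.unique(comp[truth_cells & (comp > 0)])
        detected = overlap_ids.size > 0
        region = np.isin(comp, overlap_ids[overlap_ids > 0]) if detected else truth_cells
        # one-cell dilation picks up fringe cells whose occupancy falls below
        # the detection threshold; raw-score summation lets small regression
        # errors in the region cancel
        region = ndimage.binary_dilation(region)
        cv = metrics.soft_volume(result.raw_scores, region, spec.voxel_size,
                                 scale_factor=2)
        tv = true_sphere_volume(sphere.inner_diameter)
        reports.append(SphereReport(sid, tv, cv, metrics.are_percent(tv, cv), detected))
    return {
        "spec": spec,
        "spheres": reports,
        "model": model,
        "record": record,
        "result": result,
        "splits": (train_slices, val_slices, test_slices),
    }


def lung_confusion_study(seed: int = 0, epochs: int = 30, eval_tumour: int = 1,
                         n_background_slices: int = 20,
                         spec: PhantomSpec | None = None) -> dict:
    """Detect one small lung tumour with the wavelet route and evaluate it.

    The network (binary presence targets, any-voxel down-sampling) is
    trained on the slices of the *other* tumours plus a random sample of
    tumour-free slices, then the held-out tumour's slice is scanned densely;
    the per-voxel confusion matrix of its 64x64 label map against the
    down-sampled ground truth is returned.  A perfectly segmented 2-voxel
    tumour leaves 4094 of the 4096 cells in the background class.
    """
    spec = spec or lung_default_spec(seed=seed)
    volume, truth = generate_lung(spec)
    pre = prepare(volume, method="none")
    nz = volume.shape[2]
    tumour_slices = {t.slice_index for t in spec.tumours}
    eval_slice = spec.tumours[eval_tumour - 1].slice_index
    train_tumour_slices = sorted(tumour_slices - {eval_slice})
    rng = np.random.default_rng(seed)
    background = [s for s in range(nz) if s not in tumour_slices]
    train_slices = train_tumour_slices + list(
        rng.choice(background, size=min(n_background_slices, len(background)),
                   replace=False))
    model, record = train_window_model(
        pre, truth, train_slices, domain="wavelet", levels=1, target="presence",
        algorithm="lm", epochs=epochs, seed=seed, n_background_per_slice=30)

    approx_slice = pre.with_voxels(pre.voxels[:, :, [eval_slice]])
    result = segmenter.segment_wavelet(approx_slice, model, levels=1, threshold=0.5)
    truth_cells = segmenter.downsample_truth(
        truth.labels[:, :, eval_slice] == eval_tumour, 2, "any")
    cm = metrics.confusion_matrix(result.labels.labels[:, :, 0], truth_cells)
    tumour_cells = int(truth_cells.sum())
    detected = int(cm.counts[0, 0]) == tumour_cells and tumour_cells > 0
    return {
        "spec": spec,
        "model": model,
        "record": record,
        "result": result,
        "eval_slice": eval_slice,
        "confusion": cm,
        "tumour_cells": tumour_cells,
        "background_correct": int(cm.counts[1, 1]),
        "map_cells": int(cm.total),
        "perfect": detected and int(cm.counts[0, 1]) == 0,
    }


def compare_trainers(X, y, epochs: int = 15, hidden: int = 70, seed: int = 0,
                     algorithms=("gd", "gda", "lm")) -> dict[str, float]:
    """Final training MSE per algorithm from a shared seed-matched init."""
    init = neural.init_mlp((X.shape[1], hidden, 1), seed=seed)
    out: dict[str, float] = {}
    for alg in algorithms:
        config = neural.TrainingConfig(algorithm=alg, max_epochs=epochs,
                                       learning_rate=0.05, seed=seed)
        trained, rec = neural.train(init.copy(), (X, y), config)
        out[alg] = rec.train_mse[-1] if rec.train_mse else neural.mse(
            neural.forward_batch(trained, X), y)
    return out
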