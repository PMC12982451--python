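"""Gradient-weighted class-activation saliency at named tap points.

For a chosen layer (tap point), the gradient of the target-class score
with respect to that layer's feature maps is averaged spatially to give
one importance weight per channel; the rectified, weight-summed feature
map is bilinearly upsampled to the input size and max-normalized to give
a nonnegative per-pixel saliency map.  Two scalar summaries quantify the
spatial organisation of a map: the fraction of saliency mass inside the
(dilated) occlusion-overlap region, and the spatial entropy of the map
treated as a probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from bosbench.errors import ValidationError
from bosbench.modelzoo import TrainedClassifier, _to_input
from bosbench.stimgen import (CirclePair, RectanglePair, StimulusSpec,
                              _circle_disk_mask)

TARGETS = ("left_owns", "right_owns")

#: Pixels by which the overlap rectangle is dilated for the mass statistic.
OVERLAP_DILATION = 3


@dataclass
class SaliencyMap:
    """Nonnegative H x W importance grid aligned to the input image."""

    values: np.ndarray
    tap: str
    target: str
    raw_max: float          # pre-normalization peak; 0 for a silent layer

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValidationError("saliency values must be nonnegative")


def _resolve_tap(model: TrainedClassifier, tap: str) -> str:
    if tap in model.taps:
        return model.taps[tap]
    if any(n.name == tap for n in model.graph.nodes):
        return tap
    raise ValidationError(
        f"unknown tap {tap!r}; named taps: {sorted(model.taps)}")


def gradcam(model: TrainedClassifier, image: np.ndarray, tap: str,
            target: str = "right_owns") -> SaliencyMap:
    """Class-activation map for one image at one tap point.

    ``target`` selects whose evidence is highlighted: the score for
    ``right_owns`` is the head logit, for ``left_owns`` its negation.
    """
    if target not in TARGETS:
        raise ValidationError(f"target must be one of {TARGETS}")
    node = _resolve_tap(model, tap)
    size = model.spec.input_size
    x = _to_input(image, size)
    if x.shape[0] != 1:
        raise ValidationError("gradcam takes a single image")
    graph = model.graph
    graph.forward(x, keep=True)
    sign = 1.0 if target == "right_owns" else -1.0
    for p in graph.params():
        p.grad[...] = 0.0
    graph.gradients = {}
    graph.backward(np.array([[sign]], dtype=np.float32), keep=True)
    acts = graph.activations[node][0]          # (C, h, w)
    grads = graph.gradients[node][0]
    weights = grads.mean(axis=(1, 2))          # channel importances
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    zoom = (size / cam.shape[0], size / cam.shape[1])
    cam = ndimage.zoom(cam.astype(np.float64), zoom, order=1)
    cam = np.maximum(cam, 0.0)
    raw_max = float(cam.max())
    if raw_max > 0:
        cam = cam / raw_max
    return SaliencyMap(values=cam, tap=node, target=target, raw_max=raw_max)


# ---------------------------------------------------------------------------
# scalar summaries


def overlap_mask(spec: StimulusSpec,
                 dilation: int = OVERLAP_DILATION) -> np.ndarray:
    """Boolean mask of the occlusion-overlap region, dilated."""
    c = spec.constraints
    shape = (c.height, c.width)
    g = spec.geometry
    m = np.zeros(shape, dtype=bool)
    if isinstance(g, RectanglePair):
        x, y, w, h = g.overlap_box()
        m[max(0, y - dilation):y + h + dilation,
          max(0, x - dilation):x + w + dilation] = True
    elif isinstance(g, CirclePair):
        lens = (_circle_disk_mask(shape, g.cxL, g.cyL, g.rL + 0.5)
                & _circle_disk_mask(shape, g.cxR, g.cyR, g.rR + 0.5))
        m = ndimage.binary_dilation(lens, iterations=dilation)
    else:  # pragma: no cover
        raise ValidationError("unknown geometry type")
    return m


def overlap_mass_fraction(smap: SaliencyMap, spec: StimulusSpec) -> float:
    """Fraction of total saliency mass inside the dilated overlap region."""
    total = smap.values.sum()
    if total == 0:
        return 0.0
    return float(smap.values[overlap_mask(spec)].sum() / total)


def spatial_entropy(smap: SaliencyMap) -> float:
    """Entropy (nats) of the map normalized to a spatial distribution.

    An identically zero map carries no spatial information and is scored
    as maximally spread: log(H * W).
    """
    v = smap.values
    total = v.sum()
    if total == 0:
        return float(np.log(v.size))
    p = (v / total).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# sweep protocols


def depth_sweep(model: TrainedClassifier, images: np.ndarray,
                specs: list[StimulusSpec],
                taps: tuple[str, ...] = ("shallow", "mid", "deep"),
                target_mode: str = "true",
                return_maps: bool = False):
    """Saliency maps and summaries across network depth.

    ``target_mode`` is ``true`` (visualize the ground-truth class) or
    ``predicted``.  Returns a tidy frame with one row per (image, tap)
    carrying the overlap mass fraction and spatial entropy; with
    ``return_maps`` also the map objects.
    """
    if len(images) == 0:
        raise ValidationError("need at least one image")
    rows, maps = [], []
    for i, (img, spec) in enumerate(zip(images, specs)):
        if target_mode == "true":
            target = spec.label
        else:
            p = model.predict_proba(img[None])[0]
            target = "right_owns" if p >= 0.5 else "left_owns"
        for tap in taps:
            smap = gradcam(model, img, tap, target)
            rows.append(dict(image=i, tap=tap, node=smap.tap, target=target,
                             overlap_mass=overlap_mass_fraction(smap, spec),
                             entropy=spatial_entropy(smap)))
            if return_maps:
                maps.append(smap)
    frame = pd.DataFrame(rows)
    return (frame, maps) if return_maps else frame


def gap_sweep_saliency(model: TrainedClassifier,
                       suites: dict[str, tuple[np.ndarray, list[StimulusSpec]]],
                       taps: tuple[str, ...] = ("shallow", "mid", "deep"),
                       ) -> pd.DataFrame:
    """Mean saliency summaries per gap level.

    ``suites`` maps a gap-level label to ``(images, specs)`` for that
    level (the same base geometries should be used across levels).
    Returns one row per (gap level, tap) with mean entropy and mean
    overlap-mass fraction.
    """
    rows = []
    for level, (images, specs) in suites.items():
        frame = depth_sweep(model, images, specs, taps=taps)
        agg = frame.groupby("tap", sort=False).agg(
            entropy=("entropy", "mean"),
            overlap_mass=("overlap_mass", "mean")).reset_index()
        agg.insert(0, "gap_n", level)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def save_heatmap(smap: SaliencyMap, path, image: np.ndarray | None = None
                 ) -> None:
    """Write the map as a PNG heatmap, optionally overlaid on the stimulus."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3), dpi=100)
    if image is not None:
        ax.imshow(np.asarray(image), cmap="gray", vmin=0, vmax=255)
        ax.imshow(smap.values, cmap="jet", alpha=0.5)
    else:
        ax.imshow(smap.values, cmap="jet")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
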