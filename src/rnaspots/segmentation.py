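"""DAPI nuclei segmentation.

The default backend ("quantise-watershed") follows the classic recipe
for widefield DAPI images in which nuclei sit at different depths and
are therefore unequally bright:

1. smooth the DAPI channel with a Gaussian (sigma 7 px by default) to
   suppress intensity inhomogeneities;
2. multi-level Otsu quantisation into background plus three foreground
   intensity tiers, so dim and bright nuclei are both captured;
3. watershed splitting of touching nuclei, adapted to the detected
   tiers: seeds are regional maxima of the smoothed image extracted
   per tier, so a dim nucleus next to a bright one still contributes
   its own seed;
4. halo removal: the heavy smoothing needed for quantisation spreads
   every nucleus outward, so each watershed region is gated back to
   the pixels whose lightly-smoothed DAPI intensity clears the same
   background threshold — boundaries come from the image, tiers and
   splitting from the smoothed version;
5. removal of components smaller than ``min_area`` and contiguous
   relabelling.

Alternative backends (e.g. a star-convex-polygon deep-learning
segmenter) can be plugged in through :func:`register_backend`; only the
interface is provided here, no trained model is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu
from skimage.morphology import local_maxima
from skimage.segmentation import relabel_sequential, watershed

from .detection import DAPI_CHANNEL, ChannelImage

__all__ = [
    "SegmentationParams",
    "NucleusLabelMap",
    "segment_nuclei",
    "register_backend",
    "get_backend",
    "available_backends",
]

#: Number of foreground intensity tiers the quantisation detects.
N_LEVELS = 3


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the nuclei segmentation stage.

    ``dapi_sigma`` is the smoothing width in pixels (default 7);
    ``min_area`` the minimum nucleus area in px^2 (default 150, suited
    to 63x fields); ``backend`` names a registered segmenter.
    """

    dapi_sigma: float = 7.0
    min_area: int = 150
    backend: str = "quantise-watershed"
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        if self.dapi_sigma <= 0:
            raise ValueError("dapi_sigma must be > 0")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.n_levels != N_LEVELS:
            raise ValueError(f"n_levels is fixed at {N_LEVELS}")


class NucleusLabelMap:
    """Integer-labelled nuclei: 0 = background, 1..n = nuclei.

    Labels are 4-connected, contiguous from 1, and each satisfies
    ``area >= min_area`` of the params that produced the map.
    """

    def __init__(self, labels: np.ndarray):
        labels = np.asarray(labels)
        if labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32)

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def areas(self) -> dict[int, int]:
        """Per-label pixel area."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Per-label centroid as (x, y) in pixel coordinates."""
        ids = np.arange(1, self.n_nuclei + 1)
        if len(ids) == 0:
            return {}
        cy_cx = ndi.center_of_mass(np.ones_like(self.labels), self.labels, ids)
        return {int(i): (float(c[1]), float(c[0])) for i, c in zip(ids, cy_cx)}


Segmenter = Callable[[ChannelImage, SegmentationParams], NucleusLabelMap]

_BACKENDS: dict[str, Segmenter] = {}


def register_backend(name: str, segmenter: Segmenter) -> None:
    """Register a segmentation backend under ``name``.

    The callable must map a DAPI :class:`ChannelImage` plus params to a
    :class:`NucleusLabelMap` honouring its invariants.  Registering a
    name twice is an error.
    """
    if name in _BACKENDS:
        raise ValueError(f"backend {name!r} is already registered")
    _BACKENDS[name] = segmenter


def get_backend(name: str) -> Segmenter:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown segmentation backend {name!r}; "
            f"available: {sorted(_BACKENDS)}"
        ) from None


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def _filter_min_area(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Drop components below min_area and relabel contiguously from 1."""
    if labels.max() == 0:
        return labels
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    mask = np.isin(labels, keep)
    out = np.where(mask, labels, 0)
    out, _, _ = relabel_sequential(out)
    return out.astype(np.int32)


def _tier_seeds(smooth: np.ndarray, tiers: np.ndarray, n_levels: int) -> np.ndarray:
    """Watershed seeds: regional maxima of the smoothed image per tier.

    Maxima are detected with 8-connectivity inside each foreground tier
    separately, then merged; maxima of different tiers that touch are
    fused into one seed by the final connected-component labelling.
    """
    seed_mask = np.zeros(smooth.shape, dtype=bool)
    maxima = local_maxima(smooth, connectivity=2)
    for level in range(1, n_levels + 1):
        seed_mask |= maxima & (tiers == level)
    seeds, _ = ndi.label(seed_mask, structure=np.ones((3, 3), dtype=int))
    return seeds


def _quantise_watershed(dapi: ChannelImage, params: SegmentationParams) -> NucleusLabelMap:
    smooth = ndi.gaussian_filter(dapi.pixels, params.dapi_sigma, mode="reflect")
    if np.ptp(smooth) == 0:
        return NucleusLabelMap(np.zeros(smooth.shape, dtype=np.int32))

    # 3 thresholds -> background + three foreground intensity tiers
    try:
        thresholds = threshold_multiotsu(smooth, classes=params.n_levels + 1)
    except ValueError:
        # fewer distinct grey levels than classes: fall back to a single
        # Otsu-like split at the midrange
        thresholds = np.array([0.5 * (smooth.min() + smooth.max())])
    tiers = np.digitize(smooth, thresholds)
    mask = tiers > 0
    if not mask.any():
        return NucleusLabelMap(np.zeros(smooth.shape, dtype=np.int32))

    seeds = _tier_seeds(smooth, tiers, params.n_levels)
    seeds = np.where(mask, seeds, 0)
    if seeds.max() == 0:
        labels, _ = ndi.label(mask)  # no interior maxima: plain components
    else:
        labels = watershed(-smooth, markers=seeds, mask=mask, connectivity=1)
        # mask pixels unreachable from any seed: keep as own components
        orphan = mask & (labels == 0)
        if orphan.any():
            extra, n_extra = ndi.label(orphan)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)

    # gate each region on the barely-smoothed image: the sigma-7 blur
    # dilates every nucleus by several pixels, and those halo pixels sit
    # below the background threshold in the original image
    light = ndi.gaussian_filter(dapi.pixels, 1.0, mode="reflect")
    labels = np.where(light > thresholds[0], labels, 0)
    labels = _largest_component_per_label(labels)

    labels = _filter_min_area(labels, params.min_area)
    return NucleusLabelMap(labels)


def _largest_component_per_label(labels: np.ndarray) -> np.ndarray:
    """Keep each label 4-connected by retaining its largest piece."""
    out = np.zeros_like(labels)
    four = ndi.generate_binary_structure(2, 1)
    for lab in np.unique(labels[labels > 0]):
        comp, n = ndi.label(labels == lab, structure=four)
        if n == 1:
            out[comp == 1] = lab
            continue
        sizes = ndi.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
        out[comp == int(np.argmax(sizes)) + 1] = lab
    return out


def _star_convex_stub(dapi: ChannelImage, params: SegmentationParams) -> NucleusLabelMap:
    raise NotImplementedError(
        "the 'star-convex' backend is an interface for an external "
        "star-convex-polygon segmenter (e.g. a StarDist-style model); "
        "register an implementation with register_backend() to use it"
    )


register_backend("quantise-watershed", _quantise_watershed)
register_backend("star-convex", _star_convex_stub)


def segment_nuclei(dapi: ChannelImage, params: SegmentationParams | None = None) -> NucleusLabelMap:
    """Segment DAPI nuclei into a label map using the configured backend.

    A blank DAPI channel yields an empty label map (0 nuclei), not an
    error.
    """
    params = params or SegmentationParams()
    if dapi.channel_id != DAPI_CHANNEL:
        raise ValueError(f"nuclei segmentation expects channel {DAPI_CHANNEL} (DAPI)")
    backend = get_backend(params.backend)
    out = backend(dapi, params)
    if out.shape != dapi.shape:
        raise ValueError("backend returned a label map of wrong shape")
    return out
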