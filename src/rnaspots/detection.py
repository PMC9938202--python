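"""Single-molecule dot detection on multiplex FISH probe channels.

Each target mRNA molecule appears as a diffraction-limited bright dot in
one fluorescence channel.  Detection is a two-stage process:

1.  A difference-of-Gaussians (DoG) band-pass: the image blurred with a
    small Gaussian (``sigma_small``, default 0.5 px, signal enhancement)
    minus the same image blurred with a large Gaussian (``sigma_large``,
    default 3 px, background estimate).
2.  Local-maxima detection on the filtered image with a per-channel
    intensity threshold and greedy non-maximum suppression so that no
    two retained dots are closer than ``min_separation`` pixels.

Probe channels are conventionally numbered 1, 2 and 4; channel 3 is the
DAPI nuclear counterstain and is handled by :mod:`rnaspots.segmentation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ChannelImage",
    "DoGParams",
    "SpotSet",
    "dog_filter",
    "detect_spots",
]

#: Channel index of the DAPI nuclear counterstain in a 4-channel field.
DAPI_CHANNEL = 3

#: Probe channels carrying single-mRNA dots.
PROBE_CHANNELS = (1, 2, 4)


@dataclass(frozen=True)
class ChannelImage:
    """A single 2-D channel of a multiplex field.

    Coordinates are 0-based with ``x`` the column and ``y`` the row.
    """

    pixels: np.ndarray
    channel_id: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("ChannelImage requires a non-empty 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians parameters (defaults 0.5 px and 3 px)."""

    sigma_small: float = 0.5
    sigma_large: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_small < self.sigma_large:
            raise ValueError(
                "require 0 < sigma_small < sigma_large, got "
                f"{self.sigma_small} and {self.sigma_large}"
            )


@dataclass
class SpotSet:
    """Detected dots for one or more channels of one field.

    ``spots`` is a float array of shape (n, 4) with columns
    ``(x, y, channel_id, filtered_intensity)``; x and y are integer
    pixel positions of the detected maxima.  ``threshold_used`` records
    the per-channel detection threshold (th1, th2, th4).
    """

    spots: np.ndarray
    threshold_used: dict[int, float] = field(default_factory=dict)
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.spots, dtype=float)
        if arr.size == 0:
            arr = np.empty((0, 4), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("spots must be an (n, 4) array of (x, y, channel, intensity)")
        self.spots = arr

    def __len__(self) -> int:
        return len(self.spots)

    def for_channel(self, channel_id: int) -> np.ndarray:
        """Rows belonging to one channel."""
        return self.spots[self.spots[:, 2] == channel_id]

    @property
    def xy(self) -> np.ndarray:
        return self.spots[:, :2]

    @staticmethod
    def concatenate(parts: list["SpotSet"]) -> "SpotSet":
        if not parts:
            return SpotSet(np.empty((0, 4)))
        thresholds: dict[int, float] = {}
        for p in parts:
            thresholds.update(p.threshold_used)
        shape = next((p.image_shape for p in parts if p.image_shape), None)
        return SpotSet(
            np.vstack([p.spots for p in parts]),
            threshold_used=thresholds,
            image_shape=shape,
        )


def dog_filter(img: ChannelImage, params: DoGParams = DoGParams()) -> ChannelImage:
    """Band-pass an image: ``blur(img, sigma_small) - blur(img, sigma_large)``.

    Both blurs use normalised sampled Gaussian kernels with reflective
    (symmetric) boundary handling, so constant images map exactly to
    zero.  The output may be negative.
    """
    px = img.pixels
    small = ndi.gaussian_filter(px, params.sigma_small, mode="reflect")
    large = ndi.gaussian_filter(px, params.sigma_large, mode="reflect")
    return ChannelImage(small - large, img.channel_id)


def _local_maxima(filtered: np.ndarray, threshold: float) -> np.ndarray:
    """Integer (y, x) positions of 8-connected local maxima above threshold.

    Maxima on the 1-px image border are discarded: their neighbourhood is
    incomplete.
    """
    footprint = np.ones((3, 3), dtype=bool)
    maxed = ndi.maximum_filter(filtered, footprint=footprint, mode="reflect")
    is_max = (filtered == maxed) & (filtered > threshold)
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False
    return np.argwhere(is_max)


def detect_spots(
    filtered: ChannelImage,
    threshold: float,
    min_separation: float = 2.0,
) -> SpotSet:
    """Detect dots as thresholded local maxima with greedy suppression.

    Candidate dots are 8-connected local maxima of the (DoG-filtered)
    image with value strictly above ``threshold``.  Candidates are then
    pruned greedily in decreasing-intensity order: a candidate closer
    than ``min_separation`` (Euclidean) to an already-retained dot is
    dropped, so the brighter of two conflicting detections wins.

    An empty :class:`SpotSet` is a valid result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    px = filtered.pixels
    yx = _local_maxima(px, threshold)
    if len(yx) == 0:
        return SpotSet(
            np.empty((0, 4)),
            threshold_used={filtered.channel_id: float(threshold)},
            image_shape=px.shape,
        )
    intensities = px[yx[:, 0], yx[:, 1]]
    # stable order: intensity desc, then (y, x) for determinism on ties
    order = np.lexsort((yx[:, 1], yx[:, 0], -intensities))
    yx = yx[order]
    intensities = intensities[order]

    kept: list[int] = []
    kept_pos = np.empty((len(yx), 2), dtype=float)
    for i, pos in enumerate(yx):
        if kept:
            d2 = np.sum((kept_pos[: len(kept)] - pos) ** 2, axis=1)
            if np.any(d2 < min_separation**2):
                continue
        kept_pos[len(kept)] = pos
        kept.append(i)

    rows = np.column_stack(
        [
            yx[kept, 1].astype(float),  # x = column
            yx[kept, 0].astype(float),  # y = row
            np.full(len(kept), float(filtered.channel_id)),
            intensities[kept],
        ]
    )
    return SpotSet(
        rows,
        threshold_used={filtered.channel_id: float(threshold)},
        image_shape=px.shape,
    )
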