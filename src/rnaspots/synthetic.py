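"""Synthetic multiplex FISH fields and behavioural cohorts with ground truth.

No public imaging dataset accompanies the quantification problem this
package addresses, so every pipeline stage is exercised against
simulated data whose ground truth is known exactly:

* :func:`generate_field` renders a 4-channel field — elliptical DAPI
  nuclei in three brightness tiers (nuclei sit at different depths, so
  not all are equally bright), optionally placed in touching pairs to
  exercise watershed splitting, and diffraction-limited probe dots
  (2-D Gaussians) with Poisson per-cell counts plus additive noise —
  together with the true label map, per-cell dot counts and dot
  coordinates.

* :func:`generate_behavior` simulates a schedule-induced-polydipsia
  cohort: an animal x session water-intake table in which a planted
  fraction of animals escalates its drinking after an onset session,
  giving a known High-drinker set for phenotyping oracles.

Dots owned by a nucleus are placed inside that nucleus' mask, so the
generator's ownership is valid under the pipeline's 10-pixel
assignment rule; a configurable fraction of dots is placed far
(> 10 px) from every nucleus to exercise the unassigned branch.
All randomness derives from the spec's seed: identical spec, identical
output, bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import ConfigurationError, PlacementError
from .stats import BehaviorTable

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "MultiplexField",
    "BehaviorSpec",
    "generate_field",
    "generate_behavior",
]

#: Channel order of the image stack: probe-1, probe-2, DAPI, probe-4.
CHANNEL_IDS = (1, 2, 3, 4)
PROBE_CHANNEL_IDS = (1, 2, 4)


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic 4-channel field.

    ``per_channel_lambda`` gives the mean true dots per cell for probe
    channels (1, 2, 4).  ``brightness_tiers`` are the three relative
    DAPI intensity levels (strictly increasing), scaled by
    ``dapi_amplitude``.  ``touching_fraction`` of the nuclei are placed
    in touching pairs.  ``far_dot_fraction`` of each channel's dots is
    placed more than 10 px from every nucleus.
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 20
    nucleus_radius_range: tuple[float, float] = (18.0, 28.0)
    nucleus_eccentricity_range: tuple[float, float] = (0.0, 0.6)
    brightness_tiers: tuple[float, float, float] = (0.4, 0.7, 1.0)
    dapi_amplitude: float = 200.0
    touching_fraction: float = 0.0
    per_channel_lambda: tuple[float, float, float] = (5.0, 5.0, 5.0)
    dot_sigma: float = 1.0
    dot_amplitude: float = 100.0
    dot_min_separation: float = 4.0
    far_dot_fraction: float = 0.05
    background_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not 0 < lo <= hi:
            raise ValueError("nucleus radii must be positive with min <= max")
        elo, ehi = self.nucleus_eccentricity_range
        if not 0 <= elo <= ehi < 1:
            raise ValueError("eccentricity range must lie in [0, 1)")
        t = self.brightness_tiers
        if not (len(t) == 3 and t[0] < t[1] < t[2]):
            raise ValueError("brightness_tiers must be three strictly increasing levels")
        if any(lam < 0 for lam in self.per_channel_lambda):
            raise ValueError("per-channel lambdas must be >= 0")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must be in [0, 1]")
        if not 0 <= self.far_dot_fraction < 1:
            raise ValueError("far_dot_fraction must be in [0, 1)")
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be >= 0")


@dataclass
class MultiplexField:
    """A 4-channel image field plus identifying metadata.

    ``image`` has shape (4, height, width) in the channel order
    probe-1, probe-2, DAPI, probe-4.
    """

    image: np.ndarray
    field_id: str = "field"
    animal_id: str | None = None
    field_index: int | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 3 or img.shape[0] != 4:
            raise ValueError("image must have shape (4, height, width)")
        self.image = img

    def channel(self, channel_id: int):
        from .detection import ChannelImage

        if channel_id not in CHANNEL_IDS:
            raise ValueError(f"channel_id must be one of {CHANNEL_IDS}")
        return ChannelImage(self.image[CHANNEL_IDS.index(channel_id)], channel_id)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[1:]


@dataclass
class GroundTruth:
    """Exact ground truth for one synthetic field.

    ``label_map``: integer nucleus labels (0 = background).
    ``true_counts``: DataFrame indexed by nucleus label with columns
    ``count_ch1, count_ch2, count_ch4`` — the dots owned by each cell.
    ``dot_positions``: DataFrame with columns ``x, y, channel, owner``
    (owner 0 means no owning nucleus).
    """

    label_map: np.ndarray
    true_counts: pd.DataFrame
    dot_positions: pd.DataFrame

    def counts_for_channel(self, channel_id: int) -> pd.Series:
        return self.true_counts[f"count_ch{channel_id}"]


# ---------------------------------------------------------------------------
# field generation


def _ellipse_radius(a: float, b: float, phi: float, theta: float) -> float:
    """Boundary radius of a rotated ellipse along direction theta."""
    psi = theta - phi
    return a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator):
    """Choose centres and shapes; returns list of (cx, cy, a, b, phi, tier)."""
    n = spec.n_nuclei
    n_pairs = int(round(spec.touching_fraction * n / 2))
    lo, hi = spec.nucleus_radius_range
    elo, ehi = spec.nucleus_eccentricity_range

    # shapes first so geometry is independent of placement retries
    a_ax = rng.uniform(lo, hi, size=n)
    ecc = rng.uniform(elo, ehi, size=n)
    b_ax = a_ax * np.sqrt(1 - ecc**2)
    phi = rng.uniform(0, math.pi, size=n)
    tiers = (np.arange(n) % 3) + 1
    rng.shuffle(tiers)

    margin = hi + 2
    if spec.width <= 2 * margin or spec.height <= 2 * margin:
        if n > 0:
            raise PlacementError("field too small for the requested nucleus radii")
    placed: list[tuple[float, float]] = []

    def collides(cx: float, cy: float, a: float, partner: int | None = None) -> bool:
        for j, (px, py) in enumerate(placed):
            if partner is not None and j == partner:
                continue
            # free-standing nuclei stay separated by more than the DAPI
            # smoothing scale, so "non-touching" survives segmentation
            if math.hypot(cx - px, cy - py) < a + a_ax[j] + 10:
                return True
        return False

    def place_free(i: int) -> tuple[float, float]:
        for _ in range(400):
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(margin, spec.height - margin)
            if not collides(cx, cy, a_ax[i]):
                return cx, cy
        raise PlacementError(
            f"could not place nucleus {i + 1}/{n}: field too crowded"
        )

    order = list(range(n))
    i = 0
    pair_of: dict[int, int] = {}
    while i + 1 < 2 * n_pairs:
        pair_of[order[i]] = order[i + 1]
        i += 2

    centres = np.zeros((n, 2))
    done = np.zeros(n, dtype=bool)
    for i in range(n):
        if done[i]:
            continue
        cx, cy = place_free(i)
        centres[i] = (cx, cy)
        placed.append((cx, cy))
        done[i] = True
        j = pair_of.get(i)
        if j is None:
            continue
        # touching partner: centre distance slightly under the sum of the
        # boundary radii along the joining direction (<= 30% overlap)
        for _ in range(400):
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.92 * (
                _ellipse_radius(a_ax[i], b_ax[i], phi[i], theta)
                + _ellipse_radius(a_ax[j], b_ax[j], phi[j], theta + math.pi)
            )
            jx, jy = cx + d * math.cos(theta), cy + d * math.sin(theta)
            if (
                margin <= jx <= spec.width - margin
                and margin <= jy <= spec.height - margin
                and not collides(jx, jy, a_ax[j], partner=len(placed) - 1)
            ):
                centres[j] = (jx, jy)
                placed.append((jx, jy))
                done[j] = True
                break
        else:
            raise PlacementError("could not place touching partner nucleus")

    return [
        (centres[i, 0], centres[i, 1], a_ax[i], b_ax[i], phi[i], int(tiers[i]))
        for i in range(n)
    ]


def _rasterise(spec: FieldSpec, nuclei) -> tuple[np.ndarray, np.ndarray]:
    """Label map from ellipse parameters; contested pixels (touching
    pairs) go to the nucleus whose normalised ellipse distance is
    smaller.  Also returns that squared normalised distance (in [0, 1]
    inside nuclei) for the radial DAPI brightness profile."""
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)
    best = np.full((h, w), np.inf)
    yy, xx = np.mgrid[0:h, 0:w]
    for lab, (cx, cy, a, b, phi, _tier) in enumerate(nuclei, start=1):
        r = int(math.ceil(a)) + 2
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        nd = (u / a) ** 2 + (v / b) ** 2
        inside = nd <= 1.0
        better = inside & (nd < best[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][better] = lab
        best[y0:y1, x0:x1][better] = nd[better]
    return labels, best


def _sample_dot_positions(
    rng: np.random.Generator,
    candidate_yx: np.ndarray,
    n_wanted: int,
    taken_xy: list[tuple[float, float]],
    min_sep: float,
) -> list[tuple[int, int]]:
    """Pick up to ``n_wanted`` candidate pixels at least min_sep apart
    from each other and from ``taken_xy`` (same channel)."""
    out: list[tuple[int, int]] = []
    if len(candidate_yx) == 0:
        return out
    min_sep2 = min_sep**2
    for _ in range(n_wanted):
        for _try in range(100):
            y, x = candidate_yx[rng.integers(len(candidate_yx))]
            if all((x - tx) ** 2 + (y - ty) ** 2 >= min_sep2 for tx, ty in taken_xy):
                out.append((int(x), int(y)))
                taken_xy.append((float(x), float(y)))
                break
    return out


def _render_dot(channel: np.ndarray, x: int, y: int, amp: float, sigma: float) -> None:
    h, w = channel.shape
    r = max(2, int(math.ceil(4 * sigma)))
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    channel[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def generate_field(spec: FieldSpec) -> tuple[MultiplexField, GroundTruth]:
    """Render one synthetic field and its exact ground truth.

    Deterministic given ``spec.seed``.  Raises :class:`PlacementError`
    if the requested nuclei cannot be placed after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_nuclei(spec, rng)
    labels, norm_dist = _rasterise(spec, nuclei)

    image = np.zeros((4, spec.height, spec.width), dtype=float)

    # DAPI (channel 3): per-tier brightness with a radial dome profile
    # (projected chromatin is brightest at the nucleus centre; a flat
    # disc would leave the watershed no intensity peak to seed from),
    # plus blurred edges
    dapi = np.zeros((spec.height, spec.width))
    for lab, (_cx, _cy, _a, _b, _phi, tier) in enumerate(nuclei, start=1):
        m = labels == lab
        dome = 1.0 - 0.5 * norm_dist[m]
        dapi[m] = spec.brightness_tiers[tier - 1] * spec.dapi_amplitude * dome
    image[2] = ndi.gaussian_filter(dapi, 1.5, mode="reflect")

    # probe dots
    n = len(nuclei)
    counts = np.zeros((n, 3), dtype=int)
    dot_rows: list[tuple[int, int, int, int]] = []  # x, y, channel, owner

    # planted-unassigned dots sit well clear of the nuclei: beyond the
    # 10-px attribution radius plus the halo a smoothed segmentation can
    # add around the true ellipse, so their label is unambiguous
    far_ok = ndi.distance_transform_edt(labels == 0) > 25 if n else labels == 0
    far_ok[:2, :] = far_ok[-2:, :] = False  # keep dots off the image border,
    far_ok[:, :2] = far_ok[:, -2:] = False  # where maxima are ill-defined
    far_candidates = np.argwhere(far_ok)

    label_pixels = {
        lab: np.argwhere(labels == lab) for lab in range(1, n + 1)
    }
    for ci, channel_id in enumerate(PROBE_CHANNEL_IDS):
        taken: list[tuple[float, float]] = []
        plane = image[CHANNEL_IDS.index(channel_id)]
        lam = spec.per_channel_lambda[ci]
        for lab in range(1, n + 1):
            wanted = int(rng.poisson(lam))
            pts = _sample_dot_positions(
                rng, label_pixels[lab], wanted, taken, spec.dot_min_separation
            )
            counts[lab - 1, ci] = len(pts)
            for x, y in pts:
                dot_rows.append((x, y, channel_id, lab))
                _render_dot(plane, x, y, spec.dot_amplitude, spec.dot_sigma)
        n_owned = int(counts[:, ci].sum())
        n_far = int(round(spec.far_dot_fraction * n_owned))
        far_pts = _sample_dot_positions(
            rng, far_candidates, n_far, taken, spec.dot_min_separation
        )
        for x, y in far_pts:
            dot_rows.append((x, y, channel_id, 0))
            _render_dot(plane, x, y, spec.dot_amplitude, spec.dot_sigma)

    if spec.background_sigma > 0:
        image += rng.normal(0, spec.background_sigma, size=image.shape)

    true_counts = pd.DataFrame(
        counts,
        index=pd.RangeIndex(1, n + 1, name="nucleus_id"),
        columns=[f"count_ch{c}" for c in PROBE_CHANNEL_IDS],
    )
    dot_positions = pd.DataFrame(
        dot_rows, columns=["x", "y", "channel", "owner"]
    ).astype(int)
    field = MultiplexField(image, field_id=f"synthetic-{spec.seed}")
    return field, GroundTruth(labels, true_counts, dot_positions)


# ---------------------------------------------------------------------------
# behavioural cohort


@dataclass(frozen=True)
class BehaviorSpec:
    """Parameters of a synthetic polydipsia cohort.

    A planted fraction of animals (``hd_fraction``) escalates its daily
    water intake linearly by ``escalation_rate`` mL/session from
    ``escalation_onset_session`` onwards; all intakes get i.i.d.
    Gaussian noise (sd ``noise_sd``) and are clipped at 0.
    """

    n_animals: int = 48
    n_sessions: int = 21
    baseline_sessions: int = 2
    hd_fraction: float = 0.25
    escalation_onset_session: int = 7
    escalation_rate: float = 1.5
    base_intake: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hd_fraction <= 1:
            raise ValueError("hd_fraction must be in [0, 1]")
        if self.n_sessions < self.baseline_sessions:
            raise ConfigurationError("n_sessions must be >= baseline_sessions")
        if not 1 <= self.escalation_onset_session <= self.n_sessions:
            raise ValueError("escalation_onset_session out of session range")


def generate_behavior(spec: BehaviorSpec) -> BehaviorTable:
    """Simulate an animal x session water-intake table.

    The returned table carries the planted escalator IDs in
    ``planted_escalators`` as the phenotyping oracle.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_esc = int(round(spec.hd_fraction * spec.n_animals))
    animals = [f"rat{i + 1:03d}" for i in range(spec.n_animals)]
    escalators = sorted(rng.choice(animals, size=n_esc, replace=False).tolist())

    sessions = np.arange(1, spec.n_sessions + 1)
    ramp = np.maximum(0, sessions - spec.escalation_onset_session) * spec.escalation_rate
    intake = np.full((spec.n_animals, spec.n_sessions), spec.base_intake)
    esc_idx = [animals.index(a) for a in escalators]
    intake[esc_idx] += ramp
    if spec.noise_sd > 0:
        intake += rng.normal(0, spec.noise_sd, size=intake.shape)
    intake = np.clip(intake, 0, None)

    frame = pd.DataFrame(intake, index=pd.Index(animals, name="animal_id"), columns=sessions)
    return BehaviorTable(
        intake=frame,
        baseline_sessions=spec.baseline_sessions,
        final_window=3,
        planted_escalators=escalators,
    )
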