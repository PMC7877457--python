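"""Round alignment, illumination correction, spot enhancement, segmentation.

The first two stages of the multiplexed pipeline: per-round translational
registration against the MAP2 channel, subtraction of a smooth morphological
background, white top-hat spot enhancement, robust-background thresholding
(computed on untreated images and reused everywhere so both treatment groups
are segmented identically), watershed declumping of puncta, and DAPI/MAP2
compartment masks.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import (
    disk,
    erosion,
    opening,
    remove_small_objects,
    white_tophat as sk_white_tophat,
)
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .synthetic_data import MultiplexedField

logger = logging.getLogger(__name__)

#: default structuring-element radius of the illumination background opening
ILLUMINATION_RADIUS = 20
#: default structuring-element radius of the puncta top-hat
TOPHAT_RADIUS = 4


class AlignmentError(RuntimeError):
    """Registration cannot be estimated (featureless reference channel)."""


# --------------------------------------------------------------------------
# Alignment
# --------------------------------------------------------------------------


def estimate_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer translation that was applied to ``moving`` relative to ``reference``.

    Estimated by cross-correlation (FFT phase correlation restricted to whole
    pixels).  The returned ``(dr, dc)`` is the acquisition displacement, i.e.
    shifting ``moving`` by ``(-dr, -dc)`` registers it onto ``reference``.
    """
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise AlignmentError("featureless image: cannot estimate shift")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=1, normalization=None
    )
    # phase_cross_correlation returns the shift to apply to `moving` to match
    # `reference`; the acquisition displacement is its negation
    return (-int(round(shift[0])), -int(round(shift[1])))


def apply_shift(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Undo an acquisition displacement (integer translation, zero fill)."""
    dr, dc = shift
    if dr == 0 and dc == 0:
        return image.copy()
    out = np.zeros_like(image)
    h, w = image.shape
    rs_src = slice(max(0, dr), min(h, h + dr))
    cs_src = slice(max(0, dc), min(w, w + dc))
    rs_dst = slice(max(0, -dr), min(h, h - dr))
    cs_dst = slice(max(0, -dc), min(w, w - dc))
    out[rs_dst, cs_dst] = image[rs_src, cs_src]
    return out


def align_rounds(field: MultiplexedField, reference_round: int = 0) -> MultiplexedField:
    """Register every round onto the reference round using the MAP2 channel.

    Each round re-images MAP2, so per-round shifts are estimated from MAP2
    and the same correction is applied to all channels of that round.
    Returns a new field with aligned images and the estimated shifts
    recorded in ``field.shifts``.
    """
    map2_slots = {
        rnd: slot
        for slot, target in field.channel_map.items()
        if target == "MAP2"
        for rnd in [slot[0]]
    }
    for rnd in field.rounds():
        if rnd not in map2_slots:
            raise AlignmentError(f"round {rnd} has no MAP2 channel to align with")
    reference = field.images[map2_slots[reference_round]]
    shifts: dict[int, tuple[int, int]] = {}
    for rnd in field.rounds():
        if rnd == reference_round:
            shifts[rnd] = (0, 0)
            continue
        moving = field.images[map2_slots[rnd]]
        try:
            shifts[rnd] = estimate_shift(reference, moving)
        except AlignmentError as exc:
            raise AlignmentError(f"round {rnd}: {exc}") from None
    images = {
        (rnd, ch): apply_shift(img, shifts[rnd])
        for (rnd, ch), img in field.images.items()
    }
    return dataclasses.replace(field, images=images, shifts=shifts)


# --------------------------------------------------------------------------
# Illumination correction and spot enhancement
# --------------------------------------------------------------------------


def correct_illumination(image: np.ndarray, radius: int = ILLUMINATION_RADIUS) -> np.ndarray:
    """Subtract a smooth background estimated by a large morphological opening.

    The opening (octagonal approximation of a disk of ``radius`` px) removes
    every structure smaller than the element, leaving the smooth background,
    which is then subtracted and the result clipped at zero.  Structures of
    punctum scale pass through unchanged; smooth gradients are removed up to
    boundary effects of order slope x radius.
    """
    footprint = disk(radius, decomposition="sequence")
    background = opening(image, footprint)
    return np.clip(image - background, 0.0, None)


def white_tophat(image: np.ndarray, se_radius: int = TOPHAT_RADIUS) -> np.ndarray:
    """White top-hat: image minus its opening with a disk of ``se_radius`` px.

    Enhances spots smaller than the structuring element and suppresses the
    interiors of larger plateaus; the result is nonnegative by construction.
    """
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    return sk_white_tophat(image, disk(se_radius))


# --------------------------------------------------------------------------
# Thresholding
# --------------------------------------------------------------------------


def robust_background_threshold(
    images: list[np.ndarray] | np.ndarray,
    trim_lo: float = 0.05,
    trim_hi: float = 0.05,
    k_sd: float = 2.0,
) -> float:
    """Robust-background threshold averaged over a set of images.

    Per image the dimmest ``trim_lo`` and brightest ``trim_hi`` fractions of
    pixels are discarded and the threshold is mean + ``k_sd`` x sd
    (population sd) of the remainder; the returned value is the mean of the
    per-image thresholds.  By contract the caller computes this from
    untreated-group images only and applies it to all groups, so both
    conditions are segmented identically.
    """
    if isinstance(images, np.ndarray):
        images = [images]
    if len(images) == 0:
        raise ValueError("need at least one image")
    if not (0.0 <= trim_lo and 0.0 <= trim_hi and trim_lo + trim_hi < 1.0):
        raise ValueError("require 0 <= trim_lo + trim_hi < 1")
    per_image = []
    for img in images:
        flat = np.sort(np.asarray(img, dtype=float).ravel())
        n = flat.size
        lo = int(np.floor(trim_lo * n))
        hi = int(np.floor(trim_hi * n))
        kept = flat[lo : n - hi]
        if kept.size == 0:
            raise ValueError("no pixels remain after trimming")
        per_image.append(float(kept.mean() + k_sd * kept.std()))
    return float(np.mean(per_image))


# --------------------------------------------------------------------------
# Puncta segmentation
# --------------------------------------------------------------------------


@dataclass
class LabeledObjects:
    """Labelled segmentation of one target channel.

    ``label_image`` uses contiguous positive integer labels with 0 as
    background; the per-label pixel lists partition the foreground.
    """

    label_image: np.ndarray
    target: str

    @property
    def count(self) -> int:
        return int(self.label_image.max())

    def pixels(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.label_image == label)

    def labels(self) -> range:
        return range(1, self.count + 1)


def segment_puncta(
    enhanced: np.ndarray,
    threshold: float,
    min_peak_distance: int = 3,
    smoothing_sigma: float = 1.0,
    target: str = "",
) -> LabeledObjects:
    """Threshold and declump puncta by intensity peaks.

    Foreground is ``enhanced > threshold``; each connected component is
    split into one object per local maximum of the Gaussian-smoothed
    intensity (peaks at least ``min_peak_distance`` px apart) by a seeded
    watershed on the inverted intensity.  8-connectivity throughout.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = enhanced > threshold
    if not mask.any():
        return LabeledObjects(np.zeros(enhanced.shape, dtype=np.int32), target)
    smoothed = ndi.gaussian_filter(np.asarray(enhanced, dtype=float), smoothing_sigma)
    components = sk_label(mask, connectivity=2)
    # all strict 3x3 local maxima first, then minimum-separation suppression
    # brightest-first; a genuine dim maximum on the shoulder of a brighter
    # neighbour survives as long as it keeps min_peak_distance clearance
    candidates = peak_local_max(
        smoothed, min_distance=1, labels=components, exclude_border=False
    )
    order = np.argsort(-smoothed[tuple(candidates.T)], kind="stable")
    ranked = candidates[order]
    suppressed = np.zeros(len(ranked), dtype=bool)
    if len(ranked):
        from scipy.spatial import cKDTree

        tree = cKDTree(ranked)
        neighbourhoods = tree.query_ball_point(ranked, r=min_peak_distance - 1e-9)
        for i, neighbours in enumerate(neighbourhoods):
            if suppressed[i]:
                continue
            for j in neighbours:
                if j != i and not suppressed[j] and j > i:
                    suppressed[j] = True
    peaks = ranked[~suppressed]
    markers = np.zeros(enhanced.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=2)
    # components that received no marker (flat plateaus) keep their own label
    orphan = mask & (labels == 0)
    if orphan.any():
        extra = sk_label(orphan, connectivity=2)
        extra[extra > 0] += labels.max()
        labels = labels + extra
    # relabel contiguously for a stable 1..K labelling
    labels, _, _ = relabel_sequential(labels)
    return LabeledObjects(labels.astype(np.int32), target)


def relabel_sequential(labels: np.ndarray):
    from skimage.segmentation import relabel_sequential as _rs

    return _rs(labels)


# --------------------------------------------------------------------------
# Compartment segmentation
# --------------------------------------------------------------------------


def segment_compartments(
    dapi_image: np.ndarray,
    map2_image: np.ndarray,
    nuclei_sigma: float = 3.0,
    nuclei_min_size: int = 50,
    dendrite_sigma: float = 1.0,
    dendrite_min_size: int = 64,
    trim_lo: float = 0.05,
    trim_hi: float = 0.05,
    k_sd: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Nuclei mask from DAPI (Otsu) and dendrite mask from MAP2.

    Nuclei: Gaussian smoothing, global Otsu threshold, hole filling, and
    small-object removal; a featureless DAPI image yields an empty mask.
    Dendrites: light Gaussian smoothing (suppresses boundary roughness that
    would otherwise grow spurious skeleton branches), robust-background
    threshold, and small-object removal.
    """
    dapi = np.asarray(dapi_image, dtype=float)
    if np.ptp(dapi) == 0:
        nuclei = np.zeros(dapi.shape, dtype=bool)
    else:
        smoothed = ndi.gaussian_filter(dapi, nuclei_sigma)
        nuclei = smoothed > threshold_otsu(smoothed)
        nuclei = ndi.binary_fill_holes(nuclei)
        nuclei = remove_small_objects(nuclei, max_size=nuclei_min_size - 1)

    map2 = np.asarray(map2_image, dtype=float)
    if np.ptp(map2) == 0:
        dendrite = np.zeros(map2.shape, dtype=bool)
    else:
        smoothed_map2 = ndi.gaussian_filter(map2, dendrite_sigma)
        thr = robust_background_threshold([smoothed_map2], trim_lo, trim_hi, k_sd)
        dendrite = smoothed_map2 > thr
        # erode one pixel to undo the dilation introduced by the smoothing
        dendrite = erosion(dendrite, disk(1))
        dendrite = remove_small_objects(dendrite, max_size=dendrite_min_size - 1)
    return nuclei, dendrite
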