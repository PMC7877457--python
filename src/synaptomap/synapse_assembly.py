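"""Grouping per-target puncta into synapses anchored on synapsin1.

A synapse is one synapsin1 anchor punctum plus every other-channel punctum
assigned to it by the overlap rules: presynaptic puncta (vGlut1, vGAT,
bassoon) need at least 50% of their area overlapping the anchor,
postsynaptic puncta at least 6.25% (= 1 pixel of a 16-pixel punctum).
Puncta are first filtered by equivalent diameter (3-15 px inclusive),
excluded if they touch the nuclei mask, and excluded if they lie more than
8 px (edge-to-edge Euclidean distance) from the dendrite mask.  Each
synapse is then classified excitatory / inhibitory / dual / unknown from
the presence of its vesicular-transporter children.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image_processing import LabeledObjects
from .synthetic_data import ANCHOR_TARGET, TARGET_ROLES

logger = logging.getLogger(__name__)

#: minimum overlap fraction (child-normalized) per child role
PRESYNAPTIC_MIN_OVERLAP = 0.50
POSTSYNAPTIC_MIN_OVERLAP = 0.0625
#: maximum Euclidean distance (px) from a punctum to the dendrite mask
DENDRITE_MAX_DISTANCE = 8.0
#: inclusive equivalent-diameter bounds (px)
SIZE_MIN_DIAMETER = 3.0
SIZE_MAX_DIAMETER = 15.0


class MissingChannelError(KeyError):
    """A required target channel is absent."""


@dataclass
class Punctum:
    """One segmented object on one target channel."""

    id: int
    target: str
    rows: np.ndarray
    cols: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)

    @property
    def role(self) -> str:
        return TARGET_ROLES[self.target]

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def equivalent_diameter(self) -> float:
        return 2.0 * np.sqrt(self.area / np.pi)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def linear_indices(self) -> np.ndarray:
        return self.rows * self.shape[1] + self.cols


def puncta_from_labels(objects: LabeledObjects) -> list[Punctum]:
    """Extract one Punctum per label of a segmented channel."""
    out = []
    img = objects.label_image
    if img.max() == 0:
        return out
    all_rows, all_cols = np.nonzero(img)
    labels = img[all_rows, all_cols]
    order = np.argsort(labels, kind="stable")
    all_rows, all_cols, labels = all_rows[order], all_cols[order], labels[order]
    bounds = np.searchsorted(labels, np.arange(1, img.max() + 2))
    for lab in range(1, img.max() + 1):
        lo, hi = bounds[lab - 1], bounds[lab]
        out.append(
            Punctum(
                id=lab,
                target=objects.target,
                rows=all_rows[lo:hi],
                cols=all_cols[lo:hi],
                shape=img.shape,
            )
        )
    return out


@dataclass
class Synapse:
    """One synapsin1 anchor plus its assigned per-target children."""

    anchor: Punctum
    children: dict[str, list[Punctum]] = field(default_factory=dict)
    class_label: str = "unknown"
    replicate_id: int | None = None
    treatment: str | None = None
    field_id: int | None = None

    def children_of(self, target: str) -> list[Punctum]:
        return self.children.get(target, [])


# --------------------------------------------------------------------------
# Rules
# --------------------------------------------------------------------------


def overlap_fraction(child: Punctum, anchor: Punctum) -> float:
    """|child ∩ anchor| / |child| on the shared pixel grid."""
    if child.area == 0:
        raise ValueError("child punctum has an empty pixel set")
    if child.shape != anchor.shape:
        raise ValueError("puncta are not on the same pixel grid")
    inter = np.intersect1d(
        child.linear_indices, anchor.linear_indices, assume_unique=True
    )
    return inter.size / child.area


def size_filter(
    puncta: list[Punctum],
    d_min: float = SIZE_MIN_DIAMETER,
    d_max: float = SIZE_MAX_DIAMETER,
) -> list[Punctum]:
    """Keep puncta with equivalent diameter in [d_min, d_max] (inclusive)."""
    if d_min > d_max:
        raise ValueError("d_min must not exceed d_max")
    return [p for p in puncta if d_min <= p.equivalent_diameter <= d_max]


def _passes_location_rules(
    p: Punctum, nuclei_mask: np.ndarray, dendrite_distance: np.ndarray,
    max_distance: float,
) -> bool:
    if nuclei_mask[p.rows, p.cols].any():
        return False
    return float(dendrite_distance[p.rows, p.cols].min()) <= max_distance


def assemble_synapses(
    puncta_by_target: dict[str, list[Punctum]],
    nuclei_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    dendrite_max_distance: float = DENDRITE_MAX_DISTANCE,
) -> tuple[list[Synapse], dict[str, int]]:
    """Apply location and overlap rules, seed synapses, assign children.

    Every surviving synapsin1 punctum seeds one synapse.  Every surviving
    non-anchor punctum joins the anchor with which its child-normalized
    overlap is maximal (ties broken toward the smaller anchor label),
    provided the fraction meets its role's threshold; otherwise it is
    counted non-synaptic.  Returns the synapses plus bookkeeping counts.
    """
    if ANCHOR_TARGET not in puncta_by_target:
        raise MissingChannelError(f"no {ANCHOR_TARGET} puncta provided")
    dendrite_distance = ndi.distance_transform_edt(~np.asarray(dendrite_mask, bool))
    nuclei_mask = np.asarray(nuclei_mask, bool)

    stats = {"anchors_rejected": 0, "children_rejected_location": 0,
             "children_unassigned": 0, "children_assigned": 0}

    anchors = [
        a
        for a in puncta_by_target[ANCHOR_TARGET]
        if _passes_location_rules(a, nuclei_mask, dendrite_distance, dendrite_max_distance)
    ]
    stats["anchors_rejected"] = len(puncta_by_target[ANCHOR_TARGET]) - len(anchors)
    synapses = {a.id: Synapse(anchor=a) for a in anchors}

    if anchors:
        shape = anchors[0].shape
        # anchors come from one segmentation, so their pixel sets are disjoint
        # and a single label image encodes them losslessly
        anchor_label_img = np.zeros(shape, dtype=np.int32)
        for a in anchors:
            anchor_label_img[a.rows, a.cols] = a.id
        max_id = max(a.id for a in anchors)
    else:
        anchor_label_img = None
        max_id = 0

    thresholds = {
        "presynaptic": PRESYNAPTIC_MIN_OVERLAP,
        "postsynaptic": POSTSYNAPTIC_MIN_OVERLAP,
    }

    for target, puncta in puncta_by_target.items():
        if target == ANCHOR_TARGET:
            continue
        role = TARGET_ROLES[target]
        min_overlap = thresholds[role]
        for child in puncta:
            if not _passes_location_rules(
                child, nuclei_mask, dendrite_distance, dendrite_max_distance
            ):
                stats["children_rejected_location"] += 1
                continue
            if anchor_label_img is None:
                stats["children_unassigned"] += 1
                continue
            labels_under = anchor_label_img[child.rows, child.cols]
            counts = np.bincount(labels_under[labels_under > 0], minlength=max_id + 1)
            if counts.sum() == 0:
                stats["children_unassigned"] += 1
                continue
            best = int(np.argmax(counts))  # argmax returns the smallest index on ties
            fraction = counts[best] / child.area
            if fraction >= min_overlap:
                synapses[best].children.setdefault(target, []).append(child)
                stats["children_assigned"] += 1
            else:
                stats["children_unassigned"] += 1

    out = [synapses[a.id] for a in anchors]
    for syn in out:
        syn.class_label = classify_synapse(syn)
    return out, stats


def classify_synapse(synapse: Synapse) -> str:
    """Excitatory / inhibitory / dual / unknown from transporter children."""
    has_vglut = len(synapse.children_of("vGlut1")) > 0
    has_vgat = len(synapse.children_of("vGAT")) > 0
    if has_vglut and has_vgat:
        return "dual"
    if has_vglut:
        return "excitatory"
    if has_vgat:
        return "inhibitory"
    return "unknown"
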