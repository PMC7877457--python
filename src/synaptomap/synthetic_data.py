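"""Synthetic multiplexed-immunofluorescence field generator.

Emulates multi-round, multi-channel confocal acquisition of cultured
hippocampal neurons stained for a panel of synaptic proteins: a MAP2
dendrite arbor (re-imaged every round and used for registration), DAPI
nuclei, a synapsin1 anchor punctum field, and per-target child puncta
(vGlut1, vGAT, PSD-95, SHANK3, homer-1b/c, NR2B, gephyrin, bassoon,
cortactin, actin) whose presence and intensity follow configurable
subtype profiles.  Round-to-round integer misalignment, a smooth
multiplicative illumination gradient, and Poisson + Gaussian noise are
applied after rendering, and every rendered punctum is recorded in a
ground-truth table so downstream segmentation, assembly, classification,
clustering, and statistics can be validated against known truth.

Intensity units are arbitrary: only relative (fold-change) effects are
meaningful, matching how the imaging data themselves are analyzed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Target panel and roles
# --------------------------------------------------------------------------

ANCHOR_TARGET = "Synapsin1"
PRESYNAPTIC_TARGETS = ("vGlut1", "vGAT", "Bassoon")
POSTSYNAPTIC_TARGETS = (
    "PSD95",
    "SHANK3",
    "Homer1bc",
    "NR2B",
    "Gephyrin",
    "Cortactin",
    "Actin",
)
SYNAPTIC_TARGETS = (ANCHOR_TARGET,) + PRESYNAPTIC_TARGETS + POSTSYNAPTIC_TARGETS
STRUCTURAL_TARGETS = ("MAP2", "DAPI")
ALL_TARGETS = STRUCTURAL_TARGETS + SYNAPTIC_TARGETS

#: role of each synaptic target in synapse assembly
TARGET_ROLES: dict[str, str] = {ANCHOR_TARGET: "anchor"}
TARGET_ROLES.update({t: "presynaptic" for t in PRESYNAPTIC_TARGETS})
TARGET_ROLES.update({t: "postsynaptic" for t in POSTSYNAPTIC_TARGETS})

CLASS_LABELS = ("excitatory", "inhibitory", "dual", "unknown")


class SizingError(ValueError):
    """Image too small to hold the requested synapse density."""


# --------------------------------------------------------------------------
# Subtype profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubtypeProfile:
    """Per-subtype generative profile for synaptic target expression.

    ``presence`` gives, per target, the probability that a punctum of that
    target is rendered at a synapse of this subtype; ``mean_log_intensity``
    and ``sd_log_intensity`` parameterize the log-normal punctum amplitude.
    Punctum kernels are isotropic 2D Gaussians; the synapsin1 anchor sigma
    is drawn uniformly from ``sigma_range`` (pixels) and child puncta use a
    fraction ``child_sigma_factor`` of their anchor's sigma (the vesicle
    pool is the largest structure of a synapse).  Children are offset from
    the synapsin1 centroid by a per-axis normal displacement whose sd
    depends on the child's role.
    """

    name: str
    class_label: str
    weight: float
    presence: Mapping[str, float]
    mean_log_intensity: Mapping[str, float]
    sd_log_intensity: float = 0.35
    sigma_range: tuple[float, float] = (1.05, 1.45)
    child_sigma_factor: tuple[float, float] = (0.70, 0.95)
    presynaptic_offset_sd: float = 0.6
    postsynaptic_offset_sd: float = 1.3

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for t, p in self.presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence[{t!r}] = {p} outside [0, 1]")
        lo, hi = self.sigma_range
        if not 0 < lo <= hi:
            raise ValueError("sigma_range must be positive and ordered")


def _profile(name, class_label, weight, presence, level, **kw):
    mean_log = {t: np.log(350.0) + level.get(t, 0.0) for t in presence}
    return SubtypeProfile(
        name=name,
        class_label=class_label,
        weight=weight,
        presence=presence,
        mean_log_intensity=mean_log,
        **kw,
    )


def default_subtype_profiles() -> list[SubtypeProfile]:
    """Six subtype profiles: five excitatory flavours and one inhibitory.

    The largest excitatory subtype expresses the full scaffold at high
    levels; the remaining excitatory subtypes are dimmer overall and each
    nearly lacks one or more postsynaptic/cytoskeletal proteins.  The
    inhibitory subtype carries vGAT and gephyrin, with moderate bleed-in
    of excitatory scaffolds, mirroring the qualitative per-cluster
    intensity ordering seen in multiplexed synapse data.
    """
    high = {
        ANCHOR_TARGET: 1.0,
        "vGlut1": 1.0,
        "vGAT": 0.0,
        "Bassoon": 0.97,
        "PSD95": 0.97,
        "SHANK3": 0.97,
        "Homer1bc": 0.97,
        "NR2B": 0.97,
        "Gephyrin": 0.03,
        "Cortactin": 0.97,
        "Actin": 0.97,
    }

    def variant(**changes):
        d = dict(high)
        d.update(changes)
        return d

    up = 0.55  # log-intensity boost of the dominant subtype
    profiles = [
        _profile(
            "exc_full", "excitatory", 0.579,
            high, {t: (up if t != ANCHOR_TARGET else 0.15) for t in high},
        ),
        _profile(
            "exc_low_shank", "excitatory", 0.10525,
            variant(SHANK3=0.03, Cortactin=0.03), {},
        ),
        _profile(
            "exc_low_nr2b", "excitatory", 0.10525,
            variant(NR2B=0.03, Actin=0.03), {"PSD95": 0.25},
        ),
        _profile(
            "exc_low_homer", "excitatory", 0.10525,
            variant(Homer1bc=0.03, Bassoon=0.03), {"SHANK3": -0.4},
        ),
        _profile(
            "exc_sparse", "excitatory", 0.10525,
            variant(
                PSD95=0.03, SHANK3=0.03, Homer1bc=0.03, NR2B=0.03,
                Cortactin=0.03, Actin=0.03,
            ),
            {t: (-0.65 if t != ANCHOR_TARGET else -0.3) for t in high},
        ),
        _profile(
            "inh", "inhibitory", 1.0,
            {
                ANCHOR_TARGET: 1.0,
                "vGlut1": 0.0,
                "vGAT": 1.0,
                "Bassoon": 0.97,
                "PSD95": 0.35,
                "SHANK3": 0.4,
                "Homer1bc": 0.75,
                "NR2B": 0.03,
                "Gephyrin": 0.97,
                "Cortactin": 0.03,
                "Actin": 0.97,
            },
            {"Gephyrin": 0.5, "vGAT": 0.3, "Bassoon": -0.3},
        ),
    ]
    for p in profiles:
        p.validate()
    return profiles


def _dual_profile(profiles: Sequence[SubtypeProfile]) -> SubtypeProfile:
    """Dual synapses: full excitatory content plus an obligatory vGAT punctum."""
    base = profiles[0]
    presence = dict(base.presence)
    presence["vGAT"] = 1.0
    presence["vGlut1"] = 1.0
    mean_log = dict(base.mean_log_intensity)
    mean_log["vGAT"] = np.log(250.0)
    return dataclasses.replace(
        base, name="dual", class_label="dual",
        presence=presence, mean_log_intensity=mean_log,
    )


def _unknown_profile() -> SubtypeProfile:
    """Synapsin1-only puncta: no vesicular transporter, sparse scaffold."""
    presence = {t: 0.0 for t in SYNAPTIC_TARGETS}
    presence[ANCHOR_TARGET] = 1.0
    for t in ("Bassoon", "Actin", "Cortactin"):
        presence[t] = 0.25
    return _profile("unknown", "unknown", 1.0, presence, {t: -0.4 for t in presence})


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Study-design and rendering parameters of the synthetic cohort.

    Defaults mirror the acquisition and design of the emulated study:
    187 nm pixels, ten imaging rounds of four channels with MAP2 carried
    in every round, six untreated and five treated culture replicates,
    excitatory/inhibitory dendritic densities of 56 and 15.8 synapses per
    100 um, a 5:1 excitatory:inhibitory ratio among classified synapses,
    and ~22% synapsin1-only ("unknown") plus ~12% dual-transporter
    ("dual") puncta.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.187
    n_rounds: int = 10
    channels_per_round: int = 4
    target_list: tuple[str, ...] = ALL_TARGETS
    n_replicates_untreated: int = 6
    n_replicates_treated: int = 5
    fields_per_replicate: int = 5
    excitatory_density_per_100um: float = 56.0
    inhibitory_density_per_100um: float = 15.8
    ei_ratio: float = 5.0
    unknown_rate: float = 0.22
    dual_rate: float = 0.12
    subtype_profiles: list[SubtypeProfile] = field(
        default_factory=default_subtype_profiles
    )
    shift_range_px: int = 3
    illumination_gradient_amplitude: float = 0.25
    poisson_scale: float = 0.5
    gaussian_noise_sd: float = 4.0
    background_level: float = 10.0
    decoy_rate: float = 0.08
    treatment_effects: dict[str, float] = field(default_factory=dict)
    dendrite_width_px: int = 5
    dendrite_length_px: int | None = None
    min_synapse_gap_px: float = 5.0
    seed: int = 0

    # ---------------------------------------------------------------- helpers

    @property
    def total_density_per_100um(self) -> float:
        return self.excitatory_density_per_100um + self.inhibitory_density_per_100um

    @property
    def n_replicates(self) -> int:
        return self.n_replicates_untreated + self.n_replicates_treated

    def replicate_treatment(self, replicate_id: int) -> str:
        return "untreated" if replicate_id < self.n_replicates_untreated else "treated"

    def treatment_factor(self, target: str) -> float:
        return float(self.treatment_effects.get(target, 1.0))

    def walk_length_px(self) -> int:
        if self.dendrite_length_px is not None:
            return int(self.dendrite_length_px)
        return int(2.2 * max(self.image_shape))

    def validate(self) -> None:
        if self.ei_ratio <= 0:
            raise ValueError("ei_ratio must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.unknown_rate + self.dual_rate >= 1.0:
            raise ValueError("unknown_rate + dual_rate must be < 1")
        if self.n_rounds < 1 or self.channels_per_round < 1:
            raise ValueError("need at least one round and one channel")
        n_slots = self.n_rounds * (self.channels_per_round - 1)
        if n_slots < len(SYNAPTIC_TARGETS) + 1:
            raise ValueError(
                "not enough (round, channel) slots for DAPI and the synaptic panel"
            )
        weights = [p.weight for p in self.subtype_profiles if p.class_label == "excitatory"]
        if weights and not np.isclose(sum(weights), 1.0):
            raise ValueError("excitatory subtype weights must sum to 1")
        for p in self.subtype_profiles:
            p.validate()
        if min(self.image_shape) < 48:
            raise SizingError(
                f"image_shape {self.image_shape} too small to render a dendrite field"
            )
        # a synapse needs ~min_synapse_gap_px of skeleton; refuse impossible densities
        per_px = self.total_density_per_100um * self.pixel_size_um / 100.0
        if per_px * max(self.min_synapse_gap_px, 1.0) > 1.0:
            raise SizingError(
                "requested synapse density exceeds what the dendrite can hold "
                f"({self.total_density_per_100um}/100um at {self.pixel_size_um} um/px)"
            )


def build_channel_map(config: SynthConfig) -> dict[tuple[int, int], str | None]:
    """Assign targets to (round, channel) slots.

    MAP2 occupies channel 0 of every round (the registration reference),
    DAPI the first free slot, then the synaptic panel in order; leftover
    slots are unused (rendered as background only) and map to ``None``.
    """
    cmap: dict[tuple[int, int], str | None] = {}
    queue = ["DAPI", *SYNAPTIC_TARGETS]
    for r in range(config.n_rounds):
        for c in range(config.channels_per_round):
            if c == 0:
                cmap[(r, c)] = "MAP2"
            else:
                cmap[(r, c)] = queue.pop(0) if queue else None
    return cmap


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------


@dataclass
class MultiplexedField:
    """One imaged field: per-(round, channel) images plus acquisition metadata.

    ``shifts`` holds per-round translations estimated during alignment
    (``None`` until the field is aligned); the true injected shifts live in
    the generator's ground truth, not here.
    """

    replicate_id: int
    field_id: int
    treatment: str
    images: dict[tuple[int, int], np.ndarray]
    channel_map: dict[tuple[int, int], str | None]
    pixel_size_um: float
    shifts: dict[int, tuple[int, int]] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def n_rounds(self) -> int:
        return 1 + max(r for r, _ in self.images)

    def rounds(self) -> list[int]:
        return sorted({r for r, _ in self.images})

    def channels_of_round(self, rnd: int) -> list[int]:
        return sorted(c for r, c in self.images if r == rnd)

    def slot_of(self, target: str, rnd: int | None = None) -> tuple[int, int]:
        for slot, t in self.channel_map.items():
            if t == target and (rnd is None or slot[0] == rnd):
                return slot
        raise KeyError(f"target {target!r} not in channel map")

    def image_for(self, target: str) -> np.ndarray:
        """The (single) image of a synaptic target, or round-0 MAP2/DAPI."""
        return self.images[self.slot_of(target)]


@dataclass
class GroundTruth:
    """Generator truth: per-synapse and per-field records plus decoys.

    ``synapses`` has one row per rendered synapse (field, replicate,
    treatment, class, subtype, centroid, and per-target true integrated
    intensity in ``intensity_<target>`` columns).  ``fields`` records the
    injected per-round shifts and the analytic dendrite skeleton length.
    ``masks`` (per-field dendrite/nuclei footprints) are kept only for
    fields generated in memory.
    """

    synapses: pd.DataFrame
    fields: pd.DataFrame
    decoys: pd.DataFrame
    masks: dict[tuple[int, int], dict[str, np.ndarray]] = field(default_factory=dict)

    @staticmethod
    def concat(parts: Iterable["GroundTruth"]) -> "GroundTruth":
        parts = list(parts)
        masks: dict = {}
        for p in parts:
            masks.update(p.masks)

        def _cat(frames: list[pd.DataFrame]) -> pd.DataFrame:
            nonempty = [f for f in frames if not f.empty]
            return pd.concat(nonempty or frames[:1], ignore_index=True)

        return GroundTruth(
            synapses=_cat([p.synapses for p in parts]),
            fields=_cat([p.fields for p in parts]),
            decoys=_cat([p.decoys for p in parts]),
            masks=masks,
        )


# --------------------------------------------------------------------------
# Rendering primitives
# --------------------------------------------------------------------------


def _gaussian_kernel(sigma: float, amplitude: float) -> np.ndarray:
    """Isotropic 2D Gaussian truncated at 3 sigma, peak value ``amplitude``."""
    half = max(1, int(np.ceil(3.0 * sigma)))
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return amplitude * k


def _add_kernel(scene: np.ndarray, row: float, col: float, kernel: np.ndarray) -> float:
    """Add a kernel centred at (row, col); return the intensity actually placed."""
    half = kernel.shape[0] // 2
    r0 = int(round(row)) - half
    c0 = int(round(col)) - half
    r1, c1 = r0 + kernel.shape[0], c0 + kernel.shape[1]
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r1, scene.shape[0]), min(c1, scene.shape[1])
    if rs >= re or cs >= ce:
        return 0.0
    sub = kernel[rs - r0 : re - r0, cs - c0 : ce - c0]
    scene[rs:re, cs:ce] += sub
    return float(sub.sum())


def _integer_shift(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate by whole pixels, zero-filling exposed borders."""
    out = np.zeros_like(image)
    h, w = image.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = image[rs_src, cs_src]
    return out


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    keep = rr**2 + cc**2 <= radius**2
    return np.stack([rr[keep], cc[keep]], axis=1)


def _render_dendrite(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed random-walk dendrite of fixed width.

    Returns (mask, path points (n, 2) float, analytic path length in um).
    The skeleton length is the summed step length of the walk, recorded
    analytically rather than re-measured from the raster.
    """
    h, w = config.image_shape
    margin = 12
    n_steps = config.walk_length_px()
    pos = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
    )
    heading = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = pos
    for i in range(n_steps):
        heading += rng.normal(0.0, 0.12)
        step = np.array([np.sin(heading), np.cos(heading)])
        nxt = pts[i] + step
        # steer back inside the margins
        if not (margin <= nxt[0] <= h - margin):
            heading = -heading
        if not (margin <= nxt[1] <= w - margin):
            heading = np.pi - heading
        step = np.array([np.sin(heading), np.cos(heading)])
        pts[i + 1] = pts[i] + step
        pts[i + 1, 0] = np.clip(pts[i + 1, 0], 2, h - 3)
        pts[i + 1, 1] = np.clip(pts[i + 1, 1], 2, w - 3)
    mask = np.zeros(config.image_shape, dtype=bool)
    offs = _disk_offsets(config.dendrite_width_px / 2.0)
    ctr = np.round(pts).astype(int)
    rr = (ctr[:, 0:1] + offs[:, 0]).ravel()
    cc = (ctr[:, 1:2] + offs[:, 1]).ravel()
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    mask[rr[ok], cc[ok]] = True
    length_um = float(n_steps) * config.pixel_size_um
    return mask, pts, length_um


def _render_nuclei(
    config: SynthConfig, soma: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """DAPI scene and binary nuclei footprint: soma nucleus + extras."""
    h, w = config.image_shape
    scene = np.zeros(config.image_shape, dtype=float)
    mask = np.zeros(config.image_shape, dtype=bool)
    n_extra = rng.poisson(1.5)
    centers = [soma]
    for _ in range(n_extra):
        centers.append(np.array([rng.uniform(15, h - 15), rng.uniform(15, w - 15)]))
    for ctr in centers:
        radius = rng.uniform(7.0, 11.0)
        amp = rng.uniform(120.0, 220.0)
        offs = _disk_offsets(radius)
        rr = np.clip(offs[:, 0] + int(round(ctr[0])), 0, h - 1)
        cc = np.clip(offs[:, 1] + int(round(ctr[1])), 0, w - 1)
        mask[rr, cc] = True
        # smooth-edged blob: Gaussian falloff outside a solid core
        kern = _gaussian_kernel(radius / 1.6, amp)
        _add_kernel(scene, ctr[0], ctr[1], kern)
    return scene, mask


# --------------------------------------------------------------------------
# Field generation
# --------------------------------------------------------------------------


def _sample_synapse_positions(
    config: SynthConfig,
    pts: np.ndarray,
    length_um: float,
    nuclei_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-core placement of synapse centres along the dendrite walk.

    The synapse count is Poisson with mean density x skeleton length;
    centres are drawn uniformly along the path (with sub-pixel
    perpendicular jitter) and accepted only if they keep at least
    ``min_synapse_gap_px`` Euclidean distance from every accepted centre
    and avoid the nuclear footprint — synapses are ~0.7 um structures
    that neither interpenetrate nor sit on the soma nucleus.
    """
    from scipy.ndimage import distance_transform_edt

    n_target = rng.poisson(config.total_density_per_100um * length_um / 100.0)
    n_path = len(pts) - 1
    h, w = nuclei_mask.shape
    nucleus_clearance = distance_transform_edt(~nuclei_mask)
    accepted_arr = np.empty((max(n_target, 1), 2))
    n_acc = 0
    gap2 = config.min_synapse_gap_px**2
    attempts = 0
    max_attempts = 500 * max(n_target, 1)
    while n_acc < n_target and attempts < max_attempts:
        attempts += 1
        s = rng.uniform(0.0, n_path)
        idx = int(s)
        frac = s - idx
        cand = pts[idx] * (1 - frac) + pts[idx + 1] * frac + rng.normal(0.0, 0.8, 2)
        pr, pc = int(round(cand[0])), int(round(cand[1]))
        if not (0 <= pr < h and 0 <= pc < w) or nucleus_clearance[pr, pc] < 6.0:
            continue
        if n_acc and (
            ((accepted_arr[:n_acc] - cand) ** 2).sum(axis=1).min() < gap2
        ):
            continue
        accepted_arr[n_acc] = cand
        n_acc += 1
    accepted = [accepted_arr[i] for i in range(n_acc)]
    if len(accepted) < n_target:
        logger.warning(
            "placed %d of %d synapses before the dendrite saturated",
            len(accepted), n_target,
        )
    return np.array(accepted).reshape(-1, 2)


def _choose_profile(
    config: SynthConfig, rng: np.random.Generator,
    dual: SubtypeProfile, unknown: SubtypeProfile,
) -> SubtypeProfile:
    u = rng.uniform()
    if u < config.unknown_rate:
        return unknown
    if u < config.unknown_rate + config.dual_rate:
        return dual
    p_exc = config.ei_ratio / (1.0 + config.ei_ratio)
    exc = [p for p in config.subtype_profiles if p.class_label == "excitatory"]
    inh = [p for p in config.subtype_profiles if p.class_label == "inhibitory"]
    if rng.uniform() < p_exc and exc:
        weights = np.array([p.weight for p in exc])
        return exc[rng.choice(len(exc), p=weights / weights.sum())]
    return inh[rng.choice(len(inh))]


def generate_field(
    config: SynthConfig, replicate_id: int, field_id: int,
    render_images: bool = True,
) -> tuple[MultiplexedField, GroundTruth]:
    """Render one multiplexed field and its ground truth.

    The per-field random stream is derived deterministically from
    ``(config.seed, replicate_id, field_id)`` so any field of a cohort can
    be regenerated independently and reproducibly.  With
    ``render_images=False`` the per-channel noise/illumination pass is
    skipped and the returned field has no images — the ground truth
    (identical to the rendered case) is still produced, which is much
    faster when only truth-level statistics are needed.
    """
    config.validate()
    treatment = config.replicate_treatment(replicate_id)
    treated = treatment == "treated"
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, replicate_id, field_id))
    )
    cmap = build_channel_map(config)

    dendrite_mask, path_pts, length_um = _render_dendrite(config, rng)
    dapi_scene, nuclei_mask = _render_nuclei(config, path_pts[0], rng)
    map2_scene = dendrite_mask.astype(float) * 60.0
    from scipy.ndimage import gaussian_filter

    map2_scene = gaussian_filter(map2_scene, 0.7)

    scenes: dict[str, np.ndarray] = {
        t: np.zeros(config.image_shape, dtype=float) for t in SYNAPTIC_TARGETS
    }
    scenes["MAP2"] = map2_scene
    scenes["DAPI"] = dapi_scene

    dual = _dual_profile(config.subtype_profiles)
    unknown = _unknown_profile()

    centres = _sample_synapse_positions(config, path_pts, length_um, nuclei_mask, rng)
    records = []
    for sid, (row, col) in enumerate(centres):
        profile = _choose_profile(config, rng, dual, unknown)
        rec = {
            "replicate": replicate_id,
            "treatment": treatment,
            "field": field_id,
            "synapse_id": sid,
            "subtype": profile.name,
            "class": profile.class_label,
            "row": row,
            "col": col,
        }
        anchor_sigma = rng.uniform(*profile.sigma_range)
        for target in SYNAPTIC_TARGETS:
            presence = profile.presence.get(target, 0.0)
            rendered = 0.0
            if rng.uniform() < presence:
                sigma = (
                    anchor_sigma
                    if target == ANCHOR_TARGET
                    else anchor_sigma * rng.uniform(*profile.child_sigma_factor)
                )
                amp = float(
                    np.exp(
                        rng.normal(
                            profile.mean_log_intensity.get(target, np.log(300.0)),
                            profile.sd_log_intensity,
                        )
                    )
                )
                if treated:
                    amp *= config.treatment_factor(target)
                if target == ANCHOR_TARGET:
                    pr, pc = row, col
                else:
                    sd = (
                        profile.presynaptic_offset_sd
                        if TARGET_ROLES[target] == "presynaptic"
                        else profile.postsynaptic_offset_sd
                    )
                    pr = row + rng.normal(0.0, sd)
                    pc = col + rng.normal(0.0, sd)
                kern = _gaussian_kernel(sigma, amp)
                rendered = _add_kernel(scenes[target], pr, pc, kern)
            rec[f"intensity_{target}"] = rendered
        records.append(rec)

    synapse_df = pd.DataFrame(records)
    if synapse_df.empty:
        synapse_df = pd.DataFrame(
            columns=["replicate", "treatment", "field", "synapse_id", "subtype",
                     "class", "row", "col"]
            + [f"intensity_{t}" for t in SYNAPTIC_TARGETS]
        )

    # decoy puncta: off-dendrite or out-of-size-range objects that the
    # location and size rules must reject
    decoy_records = []
    n_decoys = rng.poisson(config.decoy_rate * max(len(centres), 1))
    h, w = config.image_shape
    for did in range(n_decoys):
        target = SYNAPTIC_TARGETS[rng.integers(len(SYNAPTIC_TARGETS))]
        row, col = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        sigma = rng.uniform(0.5, 4.0)
        amp = float(np.exp(rng.normal(np.log(250.0), 0.4)))
        rendered = _add_kernel(scenes[target], row, col, _gaussian_kernel(sigma, amp))
        decoy_records.append(
            {
                "replicate": replicate_id,
                "treatment": treatment,
                "field": field_id,
                "decoy_id": did,
                "target": target,
                "row": row,
                "col": col,
                "sigma": sigma,
                "intensity": rendered,
            }
        )
    decoy_df = pd.DataFrame(
        decoy_records,
        columns=["replicate", "treatment", "field", "decoy_id", "target",
                 "row", "col", "sigma", "intensity"],
    )

    # per-round shifts (round 0 is the reference and stays unshifted)
    shifts: dict[int, tuple[int, int]] = {0: (0, 0)}
    for r in range(1, config.n_rounds):
        if config.shift_range_px > 0:
            shifts[r] = (
                int(rng.integers(-config.shift_range_px, config.shift_range_px + 1)),
                int(rng.integers(-config.shift_range_px, config.shift_range_px + 1)),
            )
        else:
            shifts[r] = (0, 0)

    # illumination gradient: one smooth multiplicative plane per field
    amp = config.illumination_gradient_amplitude
    if amp > 0:
        theta = rng.uniform(0, 2 * np.pi)
        rr, cc = np.meshgrid(
            np.linspace(-0.5, 0.5, h), np.linspace(-0.5, 0.5, w), indexing="ij"
        )
        gradient = 1.0 + amp * (np.cos(theta) * rr + np.sin(theta) * cc)
    else:
        gradient = np.ones(config.image_shape)

    images: dict[tuple[int, int], np.ndarray] = {}
    if render_images:
        for (rnd, ch), target in cmap.items():
            scene = (
                scenes[target] if target is not None else np.zeros(config.image_shape)
            )
            dr, dc = shifts[rnd]
            img = _integer_shift(scene, dr, dc) if (dr or dc) else scene.copy()
            img = gradient * (img + config.background_level)
            if config.poisson_scale > 0:
                img = (
                    rng.poisson(np.clip(img, 0, None) * config.poisson_scale)
                    / config.poisson_scale
                )
            if config.gaussian_noise_sd > 0:
                img = img + rng.normal(0.0, config.gaussian_noise_sd, size=img.shape)
            images[(rnd, ch)] = np.clip(img, 0.0, None).astype(np.float32)

    mfield = MultiplexedField(
        replicate_id=replicate_id,
        field_id=field_id,
        treatment=treatment,
        images=images,
        channel_map=cmap,
        pixel_size_um=config.pixel_size_um,
    )
    field_df = pd.DataFrame(
        [
            {
                "replicate": replicate_id,
                "treatment": treatment,
                "field": field_id,
                "skeleton_length_um": length_um,
                **{
                    f"shift_round{r}_{axis}": shifts[r][i]
                    for r in range(config.n_rounds)
                    for i, axis in enumerate(("row", "col"))
                },
            }
        ]
    )
    truth = GroundTruth(
        synapses=synapse_df,
        fields=field_df,
        decoys=decoy_df,
        masks={
            (replicate_id, field_id): {
                "dendrite": dendrite_mask,
                "nuclei": nuclei_mask,
            }
        },
    )
    return mfield, truth


# --------------------------------------------------------------------------
# Cohort generation and TIFF output
# --------------------------------------------------------------------------


def generate_cohort(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[MultiplexedField], GroundTruth, pd.DataFrame]:
    """Generate the full replicate/treatment cohort.

    Returns the fields, the pooled ground truth, and a manifest with one
    row per written or in-memory (round, channel) image.  When ``out_dir``
    is given every image is written as 16-bit grayscale TIFF and the
    manifest, ground-truth tables, and config are written alongside.
    """
    config.validate()
    if config.n_replicates == 0:
        raise ValueError("cohort needs at least one replicate")
    fields: list[MultiplexedField] = []
    truths: list[GroundTruth] = []
    manifest_rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for rep in range(config.n_replicates):
        treatment = config.replicate_treatment(rep)
        for fid in range(config.fields_per_replicate):
            mfield, truth = generate_field(config, rep, fid)
            fields.append(mfield)
            truths.append(truth)
            for (rnd, ch), target in mfield.channel_map.items():
                name = (
                    f"rep{rep:02d}_{treatment}_field{fid:02d}"
                    f"_round{rnd:02d}_ch{ch}_{target or 'unused'}.tif"
                )
                if out_path is not None:
                    write_tiff(out_path / name, mfield.images[(rnd, ch)])
                manifest_rows.append(
                    {
                        "path": name,
                        "replicate": rep,
                        "treatment": treatment,
                        "field": fid,
                        "round": rnd,
                        "channel": ch,
                        "target": target if target is not None else "",
                    }
                )
    truth = GroundTruth.concat(truths)
    manifest = pd.DataFrame(manifest_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        truth.synapses.to_csv(out_path / "ground_truth_synapses.csv", index=False)
        truth.fields.to_csv(out_path / "ground_truth_fields.csv", index=False)
        truth.decoys.to_csv(out_path / "ground_truth_decoys.csv", index=False)
    return fields, truth, manifest


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a nonnegative intensity image as 16-bit grayscale TIFF."""
    data = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def load_cohort(manifest_path: str | Path, pixel_size_um: float = 0.187
                ) -> list[MultiplexedField]:
    """Rebuild in-memory fields from a generator manifest and its TIFFs."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    fields = []
    for (rep, fid), grp in manifest.groupby(["replicate", "field"], sort=True):
        images = {}
        cmap: dict[tuple[int, int], str | None] = {}
        treatment = str(grp["treatment"].iloc[0])
        for _, row in grp.iterrows():
            slot = (int(row["round"]), int(row["channel"]))
            images[slot] = tifffile.imread(str(base / row["path"])).astype(np.float32)
            target = str(row["target"])
            cmap[slot] = target if target else None
        fields.append(
            MultiplexedField(
                replicate_id=int(rep),
                field_id=int(fid),
                treatment=treatment,
                images=images,
                channel_map=cmap,
                pixel_size_um=pixel_size_um,
            )
        )
    return fields


# --------------------------------------------------------------------------
# Truth-level shortcuts
# --------------------------------------------------------------------------


def generate_truth_cohort(config: SynthConfig) -> GroundTruth:
    """Ground truth of a full cohort without rendering any images.

    Orders of magnitude faster than :func:`generate_cohort`; the returned
    tables are identical to what the rendered cohort would carry, so
    statistical procedures can be calibrated directly against the
    generative model.
    """
    config.validate()
    truths = []
    for rep in range(config.n_replicates):
        for fid in range(config.fields_per_replicate):
            truths.append(generate_field(config, rep, fid, render_images=False)[1])
    return GroundTruth.concat(truths)


def truth_intensity_table(truth: GroundTruth) -> pd.DataFrame:
    """Feature-table view of the ground-truth integrated intensities.

    Columns follow the measurement naming convention
    (``IntegratedIntensity__Synapsin1__<target>``) so the statistics layer
    can consume generator truth directly.
    """
    df = truth.synapses.copy()
    renames = {
        f"intensity_{t}": f"IntegratedIntensity__{ANCHOR_TARGET}__{t}"
        for t in SYNAPTIC_TARGETS
    }
    df = df.rename(columns=renames)
    for t in SYNAPTIC_TARGETS:
        if t == ANCHOR_TARGET:
            continue
        df[f"PunctaNumber__{ANCHOR_TARGET}__{t}"] = (
            df[f"IntegratedIntensity__{ANCHOR_TARGET}__{t}"] > 0
        ).astype(float)
    return df
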