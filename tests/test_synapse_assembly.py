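"""Overlap, size, and location rules; synapse assembly and classification."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import noise_free
from synaptomap.pipeline import (
    RunConfig,
    assemble_field,
    compute_thresholds,
    process_field,
)
from synaptomap.synapse_assembly import (
    MissingChannelError,
    Punctum,
    Synapse,
    assemble_synapses,
    classify_synapse,
    overlap_fraction,
    size_filter,
)
from synaptomap.synthetic_data import generate_field

SHAPE = (64, 64)


def block(pid, target, r0, r1, c0, c1, shape=SHAPE):
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return Punctum(pid, target, rr.ravel(), cc.ravel(), shape)


def from_pixels(pid, target, pixels, shape=SHAPE):
    rows = np.array([p[0] for p in pixels])
    cols = np.array([p[1] for p in pixels])
    return Punctum(pid, target, rows, cols, shape)


class TestOverlapFraction:
    def test_sixteen_pixel_child_sharing_one_pixel(self):
        anchor = block(1, "Synapsin1", 10, 14, 10, 14)
        child = block(2, "PSD95", 13, 17, 13, 17)  # 4x4 child, 1 px shared
        assert overlap_fraction(child, anchor) == pytest.approx(0.0625)

    def test_disjoint_is_zero(self):
        anchor = block(1, "Synapsin1", 0, 4, 0, 4)
        child = block(2, "PSD95", 20, 24, 20, 24)
        assert overlap_fraction(child, anchor) == 0.0

    def test_contained_child_is_one(self):
        anchor = block(1, "Synapsin1", 10, 20, 10, 20)
        child = block(2, "vGlut1", 12, 15, 12, 15)
        assert overlap_fraction(child, anchor) == 1.0

    def test_empty_child_rejected(self):
        anchor = block(1, "Synapsin1", 0, 4, 0, 4)
        empty = Punctum(2, "PSD95", np.array([], int), np.array([], int), SHAPE)
        with pytest.raises(ValueError):
            overlap_fraction(empty, anchor)


class TestSizeFilter:
    @pytest.mark.parametrize(
        "area,kept",
        [
            (7, False),   # d = 2.99 < 3
            (8, True),    # d = 3.19
            (78, True),   # d = 9.97
            (176, True),  # d = 14.97
            (177, False),  # d = 15.01
        ],
    )
    def test_equivalent_diameter_boundaries(self, area, kept):
        rows = np.arange(area) // 16
        cols = np.arange(area) % 16
        p = Punctum(1, "PSD95", rows, cols, SHAPE)
        result = size_filter([p])
        assert (len(result) == 1) == kept

    def test_exact_boundary_diameters_inclusive(self):
        # a punctum engineered to land exactly on the bounds is retained
        p = Punctum(1, "PSD95", np.arange(8) // 4, np.arange(8) % 4, SHAPE)
        assert size_filter([p], d_min=p.equivalent_diameter,
                           d_max=p.equivalent_diameter) == [p]

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            size_filter([], d_min=10, d_max=3)


def empty_masks():
    return np.zeros(SHAPE, bool), np.ones(SHAPE, bool)


class TestAssemblyRules:
    def test_postsynaptic_boundary_inclusive(self):
        nuclei, dendrite = empty_masks()
        anchor = block(1, "Synapsin1", 10, 14, 10, 14)
        exactly = block(1, "PSD95", 13, 17, 13, 17)          # 1/16 = 0.0625
        below = from_pixels(
            2, "PSD95",
            [(13, 13)] + [(r, c) for r in range(14, 18) for c in range(13, 17)],
        )  # 1 of 17 px -> 0.0588
        synapses, _ = assemble_synapses(
            {"Synapsin1": [anchor], "PSD95": [exactly, below]}, nuclei, dendrite
        )
        assigned = [p.id for p in synapses[0].children_of("PSD95")]
        assert assigned == [1]

    def test_presynaptic_boundary_inclusive(self):
        nuclei, dendrite = empty_masks()
        anchor = block(1, "Synapsin1", 10, 20, 10, 20)
        half = block(1, "vGlut1", 15, 25, 10, 20)       # 50/100 = 0.50
        under = block(2, "vGlut1", 15, 25, 9, 19)       # 45/100 ... compute
        synapses, _ = assemble_synapses(
            {"Synapsin1": [anchor], "vGlut1": [half, under]}, nuclei, dendrite
        )
        ids = [p.id for p in synapses[0].children_of("vGlut1")]
        assert overlap_fraction(half, anchor) == pytest.approx(0.50)
        assert overlap_fraction(under, anchor) < 0.50
        assert ids == [1]

    def test_dendrite_distance_eight_inclusive_nine_excluded(self):
        nuclei = np.zeros(SHAPE, bool)
        dendrite = np.zeros(SHAPE, bool)
        dendrite[:, 10] = True
        anchor_near = from_pixels(1, "Synapsin1", [(30, 18)])  # 8 px from col 10
        anchor_far = from_pixels(2, "Synapsin1", [(40, 19)])   # 9 px
        synapses, stats = assemble_synapses(
            {"Synapsin1": [anchor_near, anchor_far]}, nuclei, dendrite
        )
        assert [s.anchor.id for s in synapses] == [1]
        assert stats["anchors_rejected"] == 1

    def test_nuclei_overlap_rejected(self):
        nuclei, dendrite = empty_masks()
        nuclei[12, 12] = True
        anchor = block(1, "Synapsin1", 10, 14, 10, 14)
        synapses, stats = assemble_synapses(
            {"Synapsin1": [anchor]}, nuclei, dendrite
        )
        assert synapses == []
        assert stats["anchors_rejected"] == 1

    def test_child_joins_anchor_with_maximal_overlap(self):
        nuclei, dendrite = empty_masks()
        a1 = block(1, "Synapsin1", 10, 20, 10, 20)
        a2 = block(2, "Synapsin1", 10, 20, 21, 31)
        child = block(1, "PSD95", 12, 16, 17, 25)  # 3 cols on a1, 4 cols on a2
        synapses, _ = assemble_synapses(
            {"Synapsin1": [a1, a2], "PSD95": [child]}, nuclei, dendrite
        )
        by_id = {s.anchor.id: s for s in synapses}
        assert [p.id for p in by_id[2].children_of("PSD95")] == [1]
        assert by_id[1].children_of("PSD95") == []

    def test_tie_broken_toward_lower_anchor_id(self):
        nuclei, dendrite = empty_masks()
        a1 = block(1, "Synapsin1", 10, 20, 10, 20)
        a2 = block(2, "Synapsin1", 10, 20, 24, 34)
        child = block(1, "PSD95", 12, 16, 18, 26)  # 2 cols on each anchor
        synapses, _ = assemble_synapses(
            {"Synapsin1": [a1, a2], "PSD95": [child]}, nuclei, dendrite
        )
        by_id = {s.anchor.id: s for s in synapses}
        assert [p.id for p in by_id[1].children_of("PSD95")] == [1]

    def test_missing_anchor_channel_errors(self):
        nuclei, dendrite = empty_masks()
        with pytest.raises(MissingChannelError):
            assemble_synapses({"PSD95": []}, nuclei, dendrite)

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        """Label-image-based assignment equals explicit all-pairs overlap."""
        from synaptomap.synthetic_data import TARGET_ROLES

        nuclei, dendrite = empty_masks()
        anchors, children = [], {}
        for pid in range(1, 7):
            r, c = rng.integers(4, 50, size=2)
            anchors.append(block(pid, "Synapsin1", r, r + rng.integers(3, 8),
                                 c, c + rng.integers(3, 8)))
        for target in ("PSD95", "vGlut1", "vGAT"):
            children[target] = []
            for pid in range(1, 10):
                r, c = rng.integers(4, 52, size=2)
                children[target].append(
                    block(pid, target, r, r + rng.integers(2, 7),
                          c, c + rng.integers(2, 7))
                )
        synapses, _ = assemble_synapses(
            {"Synapsin1": anchors, **children}, nuclei, dendrite
        )
        got = {
            (t, p.id): s.anchor.id
            for s in synapses
            for t, plist in s.children.items()
            for p in plist
        }
        expected = {}
        for target, plist in children.items():
            thr = 0.5 if TARGET_ROLES[target] == "presynaptic" else 0.0625
            for child in plist:
                fracs = [(overlap_fraction(child, a), -a.id, a.id) for a in anchors]
                best = max(fracs)
                if best[0] >= thr:
                    expected[(target, child.id)] = best[2]
        assert got == expected

    def test_class_labels_partition_anchor_count(self, assembled_default_field):
        _, _, synapses, _ = assembled_default_field
        labels = [s.class_label for s in synapses]
        total = sum(
            labels.count(k) for k in ("excitatory", "inhibitory", "dual", "unknown")
        )
        assert total == len(synapses)


class TestClassification:
    def _syn(self, vglut=0, vgat=0):
        anchor = block(1, "Synapsin1", 10, 14, 10, 14)
        s = Synapse(anchor=anchor)
        if vglut:
            s.children["vGlut1"] = [block(1, "vGlut1", 11, 13, 11, 13)]
        if vgat:
            s.children["vGAT"] = [block(1, "vGAT", 11, 13, 11, 13)]
        return s

    def test_taxonomy(self):
        assert classify_synapse(self._syn(vglut=1)) == "excitatory"
        assert classify_synapse(self._syn(vgat=1)) == "inhibitory"
        assert classify_synapse(self._syn(vglut=1, vgat=1)) == "dual"
        assert classify_synapse(self._syn()) == "unknown"


class TestEndToEndRecovery:
    def test_zero_noise_recall_and_classification(self):
        """On a clean field the pipeline recovers nearly every ground-truth
        synapse within 2 px, and matched synapses carry the true class."""
        config = noise_free(image_shape=(256, 256), seed=31)
        mfield, truth = generate_field(config, 0, 0)
        run_config = RunConfig()
        proc = process_field(mfield, run_config)
        thresholds = compute_thresholds([proc], run_config)
        synapses, _ = assemble_field(proc, thresholds, run_config)
        detected = np.array([s.anchor.centroid for s in synapses])
        tcent = truth.synapses[["row", "col"]].to_numpy()
        dist, idx = cKDTree(detected).query(tcent, k=1)
        assert (dist <= 2).mean() >= 0.95
        matched = dist <= 2
        agree = sum(
            synapses[i].class_label == cls
            for i, cls, ok in zip(idx, truth.synapses["class"], matched)
            if ok
        )
        assert agree / matched.sum() >= 0.9
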