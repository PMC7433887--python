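"""Segmentation contracts: projection, labelling, nesting, filtering."""

import numpy as np
import pytest

from organoidscreen import (AcquisitionParams, ImageStack,
                            PhenotypeParams, ValidationError,
                            generate_well_stack, project_stack,
                            segment_lumens, segment_nuclei,
                            segment_organoids, segment_well, filter_objects)

from conftest import make_fixture_stack, organoid_record


@pytest.fixture(scope="module")
def blank_stack(acq):
    stack, _ = generate_well_stack(
        PhenotypeParams(n_organoids=0), acq, seed=2, well_id="BLANK")
    return stack


class TestProjection:
    def test_single_plane_projection_is_identity(self):
        acq1 = AcquisitionParams(n_z_planes=1, frame_shape=(64, 64))
        rng = np.random.default_rng(0)
        img = rng.integers(0, 1000, size=(1, 64, 64)).astype(np.uint16)
        stack = ImageStack(img, img.copy(), acq1)
        proj = project_stack(stack)
        assert np.array_equal(proj.actin_2d, img[0])

    def test_projection_takes_per_pixel_max(self, acq):
        vol = np.zeros((acq.n_z_planes, 64, 64), dtype=np.uint16)
        vol[13, 10, 20] = 10
        stack = ImageStack(vol.copy(), vol.copy(),
                           AcquisitionParams(frame_shape=(64, 64)))
        proj = project_stack(stack)
        assert proj.actin_2d[10, 20] == 10
        assert proj.focus_map[10, 20] == 13

    def test_25_plane_stack_projects_to_single_frame(self, default_well):
        stack, _ = default_well
        proj = project_stack(stack)
        assert proj.actin_2d.shape == stack.acquisition.frame_shape
        assert proj.nuclei_2d.ndim == 2

    def test_mismatched_shapes_rejected(self, acq):
        a = np.zeros((acq.n_z_planes, 64, 64), dtype=np.uint16)
        b = np.zeros((acq.n_z_planes, 64, 65), dtype=np.uint16)
        with pytest.raises(ValidationError):
            ImageStack(a, b, AcquisitionParams(frame_shape=(64, 64)))


class TestOrganoidSegmentation:
    def test_blank_noise_frame_yields_no_labels(self, blank_stack):
        proj = project_stack(blank_stack)
        labels = segment_organoids(proj)
        assert labels.max() == 0

    def test_five_separated_organoids_recovered(self, default_well):
        stack, gt = default_well
        proj = project_stack(stack)
        labels = segment_organoids(proj)
        assert labels.max() == 5
        # each ground-truth centre lies within its own organoid radius of
        # a recovered centroid
        from skimage import measure
        centroids = [p.centroid for p in measure.regionprops(labels)]
        for row in gt.itertuples():
            r_px = row.radius_um / stack.acquisition.pixel_size
            d = min(np.hypot(cy - row.y, cx - row.x)
                    for cy, cx in centroids)
            assert d < r_px

    def test_touching_pair_split_by_watershed(self, acq):
        r = 55.0
        r_px = r / acq.pixel_size
        stack, _ = make_fixture_stack([
            organoid_record(1, x=128 - 0.85 * r_px, radius_um=r,
                            lumen_radius_um=0.5 * r, n_nuclei=10),
            organoid_record(2, x=128 + 0.85 * r_px, radius_um=r,
                            lumen_radius_um=0.5 * r, n_nuclei=10),
        ], acq, seed=3)
        labels = segment_organoids(project_stack(stack))
        assert labels.max() == 2

    def test_labels_consecutive_from_one(self, default_well):
        stack, _ = default_well
        labels = segment_organoids(project_stack(stack))
        present = np.unique(labels)
        assert present[0] == 0
        assert np.array_equal(present[1:],
                              np.arange(1, labels.max() + 1))


class TestLumens:
    def test_solid_organoid_has_no_lumen(self, acq):
        stack, _ = make_fixture_stack(
            [organoid_record(lumen_radius_um=0.0)], acq, seed=1)
        proj = project_stack(stack)
        org = segment_organoids(proj)
        lumens, parents = segment_lumens(org, proj)
        assert lumens.max() == 0 and parents == {}

    def test_half_radius_lumen_area_ratio_near_quarter(self, acq):
        # concentric discs: projected lumen/organoid area = 0.5^2 = 0.25
        stack, _ = make_fixture_stack(
            [organoid_record(radius_um=70.0, lumen_radius_um=35.0)],
            acq, seed=1)
        proj = project_stack(stack)
        org = segment_organoids(proj)
        lumens, parents = segment_lumens(org, proj)
        assert len(parents) == 1
        ratio = (lumens > 0).sum() / (org > 0).sum()
        assert 0.25 * 0.8 <= ratio <= 0.25 * 1.2

    def test_two_organoids_two_lumens_correct_parents(self, acq):
        stack, _ = make_fixture_stack([
            organoid_record(1, x=70.0, radius_um=55.0,
                            lumen_radius_um=27.0),
            organoid_record(2, x=190.0, radius_um=55.0,
                            lumen_radius_um=27.0),
        ], acq, seed=2)
        proj = project_stack(stack)
        org = segment_organoids(proj)
        lumens, parents = segment_lumens(org, proj)
        assert len(parents) == 2
        from skimage import measure
        for lid, oid in parents.items():
            cy, cx = measure.regionprops(
                (lumens == lid).astype(np.uint8))[0].centroid
            assert org[int(cy), int(cx)] == oid

    def test_lumen_pixels_nested_in_parent(self, default_well):
        stack, _ = default_well
        proj, masks = segment_well(stack)
        for lid, oid in masks.parent_of_lumen.items():
            inside = masks.organoid_labels[masks.lumen_labels == lid]
            assert (inside == oid).all()


class TestNuclei:
    def test_twelve_separated_nuclei_counted(self, acq):
        # one large organoid, nuclei rendered well apart on the shell
        stack, gt = make_fixture_stack(
            [organoid_record(radius_um=90.0, lumen_radius_um=45.0,
                             n_nuclei=12)], acq, seed=5)
        proj = project_stack(stack)
        org = segment_organoids(proj)
        nuclei, parents = segment_nuclei(proj, org)
        assert 10 <= len(parents) <= 12   # projection can merge a pair
        assert set(parents.values()) == {1}

    def test_blank_frame_has_no_nuclei(self, blank_stack):
        proj = project_stack(blank_stack)
        org = segment_organoids(proj)
        nuclei, parents = segment_nuclei(proj, org)
        assert nuclei.max() == 0 and parents == {}

    def test_nucleus_outside_organoids_discarded(self, acq):
        # nuclei blob far from any organoid: simulate by zeroing organoids
        stack, _ = make_fixture_stack(
            [organoid_record(n_nuclei=8, radius_um=70.0)], acq, seed=4)
        proj = project_stack(stack)
        org = np.zeros_like(proj.actin_2d, dtype=np.int32)
        nuclei, parents = segment_nuclei(proj, org)
        assert parents == {}


class TestFilterObjects:
    def test_all_in_focus_well_unchanged(self, default_well):
        stack, _ = default_well
        proj, masks = segment_well(stack, apply_filter=False)
        filtered = filter_objects(masks, stack)
        assert filtered.organoid_labels.max() == masks.organoid_labels.max()

    def test_defocused_organoids_removed(self, acq):
        pheno = PhenotypeParams(n_organoids=6, out_of_focus_fraction=0.4)
        stack, gt = generate_well_stack(pheno, acq, seed=11)
        proj, masks = segment_well(stack)
        assert masks.organoid_labels.max() == int(gt["in_focus"].sum())

    def test_border_clipped_organoid_removed(self, acq):
        stack, _ = make_fixture_stack(
            [organoid_record(1, x=2.0, y=128.0, radius_um=60.0),
             organoid_record(2, x=128.0, y=128.0, radius_um=60.0)],
            acq, seed=6)
        # bypass placement margins: first organoid straddles the frame edge
        proj, masks = segment_well(stack)
        assert masks.organoid_labels.max() == 1

    def test_filter_idempotent(self, acq):
        pheno = PhenotypeParams(n_organoids=6, out_of_focus_fraction=0.3)
        stack, _ = generate_well_stack(pheno, acq, seed=21)
        _, masks = segment_well(stack)
        again = filter_objects(masks, stack)
        assert np.array_equal(again.organoid_labels, masks.organoid_labels)
        assert again.parent_of_nucleus == masks.parent_of_nucleus


class TestNestingProperty:
    def test_every_nucleus_centroid_inside_an_organoid(self, default_well):
        stack, _ = default_well
        proj, masks = segment_well(stack)
        from skimage import measure
        for p in measure.regionprops(masks.nucleus_labels):
            cy, cx = p.centroid
            oid = masks.organoid_labels[int(round(cy)), int(round(cx))]
            assert oid == masks.parent_of_nucleus[p.label]
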