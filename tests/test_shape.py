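import numpy as np
import pytest

from tractshape import (
    DESCRIPTOR_NAMES,
    TrajectoryBundle,
    VoxelSet,
    bundle_diameter,
    bundle_length,
    bundle_span,
    bundle_surface_area,
    bundle_volume,
    compute_profile,
    curl,
    elongation,
    irregularity,
    voxelize_bundle,
)
from tractshape.synthetic import make_arc, make_cylinder


def straight_line(length=100.0, n=101):
    return np.column_stack([np.linspace(0, length, n), np.zeros(n), np.zeros(n)])


class TestLengthSpanCurl:
    def test_straight_streamline_length_and_span(self):
        b = TrajectoryBundle([straight_line(100.0)])
        assert bundle_length(b) == pytest.approx(100.0)
        assert bundle_span(b) == pytest.approx(100.0)
        assert curl(bundle_length(b), bundle_span(b)) == pytest.approx(1.0)

    def test_length_is_mean_over_streamlines(self):
        b = TrajectoryBundle([straight_line(80.0), straight_line(120.0)])
        assert bundle_length(b) == pytest.approx(100.0)

    def test_semicircle_arc_length_and_chord(self):
        theta = np.linspace(0, np.pi, 2000)
        arc = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), np.zeros_like(theta)])
        b = TrajectoryBundle([arc])
        assert bundle_length(b) == pytest.approx(np.pi * 50, rel=1e-3)
        assert bundle_span(b) == pytest.approx(100.0, rel=1e-9)
        assert curl(bundle_length(b), bundle_span(b)) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_closed_loop_curl_undefined(self):
        theta = np.linspace(0, 2 * np.pi, 100)
        loop = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        b = TrajectoryBundle([loop])
        with pytest.raises(ValueError):
            curl(bundle_length(b), bundle_span(b))

    def test_curl_arithmetic(self):
        assert curl(150.0, 100.0) == pytest.approx(1.5)


class TestVolumeDiameterElongation:
    def test_single_voxel_volume_at_scale_two(self):
        vox = VoxelSet(np.array([[0, 0, 0]]), scale=2, base_voxel_size_mm=1.0)
        assert bundle_volume(vox) == pytest.approx(0.125)

    def test_diameter_inverts_cylinder_volume(self):
        V = np.pi * 25 * 100  # r=5, L=100
        assert bundle_diameter(V, 100.0) == pytest.approx(10.0)
        assert bundle_diameter(100.0, 100.0) == pytest.approx(1.1284, rel=1e-4)

    def test_elongation_arithmetic(self):
        assert elongation(100.0, 10.0) == pytest.approx(10.0)
        assert elongation(7.0, 7.0) == pytest.approx(1.0)

    def test_cylinder_volume_within_discretization_error(self):
        b = make_cylinder(length_mm=100, diameter_mm=10, n_streamlines=1500, seed=4)
        V = bundle_volume(voxelize_bundle(b))
        assert V == pytest.approx(np.pi * 25 * 100, rel=0.10)


class TestSurfaceAndIrregularity:
    def test_single_voxel_surface_area(self):
        vox = VoxelSet(np.array([[0, 0, 0]]), scale=2, base_voxel_size_mm=1.0)
        assert bundle_surface_area(vox) == pytest.approx(0.25)

    def test_filled_cube_surface_area(self):
        coords = np.array(
            [[i, j, k] for i in range(5) for j in range(5) for k in range(5)]
        )
        vox = VoxelSet(coords, scale=2, base_voxel_size_mm=1.0)
        assert bundle_surface_area(vox) == pytest.approx(98 * 0.25)

    def test_cylinder_surface_area_voxel_overestimate_bounded(self):
        b = make_cylinder(length_mm=100, diameter_mm=10, n_streamlines=1500, seed=5)
        area = bundle_surface_area(voxelize_bundle(b))
        analytic = np.pi * 10 * 100 + 2 * np.pi * 25
        assert abs(area - analytic) / analytic < 0.25

    def test_irregularity_formula(self):
        # ideal cylinder with caps: (pi D L + pi D^2/2) / (pi D L) = 1 + D/(2L)
        assert irregularity(np.pi * 10 * 100 + np.pi * 50, 10, 100) == pytest.approx(1.05)
        assert irregularity(2 * np.pi * 10 * 100, 10, 100) == pytest.approx(2.0)

    def test_star_cross_section_more_irregular_than_circle(self):
        # two bundles of equal voxel volume; the 4-lobed cross-section has
        # more boundary and must score strictly higher
        rng = np.random.default_rng(11)
        n, L = 1200, 60.0
        z = np.linspace(0, L, 151)

        def bundle_from_xy(xy):
            return TrajectoryBundle(
                [
                    np.column_stack([np.full(z.size, x), np.full(z.size, y), z])
                    for x, y in xy
                ]
            )

        # star: r(theta) = 2 + 2.5*cos(4 theta)^2 ; circle of similar area
        theta = rng.uniform(0, 2 * np.pi, n)
        u = np.sqrt(rng.uniform(size=n))
        r_star = (2 + 2.5 * np.cos(4 * theta) ** 2) * u
        star = bundle_from_xy(np.column_stack([r_star * np.cos(theta), r_star * np.sin(theta)]))
        star_prof = compute_profile(star)
        r_circ = np.sqrt(star_prof.volume_mm3 / (np.pi * L)) * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, n)
        circ = bundle_from_xy(np.column_stack([r_circ * np.cos(phi), r_circ * np.sin(phi)]))
        circ_prof = compute_profile(circ)
        assert star_prof.irregularity > circ_prof.irregularity


class TestComputeProfile:
    def test_cylinder_profile_is_complete_and_sane(self):
        b = make_cylinder(length_mm=60, diameter_mm=8, n_streamlines=900, seed=6)
        prof = compute_profile(b)
        vals = prof.descriptors()
        assert set(vals) == set(DESCRIPTOR_NAMES)
        assert all(np.isfinite(v) for v in vals.values())
        assert prof.curl == pytest.approx(1.0)
        assert prof.irregularity == pytest.approx(1 + 8 / 120, rel=0.25)
        assert prof.trunk_volume_mm3 <= prof.volume_mm3 + 1e-9
        assert prof.span_mm <= prof.length_mm + 1e-9

    def test_streamline_order_invariance(self):
        b = make_cylinder(length_mm=40, diameter_mm=5, n_streamlines=300, seed=8)
        perm = TrajectoryBundle(b.streamlines[::-1], voxel_size_mm=1.0, label=b.label)
        p1 = compute_profile(b).descriptors()
        p2 = compute_profile(perm).descriptors()
        for k in DESCRIPTOR_NAMES:
            assert p1[k] == pytest.approx(p2[k], rel=1e-9), k

    def test_rigid_translation_invariance(self):
        b = make_cylinder(length_mm=40, diameter_mm=5, n_streamlines=300, seed=9)
        moved = TrajectoryBundle(
            [s + np.array([13.3, -7.7, 21.1]) for s in b.streamlines], voxel_size_mm=1.0
        )
        p1, p2 = compute_profile(b).descriptors(), compute_profile(moved).descriptors()
        assert p1["length_mm"] == pytest.approx(p2["length_mm"])
        assert p1["span_mm"] == pytest.approx(p2["span_mm"])
        # voxel metrics shift only by sub-voxel rebinning; the surface of a
        # partially covered boundary is the most phase-sensitive quantity
        assert p1["volume_mm3"] == pytest.approx(p2["volume_mm3"], rel=0.05)
        assert p1["surface_area_mm2"] == pytest.approx(p2["surface_area_mm2"], rel=0.30)

    def test_rotation_stability_of_voxel_metrics(self):
        b = make_cylinder(length_mm=50, diameter_mm=8, n_streamlines=900, seed=10)
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]) @ np.array(
            [[1, 0, 0], [0, np.cos(0.4), -np.sin(0.4)], [0, np.sin(0.4), np.cos(0.4)]]
        )
        rot = TrajectoryBundle([s_ @ R.T for s_ in b.streamlines], voxel_size_mm=1.0)
        p1, p2 = compute_profile(b), compute_profile(rot)
        assert p1.length_mm == pytest.approx(p2.length_mm, rel=1e-9)
        assert p1.span_mm == pytest.approx(p2.span_mm, rel=1e-9)
        assert p1.volume_mm3 == pytest.approx(p2.volume_mm3, rel=0.10)

    def test_similarity_scaling_of_descriptors(self):
        b = make_cylinder(length_mm=40, diameter_mm=6, n_streamlines=1500, seed=12)
        s = 1.7
        scaled = TrajectoryBundle([pts * s for pts in b.streamlines], voxel_size_mm=1.0)
        p1, p2 = compute_profile(b), compute_profile(scaled)
        assert p2.length_mm == pytest.approx(s * p1.length_mm, rel=1e-9)
        assert p2.span_mm == pytest.approx(s * p1.span_mm, rel=1e-9)
        assert p2.curl == pytest.approx(p1.curl, rel=1e-9)
        # voxel metrics scale within discretization error (the half-voxel
        # occupancy shell is relatively smaller for the scaled-up bundle)
        assert p2.volume_mm3 == pytest.approx(s**3 * p1.volume_mm3, rel=0.15)
        assert p2.diameter_mm == pytest.approx(s * p1.diameter_mm, rel=0.07)
        assert p2.elongation == pytest.approx(p1.elongation, rel=0.07)

    def test_arc_curl_matches_ground_truth(self):
        for angle in (0.1, 3 * np.pi / 4, np.pi):
            b = make_arc(angle_rad=angle, n_streamlines=60, seed=2)
            length, span = bundle_length(b), bundle_span(b)
            assert curl(length, span) == pytest.approx(b.ground_truth["curl"], rel=1e-2)
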