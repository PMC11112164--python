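"""Ellipsoid fits, closed-form curvatures and surface-ratio measures."""

import numpy as np
import pytest

from scutoid3d import geometry, phantoms, topology
from scutoid3d.topology import LayerMaps
from scutoid3d.volume_io import LabelVolume, RunConfig


def sphere_points(radius, centre=(0.0, 0.0, 0.0), n=400, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    return u * radius + np.asarray(centre)


def ellipsoid_points(semiaxes, n=400, seed=0):
    return sphere_points(1.0, n=n, seed=seed) * np.asarray(semiaxes)


class TestFitEllipsoid:
    def test_exact_sphere_recovered(self):
        fit = geometry.fit_ellipsoid(sphere_points(50.0, centre=(5, -3, 12)))
        assert np.allclose(fit.semiaxes, 50.0, atol=1e-6)
        assert np.allclose(fit.centre, (5, -3, 12), atol=1e-6)
        assert fit.residual < 1e-9

    def test_noiseless_oblate_recovered(self):
        fit = geometry.fit_ellipsoid(ellipsoid_points((40.0, 60.0, 60.0)))
        assert np.allclose(sorted(fit.semiaxes), [40, 60, 60], atol=1e-4)

    def test_rotated_ellipsoid_recovered(self):
        pts = ellipsoid_points((30.0, 50.0, 70.0))
        angle = 0.7
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(angle), -np.sin(angle)],
                [0, np.sin(angle), np.cos(angle)],
            ]
        )
        fit = geometry.fit_ellipsoid(pts @ rot.T)
        assert np.allclose(sorted(fit.semiaxes), [30, 50, 70], atol=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="9 points"):
            geometry.fit_ellipsoid(sphere_points(10.0)[:5])

    def test_coplanar_points_rejected(self):
        pts = np.column_stack(
            [np.zeros(50), np.linspace(0, 1, 50), np.linspace(1, 0, 50) ** 2]
        )
        with pytest.raises(ValueError):
            geometry.fit_ellipsoid(pts)


class TestPrincipalCurvatures:
    def test_sphere_curvature_is_inverse_radius_everywhere(self):
        fit = geometry.fit_ellipsoid(sphere_points(50.0))
        for point in [(50, 0, 0), (0, 0, -50), (30, 30, 30)]:
            k_h, k_w = geometry.principal_curvatures(fit, np.asarray(point, float))
            assert k_h == pytest.approx(1 / 50, abs=1e-6)
            assert k_w == pytest.approx(1 / 50, abs=1e-6)

    def test_spheroid_pole_curvature(self):
        a, c = 60.0, 40.0  # (z, y, x) = (c, a, a): pole on the z axis
        fit = geometry.fit_ellipsoid(ellipsoid_points((c, a, a)))
        k_h, k_w = geometry.principal_curvatures(fit, np.array([c, 0.0, 0.0]))
        assert k_h == pytest.approx(c / a**2, abs=1e-6)
        assert k_w == pytest.approx(c / a**2, abs=1e-6)

    def test_spheroid_equator_curvatures(self):
        a, c = 60.0, 40.0
        fit = geometry.fit_ellipsoid(ellipsoid_points((c, a, a)))
        k_h, k_w = geometry.principal_curvatures(fit, np.array([0.0, a, 0.0]))
        assert k_h == pytest.approx(a / c**2, abs=1e-6)
        assert k_w == pytest.approx(1 / a, abs=1e-6)

    def test_centre_point_rejected(self):
        fit = geometry.fit_ellipsoid(sphere_points(50.0))
        with pytest.raises(ValueError, match="centre"):
            geometry.principal_curvatures(fit, fit.centre)


@pytest.fixture(scope="module")
def fine_shell():
    """Concentric-sphere patch at 1 µm resolution (low discretization)."""
    spec = phantoms.default_phantom_spec(
        n_cells=120, rng_seed=13, spacing=(1.0, 1.0, 1.0)
    )
    volume, _ = phantoms.make_voronoi_epithelium(spec)
    return volume


class TestSurfaceRatioAnisotropy:
    def test_concentric_spheres_are_isotropic(self, fine_shell):
        layers = topology.extract_layers(fine_shell)
        selected = topology.select_band(fine_shell, 30.0)
        record = geometry.surface_ratio_anisotropy(fine_shell, layers, selected)
        assert record.sra <= 0.02
        # both surface ratios near outer/inner radius ratio
        assert record.SR_h == pytest.approx(80 / 55, rel=0.05)

    def test_similar_ellipsoids_have_zero_anisotropy_and_sr_equal_scale(self):
        # apical = s * basal (uniform scaling): every radius scales by s,
        # so SR_h = SR_w = s and sra = 0 in the continuum
        s = 1.3
        basal_axes = np.array([50.0, 60.0, 70.0])
        apical = geometry.fit_ellipsoid(ellipsoid_points(basal_axes * s))
        basal = geometry.fit_ellipsoid(ellipsoid_points(basal_axes))
        SR_h, SR_w = [], []
        for point in ellipsoid_points(basal_axes * (s + 1) / 2, n=30, seed=5):
            ka = geometry.principal_curvatures(apical, point)
            kb = geometry.principal_curvatures(basal, point)
            SR_h.append((1 / ka[0]) / (1 / kb[0]))
            SR_w.append((1 / ka[1]) / (1 / kb[1]))
        assert np.mean(SR_h) == pytest.approx(s, rel=1e-6)
        assert abs(np.mean(SR_h) - np.mean(SR_w)) < 1e-6

    def test_oblate_over_sphere_matches_closed_form_radii(self):
        # apical sphere R=60 over basal oblate (45, 55, 55): the anisotropy
        # of the ratio comes entirely from the basal radii, which are known
        # in closed form at the pole: R_h = R_w = a²/c ... off-pole values
        # probed against the analytic shape operator through the fit
        apical = geometry.fit_ellipsoid(sphere_points(60.0, n=600))
        basal = geometry.fit_ellipsoid(ellipsoid_points((45.0, 55.0, 55.0), n=600))
        point = np.array([-60.0, 0.0, 0.0])  # pole of the viewing axis
        ka = geometry.principal_curvatures(apical, point)
        kb = geometry.principal_curvatures(basal, point)
        SR_h = (1 / ka[0]) / (1 / kb[0])
        SR_w = (1 / ka[1]) / (1 / kb[1])
        # basal pole radii: a²/c = 55²/45; apical: 60
        expected = 60.0 / (55.0**2 / 45.0)
        assert SR_h == pytest.approx(expected, rel=0.05)
        assert SR_w == pytest.approx(expected, rel=0.05)

    def test_non_similar_surfaces_have_positive_sra(self):
        # spherical apical surface over an oblate basal surface: the
        # apical/basal radius ratio differs between the two principal
        # axes, so the anisotropy must be positive (similar surfaces —
        # one a uniform scaling of the other — would give exactly 0)
        spec = phantoms.PhantomSpec(
            outer_semiaxes=(80.0, 80.0, 80.0),
            inner_semiaxes=(55.0, 40.0, 55.0),
            n_cells=120,
            spacing=(1.0, 1.0, 1.0),
            jitter=1.0,
            cap_angle=1.1,
            rng_seed=13,
        )
        volume, _ = phantoms.make_voronoi_epithelium(spec)
        layers = topology.extract_layers(volume)
        selected = topology.select_band(volume, 30.0)
        record = geometry.surface_ratio_anisotropy(volume, layers, selected)
        assert record.sra > 0.05

    def test_too_few_cells_rejected(self, fine_shell):
        layers = topology.extract_layers(fine_shell)
        with pytest.raises(ValueError, match="9 selected"):
            geometry.surface_ratio_anisotropy(fine_shell, layers, {1, 2, 3})


def cap_layer(radius, aperture_lateral, shape=(121, 121), spacing=(1.0, 1.0, 1.0)):
    """Synthetic spherical-cap depth map: depth = offset + R - sqrt(R²-r²)."""
    dz, dy, dx = spacing
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    r2 = ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
    inside = r2 <= aperture_lateral**2
    depth = np.where(inside, (radius - np.sqrt(np.clip(radius**2 - r2, 0, None))) / dz, -1.0)
    labels = inside.astype(np.int64)
    return labels, depth


class TestTissueSurfaceRatio:
    def test_flat_slab_ratio_is_one(self):
        vol = phantoms.make_prism_lattice(4, 4, cell_xy=10, height=10)
        layers = topology.extract_layers(vol)
        assert geometry.tissue_surface_ratio(layers, vol.spacing) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_concentric_caps_scale_as_radius_squared(self):
        # apical cap radius 2R over basal cap radius R, same solid angle
        # (aperture angle 30°): area ratio (2R/R)² = 4
        R = 40.0
        theta = np.pi / 6
        basal_lab, basal_depth = cap_layer(R, R * np.sin(theta))
        apical_lab, apical_depth = cap_layer(2 * R, 2 * R * np.sin(theta))
        layers = LayerMaps(
            apical_labels=apical_lab,
            basal_labels=basal_lab,
            apical_depth=apical_depth,
            basal_depth=basal_depth,
        )
        ratio = geometry.tissue_surface_ratio(layers, (1.0, 1.0, 1.0))
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_ratio_decreases_towards_one_for_thinner_shells(self):
        R = 40.0
        theta = np.pi / 6
        ratios = []
        for outer in (80.0, 60.0, 45.0):
            basal_lab, basal_depth = cap_layer(R, R * np.sin(theta))
            ap_lab, ap_depth = cap_layer(outer, outer * np.sin(theta))
            layers = LayerMaps(ap_lab, basal_lab, ap_depth, basal_depth)
            ratios.append(geometry.tissue_surface_ratio(layers, (1.0, 1.0, 1.0)))
        assert ratios[0] > ratios[1] > ratios[2] > 1.0

    def test_shell_patch_ratio_exceeds_one_on_counted_cells(self, fine_shell):
        layers = topology.extract_layers(fine_shell)
        calls = topology.call_scutoids(fine_shell, RunConfig())
        ratio = geometry.tissue_surface_ratio(
            layers, fine_shell.spacing, set(calls.counted)
        )
        assert ratio > 1.0

    def test_empty_basal_rejected(self):
        lab = np.zeros((5, 5), dtype=np.int64)
        depth = -np.ones((5, 5))
        layers = LayerMaps(lab, lab, depth, depth)
        with pytest.raises(ValueError, match="basal"):
            geometry.tissue_surface_ratio(layers, (1, 1, 1))


class TestEmbryoAxes:
    @staticmethod
    def solid(semiaxes, spacing=(1.0, 1.0, 1.0)):
        shape = tuple(int(2 * s / sp) + 5 for s, sp in zip(semiaxes, spacing))
        zz, yy, xx = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * sp for n, sp in zip(shape, spacing)],
            indexing="ij",
        )
        a, b, c = semiaxes
        mask = (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1
        return LabelVolume(mask.astype(np.int64), spacing)

    def test_sphere_aspect_ratio_is_one(self):
        _, aspect, major = geometry.embryo_axes(self.solid((40.0, 40.0, 40.0)))
        assert aspect == pytest.approx(1.0, abs=0.02)
        assert major == pytest.approx(1.0, abs=0.02)

    def test_oblate_aspect_and_major_axes_ratio(self):
        lengths, aspect, major = geometry.embryo_axes(self.solid((40.0, 60.0, 60.0)))
        assert aspect == pytest.approx(1.5, rel=0.02)
        assert major == pytest.approx(1.0, abs=0.02)

    def test_prolate_major_axes_ratio(self):
        _, aspect, major = geometry.embryo_axes(self.solid((40.0, 40.0, 60.0)))
        assert major == pytest.approx(1.5, rel=0.02)


class TestRotationInvariance:
    def test_sra_invariant_under_axis_permutation(self, fine_shell):
        layers = topology.extract_layers(fine_shell)
        selected = topology.select_band(fine_shell, 30.0)
        base = geometry.surface_ratio_anisotropy(fine_shell, layers, selected)
        # rotate the volume 90° about z (swap y and x): a rigid rotation
        rotated = LabelVolume(
            np.transpose(fine_shell.voxels, (0, 2, 1))[:, :, ::-1].copy(),
            fine_shell.spacing,
        )
        layers_r = topology.extract_layers(rotated)
        selected_r = topology.select_band(rotated, 30.0)
        rec = geometry.surface_ratio_anisotropy(rotated, layers_r, selected_r)
        assert abs(rec.sra - base.sra) <= 0.02
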