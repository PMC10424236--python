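"""Gyration/orientation estimators, KDE, superposition, RMSF and RDF."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dnapmf import (
    SimulationBox,
    build_linear_duplex_model,
    build_minicircle_model,
    coordination_number,
    first_shell_radius,
    gyration_tensor,
    kabsch_align,
    kde2d,
    orientation_angle,
    principal_axes,
    radius_of_gyration,
    rdf,
    rmsf_profile,
)
from dnapmf.analysis import OrientationSample, RDFCurve


def random_rotation(seed):
    return Rotation.from_quat(
        np.random.default_rng(seed).normal(size=4), scalar_first=False
    )


# ---------------------------------------------------------------------------
# gyration tensor and principal axes

class TestGyration:
    def test_single_point_zero(self):
        assert np.allclose(gyration_tensor([[1.0, -2.0, 3.0]]), 0.0)

    def test_two_points_single_mode(self):
        S = gyration_tensor([[-0.5, 0, 0], [0.5, 0, 0]])
        spec = principal_axes(S)
        assert spec.eigenvalues[0] == pytest.approx(0.25)  # (d/2)^2 with d=1
        assert np.allclose(spec.eigenvalues[1:], 0.0, atol=1e-15)

    def test_ideal_ring_radius_of_gyration(self):
        mol = build_minicircle_model(65, 0.338)
        assert radius_of_gyration(mol.positions) == pytest.approx(3.50, abs=5e-3)

    def test_diagonal_matrix(self):
        spec = principal_axes(np.diag([4.0, 9.0, 1.0]))
        assert list(spec.eigenvalues) == [9.0, 4.0, 1.0]
        assert np.allclose(np.abs(spec.eigenvectors),
                           np.eye(3)[:, [1, 0, 2]], atol=1e-12)
        assert spec.r_g == pytest.approx(math.sqrt(14.0))

    def test_rotated_matrix_same_spectrum(self):
        R = random_rotation(3).as_matrix()
        S = R @ np.diag([9.0, 4.0, 1.0]) @ R.T
        spec = principal_axes(S)
        assert np.allclose(spec.eigenvalues, [9.0, 4.0, 1.0], atol=1e-9)
        # axes are the rotated coordinate axes up to sign
        for k, col in enumerate([0, 1, 2]):
            dot = abs(spec.eigenvectors[:, k] @ R[:, col])
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_deterministic(self):
        spec = principal_axes(np.diag([9.0, 4.0, 1.0]))
        for k in range(3):
            v = spec.eigenvectors[:, k]
            assert v[np.flatnonzero(np.abs(v) > 1e-12)[0]] > 0

    def test_asymmetric_rejected(self):
        S = np.diag([1.0, 2.0, 3.0])
        S[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            principal_axes(S)

    def test_rotational_invariance_of_eigenvalues(self):
        rng = np.random.default_rng(11)
        pos = rng.normal(size=(40, 3))
        rot = random_rotation(7)
        e1 = principal_axes(gyration_tensor(pos)).eigenvalues
        e2 = principal_axes(gyration_tensor(rot.apply(pos))).eigenvalues
        assert np.allclose(e1, e2, atol=1e-9)


# ---------------------------------------------------------------------------
# orientation angle

class TestOrientation:
    def _rod(self, direction):
        mol = build_linear_duplex_model(10, 0.338)
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        rot, _ = Rotation.align_vectors(d[None, :], [[1.0, 0.0, 0.0]])
        return rot.apply(mol.positions)

    def test_parallel_orthogonal_antiparallel(self):
        a = self._rod([1, 0, 0])
        assert orientation_angle(a, self._rod([1, 0, 0]), "largest") == \
            pytest.approx(0.0, abs=1e-9)
        assert orientation_angle(a, self._rod([0, 1, 0]), "largest") == \
            pytest.approx(90.0, abs=1e-6)
        assert orientation_angle(a, self._rod([-1, 0, 0]), "largest") == \
            pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_rotation_invariant(self):
        a = self._rod([1, 0.3, -0.2])
        b = self._rod([0.2, 1, 0.4])
        t_ab = orientation_angle(a, b, "largest")
        assert t_ab == pytest.approx(orientation_angle(b, a, "largest"), rel=1e-12)
        rot = random_rotation(5)
        assert orientation_angle(rot.apply(a), rot.apply(b), "largest") == \
            pytest.approx(t_ab, abs=1e-9)

    def test_stacked_rings_and_known_tilt(self):
        ring = build_minicircle_model(65).positions
        assert orientation_angle(ring, ring + [0, 0, 2.0], "smallest") == \
            pytest.approx(0.0, abs=1e-9)
        for alpha in (5.7, 27.8, 45.0, 89.0):
            tilted = Rotation.from_euler("x", alpha, degrees=True).apply(ring)
            assert orientation_angle(ring, tilted, "smallest") == \
                pytest.approx(alpha, abs=1e-6)

    def test_degenerate_mode_warns(self):
        ring = build_minicircle_model(65).positions
        # a circle's two in-plane moments are equal: 'largest' is ambiguous
        with pytest.warns(UserWarning, match="degenerate"):
            orientation_angle(ring, ring + [0, 0, 2.0], "largest")

    def test_angle_bounds(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            t = orientation_angle(a, b, "largest")
            assert 0.0 <= t <= 90.0


# ---------------------------------------------------------------------------
# kernel density estimation

class TestKde:
    def test_grid_integral_unity(self):
        rng = np.random.default_rng(17)
        samples = np.column_stack([rng.uniform(3, 6, 400),
                                   rng.uniform(10, 80, 400)])
        field = kde2d(samples)
        integral = np.trapezoid(
            np.trapezoid(field.density, field.grid_theta, axis=1), field.grid_r
        )
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_single_cluster_mode_location(self):
        rng = np.random.default_rng(19)
        samples = np.column_stack([rng.normal(4.0, 0.1, 500),
                                   rng.normal(30.0, 2.0, 500)])
        field = kde2d(samples)
        i, j = np.unravel_index(np.argmax(field.density), field.density.shape)
        assert abs(field.grid_r[i] - samples[:, 0].mean()) <= 0.1
        assert abs(field.grid_theta[j] - samples[:, 1].mean()) <= 2.0

    def test_two_clusters_two_maxima(self):
        rng = np.random.default_rng(23)
        a = np.column_stack([rng.normal(3.0, 0.05, 300),
                             rng.normal(15.0, 1.0, 300)])
        b = np.column_stack([rng.normal(6.0, 0.05, 300),
                             rng.normal(70.0, 1.0, 300)])
        field = kde2d(np.vstack([a, b]))
        # local maxima along the ridge of the r marginal
        marginal = np.trapezoid(field.density, field.grid_theta, axis=1)
        peaks = [i for i in range(1, len(marginal) - 1)
                 if marginal[i] > marginal[i - 1] and marginal[i] > marginal[i + 1]]
        assert len(peaks) == 2

    def test_matches_direct_kernel_sum(self):
        rng = np.random.default_rng(29)
        data = np.column_stack([rng.uniform(2.5, 6.5, 60),
                                rng.uniform(5, 85, 60)])
        grid_r = np.linspace(2, 7, 31)
        grid_t = np.linspace(0, 90, 26)
        bw = (0.3, 6.0)
        field = kde2d(data, grid_r, grid_t, bw)
        # naive python double loop over grid points and samples
        direct = np.zeros((len(grid_r), len(grid_t)))
        for i, r in enumerate(grid_r):
            for j, t in enumerate(grid_t):
                acc = 0.0
                for (xr, xt) in data:
                    acc += math.exp(-0.5 * ((r - xr) / bw[0]) ** 2) * \
                        math.exp(-0.5 * ((t - xt) / bw[1]) ** 2)
                direct[i, j] = acc
        direct /= np.trapezoid(np.trapezoid(direct, grid_t, axis=1), grid_r)
        idx = rng.integers(0, direct.size, 100)
        assert np.allclose(field.density.ravel()[idx], direct.ravel()[idx],
                           rtol=1e-12, atol=1e-15)

    def test_zero_variance_instructs_explicit_bandwidth(self):
        samples = [OrientationSample(3.0, t) for t in (10.0, 20.0, 30.0)]
        with pytest.raises(ValueError, match="bandwidth"):
            kde2d(samples)


# ---------------------------------------------------------------------------
# superposition and RMSF

def quaternion_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    M = x.T @ y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = np.sum(x**2) + np.sum(y**2)
    return math.sqrt(max(e0 - 2.0 * lam, 0.0) / len(x))


class TestKabsch:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(31)
        pos = rng.normal(size=(12, 3))
        _, rmsd = kabsch_align(pos, pos)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_copy_zero(self):
        rng = np.random.default_rng(37)
        ref = rng.normal(size=(10, 3))
        mobile = random_rotation(2).apply(ref) + [1.0, -2.0, 0.5]
        aligned, rmsd = kabsch_align(mobile, ref)
        assert rmsd <= 1e-9
        assert np.allclose(aligned, ref, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(4, 3))
        mobile = random_rotation(seed + 50).apply(ref)
        mobile += rng.normal(0, 0.1, mobile.shape)
        _, rmsd = kabsch_align(mobile, ref)
        assert rmsd == pytest.approx(quaternion_rmsd(mobile, ref), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            kabsch_align(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsf:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(41)
        ref = rng.normal(size=(8, 3))
        prof = rmsf_profile([ref, ref, ref], ref)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_rigid_body_motion_removed(self):
        rng = np.random.default_rng(43)
        ref = rng.normal(size=(8, 3))
        frames = [random_rotation(s).apply(ref) + rng.normal(size=3)
                  for s in range(10)]
        prof = rmsf_profile(frames, ref)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_gaussian_jitter_gives_sigma_sqrt3(self):
        """Isotropic per-component jitter sigma -> RMSF = sigma * sqrt(3)
        (slightly reduced by the 6 rigid-body dof absorbed in alignment)."""
        rng = np.random.default_rng(47)
        sigma = 0.05
        ref = rng.normal(size=(60, 3))
        frames = [ref + rng.normal(0, sigma, ref.shape) for _ in range(4000)]
        prof = rmsf_profile(frames, ref)
        expected = sigma * math.sqrt(3)
        assert abs(prof.rmsf.mean() - expected) / expected < 0.05

    def test_rotational_invariance(self):
        rng = np.random.default_rng(53)
        ref = rng.normal(size=(10, 3))
        frames = [ref + rng.normal(0, 0.1, ref.shape) for _ in range(50)]
        rot = random_rotation(4)
        p1 = rmsf_profile(frames, ref)
        p2 = rmsf_profile([rot.apply(f) for f in frames], rot.apply(ref))
        assert np.allclose(p1.rmsf, p2.rmsf, atol=1e-9)


# ---------------------------------------------------------------------------
# radial distribution functions

class TestRdf:
    def test_two_fixed_particles_single_bin(self):
        box = SimulationBox(10.0)
        curve = rdf([np.array([[1.0, 1.0, 1.0]])],
                    [np.array([[1.0, 1.0, 2.33]])], box, bin_width=0.1)
        nz = np.flatnonzero(curve.g)
        assert len(nz) == 1
        assert curve.r_centers[nz[0]] == pytest.approx(1.35, abs=1e-12)

    def test_ideal_gas_flat_at_unity(self):
        rng = np.random.default_rng(59)
        box = SimulationBox(8.0)
        frames_b = [rng.uniform(0, 8.0, (400, 3)) for _ in range(60)]
        frames_a = [np.array([[4.0, 4.0, 4.0]])] * 60
        curve = rdf(frames_a, frames_b, box, bin_width=0.25, r_max=4.0)
        # expected count per bin sets the statistical bound
        for r, g, lo, hi in zip(curve.r_centers, curve.g,
                                curve.r_centers - 0.125,
                                curve.r_centers + 0.125):
            shell = 4 / 3 * math.pi * (hi**3 - lo**3)
            expected = 60 * 400 / box.volume * shell
            if expected < 10:
                continue
            assert abs(g - 1.0) <= 3.0 / math.sqrt(expected) + 0.02

    def test_hard_exclusion_zero_inside(self):
        rng = np.random.default_rng(61)
        box = SimulationBox(8.0)
        a = np.array([[4.0, 4.0, 4.0]])
        pts = rng.uniform(0, 8.0, (2000, 3))
        d = np.linalg.norm(box.min_image(pts - a[0]), axis=1)
        pts = pts[d >= 1.0]
        curve = rdf([a], [pts], box, bin_width=0.1, r_max=3.0)
        assert np.all(curve.g[curve.r_centers < 0.95] == 0.0)

    def test_same_group_plateau_counts_n_minus_one(self):
        """Ideal-gas self-RDF integrates to ~N_B - 1 over the full box
        (self pairs excluded, rho_B = N/V convention)."""
        rng = np.random.default_rng(67)
        n = 150
        box = SimulationBox(6.0, periodic=False)
        # points in a ball of radius 1.5 centred in the box: every pair
        # distance is below 3.0, so an r_max of 3.0 captures all pairs
        pts = []
        while len(pts) < n:
            p = rng.uniform(-1.5, 1.5, 3)
            if np.linalg.norm(p) < 1.5:
                pts.append(p)
        pts = np.asarray(pts) + 3.0
        curve = rdf([pts], [pts], box, bin_width=0.05, r_max=3.0,
                    same_group=True)
        n_tot = coordination_number(curve, 3.0)
        assert n_tot == pytest.approx(n - 1, rel=0.05)

    def test_r_max_beyond_half_box_rejected(self):
        with pytest.raises(ValueError, match="half"):
            rdf([np.zeros((1, 3))], [np.zeros((1, 3))], SimulationBox(6.0),
                r_max=4.0)


class TestCoordination:
    def test_uniform_g_closed_form(self):
        r = np.linspace(0.05, 3.0, 60)
        curve = RDFCurve(r, np.ones_like(r), rho_b=0.2)
        expected = 4.0 / 3.0 * math.pi * 2.0**3 * 0.2
        assert coordination_number(curve, 2.0) == pytest.approx(expected, rel=1e-3)

    def test_zero_g_zero(self):
        r = np.linspace(0.05, 3.0, 60)
        curve = RDFCurve(r, np.zeros_like(r), rho_b=0.2)
        assert coordination_number(curve, 2.0) == 0.0

    def test_single_shell_spike(self):
        # unit-area spike at r0: n = 4 pi rho r0^2 * area
        r = np.linspace(0.005, 3.0, 3000)
        dr = r[1] - r[0]
        g = np.zeros_like(r)
        r0_idx = 1000
        g[r0_idx] = 1.0 / dr  # unit area
        curve = RDFCurve(r, g, rho_b=0.3)
        r0 = r[r0_idx]
        expected = 4 * math.pi * 0.3 * r0**2
        assert coordination_number(curve, 2.0) == pytest.approx(expected, rel=1e-2)

    def test_first_shell_radius_detection(self):
        r = np.linspace(0.05, 3.0, 120)
        g = 1.0 + 2.0 * np.exp(-((r - 0.8) ** 2) / 0.02) \
            - 0.5 * np.exp(-((r - 1.3) ** 2) / 0.02)
        curve = RDFCurve(r, g, rho_b=0.1)
        assert first_shell_radius(curve) == pytest.approx(1.3, abs=0.1)
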