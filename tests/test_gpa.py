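"""Superimposition: centroid size, rotations, GPA, TPS bending energy,
semilandmark sliding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rostrumorph as rm
from rostrumorph.gpa import (
    DegenerateConfigurationError,
    bending_energy_model,
    centroid_size,
    gpa_align,
    optimal_rotation,
    procrustes_distance,
    slide_semilandmarks,
)


def _similarity_copies(base, n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        rot = Rotation.random(random_state=100 + i).as_matrix()
        coords = base.coordinates @ rot.T * rng.uniform(0.3, 3.0) + rng.normal(0, 20, 3)
        out.append(rm.LandmarkConfiguration(f"copy{i}", coords))
    return out


@pytest.fixture(scope="module")
def rostrum():
    return rm.generate_rostrum_landmarks(40, 10, 0.75, 0.5, noise_sd=0.3, seed=42)


class TestCentroidSize:
    def test_closed_form_square(self):
        pts = np.zeros((22, 3))
        pts[:4] = [[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]]
        # only first 4 points distinct; direct evaluation against loop oracle
        coords = np.vstack([pts[:4]] * 5 + [pts[:2]])
        assert coords.shape == (22, 3)
        cs = centroid_size(rm.LandmarkConfiguration("sq", coords))
        centroid = coords.mean(axis=0)
        oracle = np.sqrt(sum(((p - centroid) ** 2).sum() for p in coords))
        assert cs == pytest.approx(oracle, abs=1e-12)

    def test_four_point_exact_value(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        centred = pts - pts.mean(axis=0)
        assert np.sqrt((centred**2).sum()) == pytest.approx(np.sqrt(8))

    def test_homogeneity(self, rostrum):
        cs = centroid_size(rostrum)
        scaled = rm.LandmarkConfiguration("s", rostrum.coordinates * 3.5)
        assert centroid_size(scaled) == pytest.approx(3.5 * cs, rel=1e-12)

    def test_loop_oracle(self, rng):
        coords = rng.normal(0, 5, (22, 3))
        cfg = rm.LandmarkConfiguration("r", coords)
        centroid = coords.mean(axis=0)
        oracle = np.sqrt(sum(np.linalg.norm(p - centroid) ** 2 for p in coords))
        assert centroid_size(cfg) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(rm.LandmarkConfiguration("d", np.ones((22, 3))))


class TestOptimalRotation:
    def test_identity(self, rostrum):
        c = rostrum.coordinates - rostrum.coordinates.mean(axis=0)
        assert np.allclose(optimal_rotation(c, c), np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rostrum):
        c = rostrum.coordinates - rostrum.coordinates.mean(axis=0)
        r_true = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        target = c @ r_true  # row-vector application
        r_est = optimal_rotation(c, target)
        assert np.allclose(r_est, r_true, atol=1e-10)
        assert np.allclose(c @ r_est, target, atol=1e-9)

    def test_reflection_disallowed(self, rostrum):
        c = rostrum.coordinates - rostrum.coordinates.mean(axis=0)
        mirrored = c * np.array([1.0, 1.0, -1.0])
        r = optimal_rotation(c, mirrored)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        assert ((c @ r - mirrored) ** 2).sum() > 1e-3

    def test_mismatched_counts(self):
        with pytest.raises(ValueError):
            optimal_rotation(np.zeros((5, 3)), np.zeros((6, 3)))


class TestProcrustesDistance:
    def _unit(self, coords):
        c = coords - coords.mean(axis=0)
        return c / np.sqrt((c**2).sum())

    def test_self_distance_zero(self, rostrum):
        a = self._unit(rostrum.coordinates)
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = self._unit(rng.normal(size=(22, 3)))
            b = self._unit(rng.normal(size=(22, 3)))
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), abs=1e-12
            )

    def test_rotation_invariance(self, rostrum):
        a = self._unit(rostrum.coordinates)
        rot = Rotation.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        assert procrustes_distance(a, a @ rot) == pytest.approx(0.0, abs=1e-10)


class TestGPA:
    def test_similarity_copies_align_exactly(self, rostrum):
        """Randomly rotated/translated/scaled copies of one shape collapse to
        mutual Procrustes distance below 1e-8."""
        aligned = gpa_align(_similarity_copies(rostrum, 8))
        assert aligned.converged
        assert aligned.procrustes_distances.max() < 1e-8

    def test_two_shape_consensus_equidistant(self, rostrum, rng):
        other = rm.LandmarkConfiguration(
            "other", rostrum.coordinates + rng.normal(0, 0.8, (22, 3))
        )
        aligned = gpa_align([rostrum, other])
        d = aligned.procrustes_distances
        assert abs(d[0] - d[1]) < 1e-10

    def test_objective_monotone_descent_no_sliding(self, medium_assemblage):
        aligned = gpa_align(medium_assemblage.landmarks, slide=False)
        trace = np.array(aligned.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_alignment_invariant_to_input_transform(self, small_assemblage):
        configs = list(small_assemblage.landmarks[:8])
        base = gpa_align(configs)
        rot = Rotation.from_euler("xyz", [0.5, 0.2, -0.9]).as_matrix()
        moved = rm.LandmarkConfiguration(
            configs[0].specimen_id, configs[0].coordinates @ rot.T * 2.0 + 5.0
        )
        redo = gpa_align([moved] + configs[1:])
        assert np.abs(redo.shapes[0] - base.shapes[0]).max() < 1e-8

    def test_consensus_unit_size(self, aligned_medium):
        assert np.sqrt((aligned_medium.consensus**2).sum()) == pytest.approx(1.0, abs=1e-8)
        assert np.abs(aligned_medium.consensus.mean(axis=0)).max() < 1e-8

    def test_degenerate_configuration_named(self, rostrum):
        bad = rm.LandmarkConfiguration("flatliner", np.ones((22, 3)))
        with pytest.raises(DegenerateConfigurationError, match="flatliner"):
            gpa_align([rostrum, bad])


class TestBendingEnergy:
    def test_affine_annihilation(self, rostrum, rng):
        model = bending_energy_model(rostrum.coordinates)
        affine = np.array([[1.0, 0.3, -0.1], [0.0, 0.8, 0.2], [0.1, 0.0, 1.2]])
        target = rostrum.coordinates @ affine.T + np.array([3.0, -1.0, 2.0])
        assert abs(model.energy(target)) < 1e-9 * centroid_size(rostrum) ** 2

    def test_psd_and_null_space_dimension(self, rostrum):
        model = bending_energy_model(rostrum.coordinates)
        form = model.bending_energy_form
        assert np.allclose(form, form.T, atol=1e-12)
        eig = np.linalg.eigvalsh(form)
        assert eig.min() > -1e-9 * max(eig.max(), 1.0)
        null_dim = int((np.abs(eig) < 1e-8 * eig.max()).sum())
        assert null_dim == 4  # {1, x, y, z} per coordinate

    def test_energy_matches_interpolation_weights_oracle(self, rng):
        """5-landmark toy: quadratic-form energy equals the energy computed
        from explicit TPS interpolation weights of the bordered system."""
        ref = rng.normal(0, 2, (5, 3))
        target = ref + rng.normal(0, 0.3, (5, 3))
        k = 5
        diff = ref[:, None] - ref[None, :]
        kmat = -np.sqrt((diff**2).sum(axis=2))  # PD orientation in 3D
        q = np.column_stack([np.ones(k), ref])
        bordered = np.zeros((k + 4, k + 4))
        bordered[:k, :k] = kmat
        bordered[:k, k:] = q
        bordered[k:, :k] = q.T
        energy = 0.0
        for c in range(3):
            rhs = np.concatenate([target[:, c], np.zeros(4)])
            sol = np.linalg.solve(bordered, rhs)
            w = sol[:k]
            energy += float(w @ kmat @ w)
        model = bending_energy_model(ref)
        assert model.energy(target) == pytest.approx(energy, rel=1e-8, abs=1e-12)

    def test_singular_reference_raises(self):
        coplanar = np.zeros((22, 3))
        coplanar[:, 0] = np.arange(22)
        coplanar[:, 2] = np.arange(22) ** 2
        with pytest.raises(DegenerateConfigurationError):
            bending_energy_model(coplanar)


class TestSliding:
    @pytest.fixture()
    def aligned_pair(self, rostrum, rng):
        other = rm.LandmarkConfiguration(
            "o", rostrum.coordinates + rng.normal(0, 0.5, (22, 3))
        )
        aligned = gpa_align([rostrum, other], slide=False)
        return aligned

    def test_fixed_point(self, aligned_pair):
        curves = (list(range(10, 16)), list(range(16, 22)))
        once = slide_semilandmarks(aligned_pair.shapes, aligned_pair.consensus, curves)
        twice = slide_semilandmarks(once, aligned_pair.consensus, curves)
        assert np.abs(twice - once).max() < 1e-8

    def test_energy_descent_after_perturbation(self, aligned_pair, rng):
        curves = (list(range(10, 16)), list(range(16, 22)))
        model = bending_energy_model(aligned_pair.consensus)
        shapes = aligned_pair.shapes.copy()
        # perturb sliders along the outline direction
        for i in range(shapes.shape[0]):
            for j in range(10, 22):
                shapes[i, j] += rng.normal(0, 0.01, 3)
        before = [model.energy(s) for s in shapes]
        slid = slide_semilandmarks(shapes, aligned_pair.consensus, curves)
        after = [model.energy(s) for s in slid]
        for b, a in zip(before, after):
            assert a <= b + 1e-12

    def test_fixed_landmarks_bitwise_unchanged(self, aligned_pair):
        curves = (list(range(10, 16)), list(range(16, 22)))
        slid = slide_semilandmarks(aligned_pair.shapes, aligned_pair.consensus, curves)
        assert np.array_equal(slid[:, :10], aligned_pair.shapes[:, :10])

    def test_sliding_never_increases_energy_in_gpa(self, small_assemblage):
        plain = gpa_align(small_assemblage.landmarks, slide=False)
        slid = gpa_align(small_assemblage.landmarks, slide=True)
        m_plain = bending_energy_model(plain.consensus)
        m_slid = bending_energy_model(slid.consensus)
        e_plain = np.mean([m_plain.energy(s) for s in plain.shapes])
        e_slid = np.mean([m_slid.energy(s) for s in slid.shapes])
        assert e_slid <= e_plain
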