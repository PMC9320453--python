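"""Kabsch superposition: exactness, optimality against oracles, invariants."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hingemd.errors import DegenerateGeometryError, ShapeError
from hingemd.superposition import (
    RigidTransform,
    apply_transform,
    kabsch_superpose,
    rmsd,
    superposed_rmsd,
)


def random_rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return RigidTransform(R, t)


def brute_force_min_rmsd(mobile, reference, n_rotations=2000, seed=0):
    """Oracle: minimum RMSD over random proper rotations + centroid match."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rots = Rotation.random(n_rotations, rng=np.random.default_rng(seed))
    mats = rots.as_matrix()  # (k, 3, 3)
    moved = np.einsum("kij,nj->kni", mats, mob)
    sq = np.mean(np.sum((moved - ref) ** 2, axis=-1), axis=-1)
    return float(np.sqrt(sq.min()))


class TestKabschExactCases:
    def test_identity_when_already_superposed(self, rng):
        pts = rng.normal(size=(8, 3))
        transform, moved = kabsch_superpose(pts, pts)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-10)
        assert rmsd(moved, pts) < 1e-12

    def test_exact_recovery_of_rigid_copy(self, rng):
        ref = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ R.T + np.array([1.0, 2.0, 3.0])
        _, moved = kabsch_superpose(mobile, ref)
        assert rmsd(moved, ref) <= 1e-8

    def test_transform_applied_to_all_atoms_not_just_fit(self, rng):
        ref = rng.normal(size=(12, 3))
        transform = random_rigid(rng)
        mobile = transform.apply(ref)
        fit = np.arange(6)
        _, moved = kabsch_superpose(mobile, ref, fit_indices=fit)
        # the non-fit atoms must come home too (rigid copy)
        assert rmsd(moved[6:], ref[6:]) <= 1e-8

    @pytest.mark.parametrize("n_points", [5, 7, 10])
    def test_matches_brute_force_rotation_sampling(self, n_points, rng):
        mobile = rng.normal(scale=3.0, size=(n_points, 3))
        reference = rng.normal(scale=3.0, size=(n_points, 3))
        ours = superposed_rmsd(mobile, reference)
        oracle = brute_force_min_rmsd(mobile, reference, 5000, seed=n_points)
        assert ours <= oracle + 1e-3

    def test_matches_scipy_align_vectors(self, rng):
        mobile = rng.normal(size=(9, 3))
        reference = rng.normal(size=(9, 3))
        ours = superposed_rmsd(mobile, reference)
        rot, rssd = Rotation.align_vectors(
            reference - reference.mean(axis=0),
            mobile - mobile.mean(axis=0))
        assert ours == pytest.approx(rssd / np.sqrt(len(mobile)), abs=1e-10)

    def test_matches_mdanalysis_rmsd(self, rng):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        mobile = rng.normal(size=(9, 3))
        reference = rng.normal(size=(9, 3))
        ours = superposed_rmsd(mobile, reference)
        theirs = mda_rms.rmsd(mobile, reference, center=True,
                              superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_chirality_preserved_no_reflection(self, rng):
        # a chiral tetrahedron whose mirror image would fit exactly: the
        # proper-rotation optimum must be worse than 0 but match the oracle
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [0.3, 0.4, 0.5]])
        mirrored = ref * np.array([1, 1, -1])
        transform, _ = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-10)
        ours = superposed_rmsd(mirrored, ref)
        assert ours > 0.1  # cannot fit the mirror image with a proper rotation
        oracle = brute_force_min_rmsd(mirrored, ref, 20000, seed=5)
        assert ours <= oracle + 1e-3


class TestDegeneracy:
    def test_two_points_raise_in_strict_mode(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(pts, pts + 1.0)

    def test_collinear_points_raise_in_strict_mode(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(pts, pts[::-1])

    def test_mismatched_shapes_raise(self, rng):
        with pytest.raises(ShapeError):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_non_strict_mode_allows_two_points(self):
        mobile = np.array([[0.0, 0, 0], [4, 0, 0]])
        reference = np.array([[0.0, 0, 0], [2, 0, 0]])
        value = superposed_rmsd(mobile, reference, strict=False)
        assert value == pytest.approx(1.0, abs=1e-10)


class TestRigidTransform:
    def test_identity_leaves_coords_unchanged(self, rng):
        pts = rng.normal(size=(5, 3))
        assert np.allclose(RigidTransform.identity().apply(pts), pts)

    def test_pure_translation(self):
        t = RigidTransform(np.eye(3), np.array([1.0, 0, 0]))
        assert np.allclose(t.apply(np.zeros(3)), [1.0, 0, 0])

    def test_inverse_composition_is_identity(self, rng):
        t = random_rigid(rng)
        pts = rng.normal(size=(6, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-10)

    def test_pairwise_distances_preserved(self, rng):
        t = random_rigid(rng)
        pts = rng.normal(size=(7, 3))
        moved = apply_transform(t, pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-10)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


@st.composite
def point_sets(draw, n_min=4, n_max=12):
    n = draw(st.integers(n_min, n_max))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=4.0, size=(n, 3))
    # reject near-degenerate sets: strict mode is exercised elsewhere
    s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if s[1] < 1e-3:
        pts[:, 1] += np.arange(n)
    return pts


class TestInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(point_sets(), point_sets())
    def test_post_fit_rmsd_never_exceeds_pre_fit(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert superposed_rmsd(a, b) <= rmsd(a, b) + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(point_sets())
    def test_forward_and_backward_fits_are_mutually_inverse(self, a):
        rng = np.random.default_rng(int(abs(a).sum() * 1000) % 2**31)
        b = a + rng.normal(scale=0.3, size=a.shape)
        t_ab, _ = kabsch_superpose(a, b)
        t_ba, _ = kabsch_superpose(b, a)
        prod = t_ab.compose(t_ba)
        assert np.allclose(prod.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(prod.translation, 0.0, atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(point_sets(), st.integers(0, 2**31 - 1))
    def test_post_fit_rmsd_invariant_to_rigid_pretransform(self, a, seed):
        rng = np.random.default_rng(seed)
        b = a + rng.normal(scale=0.5, size=a.shape)
        base = superposed_rmsd(a, b)
        t = random_rigid(rng)
        assert superposed_rmsd(t.apply(a), b) == pytest.approx(base, abs=1e-8)
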