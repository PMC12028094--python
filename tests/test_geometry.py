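import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from pbflex.geometry import (
    DihedralSeries,
    GeometryError,
    backbone_dihedrals,
    rmsd_series,
    rmsf,
    superpose,
    torsion,
    wrap_angle,
)
from pbflex.io import ConformationalEnsemble
from pbflex.synthetic import backbone_atom_table, ensemble_from_dihedrals


def oracle_torsion(p1, p2, p3, p4):
    """Independent atan2 formulation: project the outer bonds off the axis
    and measure the signed angle between the projections."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    ang = np.degrees(np.arctan2(np.dot(axis, np.cross(u, v)), np.dot(u, v)))
    return float(wrap_angle(-ang))


class TestTorsion:
    def test_planar_cis_is_zero(self):
        assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_perpendicular_sign_convention(self):
        # right-angle quadruple: convention fixes the sign at -90
        quad = ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))
        assert torsion(*quad) == pytest.approx(-90.0)
        assert torsion(*quad) == pytest.approx(oracle_torsion(*quad))

    def test_matches_independent_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            expected = oracle_torsion(*pts)
            assert torsion(*pts) == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        ref = torsion(*pts)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3)
            moved = pts @ R.T + t
            assert torsion(*moved) == pytest.approx(ref, abs=1e-9)

    def test_reversal_and_mirror_symmetry(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(4, 3))
        ref = torsion(*pts)
        # point-order reversal preserves the dihedral ...
        assert torsion(*pts[::-1]) == pytest.approx(ref, abs=1e-9)
        # ... while a mirror image flips its sign
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert torsion(*mirrored) == pytest.approx(-ref, abs=1e-9)

    @pytest.mark.parametrize(
        "pts",
        [
            ((0, 0, 0), (0, 0, 0), (1, 1, 0), (0, 1, 0)),  # coincident
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)),  # collinear
        ],
    )
    def test_degenerate_raises(self, pts):
        with pytest.raises(GeometryError):
            torsion(*pts)


class TestBackboneDihedrals:
    def test_ideal_helix_round_trip(self):
        phi_set, psi_set = -57.0, -47.0
        n = 10
        phi = np.full(n, phi_set)
        psi = np.full(n, psi_set)
        phi[0] = np.nan
        psi[-1] = np.nan
        series = DihedralSeries(phi=phi[None], psi=psi[None], resids=np.arange(1, n + 1))
        ens = ensemble_from_dihedrals(series)
        back = backbone_dihedrals(ens)
        np.testing.assert_allclose(back.phi[0][1:], phi_set, atol=1e-6)
        np.testing.assert_allclose(back.psi[0][:-1], psi_set, atol=1e-6)

    def test_two_residue_termini_rule(self):
        series = DihedralSeries(
            phi=np.array([[np.nan, -60.0]]),
            psi=np.array([[-40.0, np.nan]]),
            resids=np.array([1, 2]),
        )
        ens = ensemble_from_dihedrals(series)
        back = backbone_dihedrals(ens)
        assert np.isnan(back.phi[0, 0]) and not np.isnan(back.phi[0, 1])
        assert not np.isnan(back.psi[0, 0]) and np.isnan(back.psi[0, 1])

    def test_frame_count_preserved(self, helix_ensemble):
        back = backbone_dihedrals(helix_ensemble)
        assert back.n_frames == helix_ensemble.n_frames


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        _, _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        R = Rotation.random(rng=rng).as_matrix()
        moved = pts @ R.T + np.array([3.0, -1.0, 2.0])
        _, _, rmsd = superpose(moved, pts)
        assert rmsd <= 1e-6

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # a near-mirrored set tempts an improper solution
        pts = rng.normal(size=(6, 3))
        R, _, _ = superpose(pts * np.array([1, 1, -1]), pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_scaled_square_matches_brute_force(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        scaled = 2.0 * square
        _, _, rmsd = superpose(scaled, square)

        def residual(theta):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            a = (scaled - scaled.mean(0)) @ R.T
            b = square - square.mean(0)
            return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))

        brute = minimize_scalar(residual, bounds=(-np.pi, np.pi), method="bounded")
        assert rmsd == pytest.approx(brute.fun, abs=1e-6)
        # analytic residual: centered corners at radius sqrt(2)/2 vs sqrt(2)
        assert rmsd == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_reference_frame_zero(self, helix_ensemble):
        series = rmsd_series(helix_ensemble, 0)
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_identical_frames_all_zero(self, helix_ensemble):
        series = rmsd_series(helix_ensemble)
        np.testing.assert_allclose(series, 0.0, atol=1e-6)

    def test_translation_removed(self, helix_ensemble):
        coords = helix_ensemble.coords.copy()
        coords[1] += np.array([3.0, 4.0, 0.0])
        ens = ConformationalEnsemble(coords, helix_ensemble.atoms)
        series = rmsd_series(ens)
        assert series[1] == pytest.approx(0.0, abs=1e-6)


class TestRmsf:
    def test_single_frame_zeros(self, helix_ensemble):
        single = helix_ensemble.slice_frames(slice(0, 1))
        prof = rmsf(single, fit=False)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_alternating_atom_rmsf_one(self):
        n_res, n_frames = 4, 40
        atoms = backbone_atom_table(n_res)
        base = np.arange(3 * n_res * 3, dtype=float).reshape(3 * n_res, 3)
        coords = np.tile(base, (n_frames, 1, 1))
        ca1 = 4  # CA of residue 2
        coords[1::2, ca1, 0] += 2.0  # alternate x between 0 and 2 about the base
        ens = ConformationalEnsemble(coords, atoms)
        prof = rmsf(ens, fit=False)
        assert prof.rmsf[1] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(prof.rmsf, 1)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_fitted_not_larger_than_unfitted(self, helix_ensemble):
        rng = np.random.default_rng(5)
        coords = helix_ensemble.coords + rng.normal(0, 0.3, helix_ensemble.coords.shape)
        # give frame 1 a large rigid motion that fitting should remove
        R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        coords[1] = coords[1] @ R.T + 4.0
        ens = ConformationalEnsemble(coords, helix_ensemble.atoms)
        fitted = rmsf(ens, fit=True).rmsf
        unfitted = rmsf(ens, fit=False).rmsf
        assert fitted.mean() <= unfitted.mean() + 1e-9
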