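"""Orientation statistics: oracles, sign conventions and rigid invariance.

Independent oracles used here:
- a second dihedral formula (normal-vector atan2 construction) against the
  package's projection-based formula;
- brute-force radial-angle recomputation from raw coordinates;
- fine-grid (0.01 deg) scans for the exposure-swap rotation;
- dense 0.1 A grid search for metal-bridge feasibility;
- imposed ground truth from the synthetic generators.
"""

import numpy as np
import pytest

from poregate import (
    IdealPoreSpec,
    SideChainTemplate,
    SyntheticTrajectorySpec,
    Trajectory,
    build_ideal_pore,
    generate_trajectory,
)
from poregate.errors import GeometryError, ParameterError, SelectionError
from poregate.geometry import (
    PoreFrame,
    chi1,
    circ_mean_deg,
    dihedral_deg,
    helix_bend,
    helix_rotation,
    intersubunit_min_distance,
    local_helix_axis,
    metal_bridge_feasibility,
    minimal_exposure_swap_rotation,
    place_by_internal_coords,
    pore_frame,
    radial_angle,
    radial_angle_series,
    rotamer_bin,
    rotamer_populations,
    rotation_matrix,
    sgamma_coord,
    smallest_enclosing_ball,
    wrap_deg,
)
from poregate.structure import Structure

from conftest import random_rigid_transform, transform_structure


def _mini_structure(coords, atom_names, resids, chain="A", resnames=None):
    n = len(coords)
    return Structure(
        chain_ids=[chain] * n,
        resids=resids,
        resnames=resnames or ["ALA"] * n,
        atom_names=atom_names,
        elements=["C"] * n,
        coords=np.asarray(coords, dtype=float),
    )


def _ideal_helix_ca(n, start_resid=0, radius=2.3, rise=1.5, twist=100.0):
    i = np.arange(n)
    a = np.radians(i * twist)
    return np.c_[radius * np.cos(a), radius * np.sin(a), rise * i]


class TestPoreFrame:
    def test_axis_is_z_for_ideal_pore(self, ideal_pore):
        pf = pore_frame(ideal_pore)
        assert np.abs(pf.axis - [0, 0, 1]).max() < 1e-6

    def test_origin_is_ca_centroid(self, ideal_pore):
        pf = pore_frame(ideal_pore)
        ca = ideal_pore.select(residues=(141, 174), atom_names="CA")
        assert np.abs(pf.origin - ca.coords.mean(axis=0)).max() < 1e-9

    def test_equivariance_under_rigid_rotation(self, ideal_pore, rng):
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = transform_structure(ideal_pore, R, t)
            pf = pore_frame(moved)
            assert np.abs(pf.axis - R @ [0, 0, 1]).max() < 1e-6

    def test_sign_points_to_extracellular_residue_ring(self, ideal_pore):
        # flipping the structure flips the axis (C-terminal residues high z)
        flipped = ideal_pore.with_coords(ideal_pore.coords * [1, 1, -1])
        pf = pore_frame(flipped)
        assert pf.axis[2] == pytest.approx(-1.0, abs=1e-6)
        pf2 = pore_frame(ideal_pore, extracellular_residue=174)
        assert pf2.axis[2] == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_geometry_raises(self):
        rng = np.random.default_rng(0)
        coords = []
        resids = []
        chains = []
        for ci, c in enumerate("ABC"):
            for r in range(3):
                # all points on a sphere-symmetric cluster: no unique axis
                coords.append(np.zeros(3))
                resids.append(141 + r)
                chains.append(c)
        s = Structure(
            chain_ids=chains, resids=resids, resnames=["ALA"] * 9,
            atom_names=["CA"] * 9, elements=["C"] * 9,
            coords=np.asarray(coords) + rng.normal(0, 1e-13, (9, 3)),
        )
        with pytest.raises(GeometryError):
            pore_frame(s, pore_residues=(141, 143))


class TestRadialAngle:
    def test_matches_brute_force_for_random_rotations(self, rng):
        # independently coded formula, from raw coordinates
        for _ in range(100):
            phi = rng.uniform(-180, 180)
            pore = build_ideal_pore(IdealPoreSpec(helix_rotation=float(phi)))
            pf = pore_frame(pore)
            got = radial_angle(pore, pf, "A", 157)
            ca_w = np.array(
                [pore.atom_coord("A", r, "CA") for r in range(154, 161)]
            )
            m = ca_w.mean(axis=0)
            axis = np.array([0.0, 0.0, 1.0])
            origin = pore.select(residues=(141, 174), atom_names="CA").coords.mean(0)
            foot = origin + np.dot(m - origin, axis) * axis
            v1 = foot - m
            v2 = pore.atom_coord("A", 157, "CA") - m
            expect = np.degrees(
                np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))
            )
            assert got == pytest.approx(expect, abs=1e-9)

    def test_collinear_toward_axis_is_zero(self):
        # window COM at (5,0,0); CA on the segment from COM toward the axis foot
        coords = [[5.0, 0.0, z] for z in (-3, -2, -1, 0, 1, 2, 3)]
        s = _mini_structure(coords, ["CA"] * 7, list(range(7)))
        s = Structure(
            chain_ids=s.chain_ids, resids=s.resids, resnames=s.resnames,
            atom_names=s.atom_names, elements=s.elements,
            coords=np.vstack([s.coords[:3], [[4.0, 0.0, 0.0]], s.coords[4:]]),
        )
        pf = PoreFrame(origin=np.zeros(3), axis=[0, 0, 1])
        assert radial_angle(s, pf, "A", 3) == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_is_180(self):
        coords = [[5.0, 0.0, z] for z in (-3, -2, -1, 0, 1, 2, 3)]
        coords[3] = [7.0, 0.0, 0.0]  # directly away from the axis
        s = _mini_structure(coords, ["CA"] * 7, list(range(7)))
        pf = PoreFrame(origin=np.zeros(3), axis=[0, 0, 1])
        assert radial_angle(s, pf, "A", 3) == pytest.approx(180.0, abs=1e-6)

    def test_window_com_on_axis_returns_nan(self):
        coords = [[0.0, 0.0, float(z)] for z in range(7)]
        s = _mini_structure(coords, ["CA"] * 7, list(range(7)))
        pf = PoreFrame(origin=np.zeros(3), axis=[0, 0, 1])
        assert np.isnan(radial_angle(s, pf, "A", 3))

    def test_missing_window_residue_raises(self, ideal_pore):
        with pytest.raises(SelectionError):
            pf = pore_frame(ideal_pore)
            radial_angle(ideal_pore, pf, "A", 142)  # needs 139..145

    def test_rigid_invariance(self, ideal_pore, rng):
        pf = pore_frame(ideal_pore)
        base = radial_angle(ideal_pore, pf, "B", 160)
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = transform_structure(ideal_pore, R, t)
            pf2 = pore_frame(moved)
            assert radial_angle(moved, pf2, "B", 160) == pytest.approx(
                base, abs=1e-6
            )


class TestHelixRotation:
    def test_reference_against_itself_is_zero(self, ideal_pore):
        traj = Trajectory(topology=ideal_pore, frames=ideal_pore.coords[None])
        series = helix_rotation(traj, ideal_pore, 171)
        assert abs(series.mean) < 1e-6
        assert np.abs(series.values["rotation_deg"]).max() < 1e-6

    def test_imposed_rotation_recovered_exactly_noiseless(self, ideal_spec):
        ref = build_ideal_pore(ideal_spec)
        traj = generate_trajectory(
            SyntheticTrajectorySpec(pore=ideal_spec, n_frames=3,
                                    rotation_offsets=15.0, seed=0)
        )
        series = helix_rotation(traj, ref, 171)
        assert series.mean == pytest.approx(15.0, abs=0.5)

    def test_sign_convention_clockwise_negative(self, ideal_spec):
        ref = build_ideal_pore(ideal_spec)
        traj = generate_trajectory(
            SyntheticTrajectorySpec(pore=ideal_spec, n_frames=3,
                                    rotation_offsets=-20.0, seed=0)
        )
        series = helix_rotation(traj, ref, 171)
        assert series.mean == pytest.approx(-20.0, abs=0.5)

    def test_recovery_under_noise(self, ideal_spec):
        ref = build_ideal_pore(ideal_spec)
        trajs = [
            generate_trajectory(
                SyntheticTrajectorySpec(
                    pore=ideal_spec, n_frames=50, rotation_offsets=15.0,
                    coordinate_noise_sd=0.3, seed=s, repeat_id=f"rep-{s}",
                )
            )
            for s in (1, 2)
        ]
        series = helix_rotation(trajs, ref, 171)
        assert series.mean == pytest.approx(15.0, abs=2.0)
        assert series.sem is not None

    def test_ramp_recovered_per_frame(self, ideal_spec):
        ramp = tuple(np.linspace(0.0, 15.0, 6))
        ref = build_ideal_pore(ideal_spec)
        traj = generate_trajectory(
            SyntheticTrajectorySpec(pore=ideal_spec, n_frames=6,
                                    rotation_offsets=ramp, seed=0)
        )
        series = helix_rotation(traj, ref, 171)
        per_frame = series.values.groupby("frame")["rotation_deg"].mean()
        assert np.abs(per_frame.to_numpy() - np.asarray(ramp)).max() < 0.5


class TestChi1:
    def test_agrees_with_independent_formula(self, rng):
        # oracle: dihedral from the two plane normals via atan2(cross, dot)
        def oracle(p0, p1, p2, p3):
            b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            x = np.dot(n1, n2)
            y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
            return np.degrees(np.arctan2(y, x))

        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3
            got = dihedral_deg(*pts)
            want = oracle(*pts)
            assert abs(wrap_deg(got - want)) < 1e-9

    def test_planar_cis_is_zero(self):
        pts = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        assert dihedral_deg(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        pts = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]
        assert abs(dihedral_deg(*pts)) == pytest.approx(180.0, abs=1e-12)

    def test_placement_round_trip(self, rng):
        for _ in range(200):
            a, b, c = rng.normal(size=(3, 3)) * 2
            tor = rng.uniform(-179.9, 180)
            d = place_by_internal_coords(a, b, c, 1.52, 109.5, tor)
            assert wrap_deg(dihedral_deg(a, b, c, d) - tor) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_chi1_of_decorated_pore(self, decorated_pore):
        for chain in "ABCDEF":
            assert chi1(decorated_pore, chain, 171) == pytest.approx(-88.0, abs=1e-9)
            assert chi1(decorated_pore, chain, 174) == pytest.approx(-60.0, abs=1e-9)

    def test_missing_atom_named_in_error(self):
        s = _mini_structure(
            [[0, 0, 0], [1.5, 0, 0]], ["N", "CA"], [160, 160],
            resnames=["PHE", "PHE"],
        )
        with pytest.raises(SelectionError, match="CB"):
            chi1(s, "A", 160)

    def test_residue_without_chi1_rejected(self, ideal_pore):
        with pytest.raises(SelectionError, match="ALA"):
            chi1(ideal_pore, "A", 160)  # backbone-only residue

    def test_rigid_invariance(self, decorated_pore, rng):
        base = chi1(decorated_pore, "A", 171)
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = transform_structure(decorated_pore, R, t)
            assert chi1(moved, "A", 171) == pytest.approx(base, abs=1e-6)


class TestRotamers:
    def test_all_minus88_is_pure_gminus(self):
        dist = rotamer_populations([-88.0] * 50, residue=171)
        assert dist.populations["g-"] == pytest.approx(1.0)

    def test_uniform_angles_are_thirds(self, rng):
        angles = rng.uniform(-180, 180, size=30000)
        dist = rotamer_populations(angles)
        for k in ("g+", "t", "g-"):
            assert dist.populations[k] == pytest.approx(1 / 3, abs=0.02)

    @pytest.mark.parametrize(
        "angle,expected",
        [(120.0, "g+"), (-120.0, "t"), (0.0, "g-"), (180.0, "t"),
         (-180.0, "t"), (60.0, "g+"), (-60.0, "g-")],
    )
    def test_bin_boundaries_half_open(self, angle, expected):
        assert rotamer_bin(angle) == expected

    def test_populations_sum_to_one_per_repeat(self, rng):
        series = {f"r{i}": rng.uniform(-180, 180, 100) for i in range(4)}
        dist = rotamer_populations(series)
        sums = dist.per_repeat.sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestCircularStats:
    def test_mean_of_identical_angles(self):
        assert circ_mean_deg([37.0, 37.0]) == pytest.approx(37.0)

    def test_wraparound_mean(self):
        assert abs(circ_mean_deg([170.0, -170.0])) == pytest.approx(180.0)

    def test_wrap_deg_range(self, rng):
        x = rng.uniform(-1000, 1000, 500)
        w = wrap_deg(x)
        assert np.all(w > -180) and np.all(w <= 180)
        assert np.allclose(np.cos(np.radians(w)), np.cos(np.radians(x)))


class TestHelixBend:
    def _structure(self, coords):
        n = len(coords)
        return _mini_structure(coords, ["CA"] * n, list(range(n)))

    def test_straight_helix_below_one_degree(self):
        s = self._structure(_ideal_helix_ca(17))
        assert helix_bend(s, "A", 8, arm_length=7).bend_deg < 1.0

    def test_imposed_kink_recovered(self):
        ca = _ideal_helix_ca(17)
        R = rotation_matrix([1, 0, 0], 25.0)
        ca[9:] = (ca[9:] - ca[8]) @ R.T + ca[8]
        s = self._structure(ca)
        assert helix_bend(s, "A", 8, arm_length=7).bend_deg == pytest.approx(
            25.0, abs=1.0
        )

    def test_rigid_invariance(self, rng):
        ca = _ideal_helix_ca(17)
        R0 = rotation_matrix([0, 1, 0], 18.0)
        ca[9:] = (ca[9:] - ca[8]) @ R0.T + ca[8]
        s = self._structure(ca)
        base = helix_bend(s, "A", 8, arm_length=7).bend_deg
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            moved = transform_structure(s, R, t)
            assert helix_bend(moved, "A", 8, arm_length=7).bend_deg == pytest.approx(
                base, abs=1e-6
            )

    def test_short_arm_rejected(self):
        s = self._structure(_ideal_helix_ca(17))
        with pytest.raises(ParameterError):
            helix_bend(s, "A", 8, arm_length=2)


class TestInterSubunitDistance:
    def test_two_atoms_known_distance(self):
        s = Structure(
            chain_ids=["A", "B"], resids=[10, 11], resnames=["ALA", "ALA"],
            atom_names=["CA", "CA"], elements=["C", "C"],
            coords=[[0, 0, 0], [2.5, 0, 0]],
        )
        rep = intersubunit_min_distance(s, 10, 11, chains=["A", "B"])
        assert rep.minimum == pytest.approx(2.5)

    def test_matches_all_pairs_brute_force(self, decorated_pore):
        rep = intersubunit_min_distance(decorated_pore, 174, 171)
        # brute force over the same adjacent-chain pairs
        best = np.inf
        chains = "ABCDEF"
        for k in range(6):
            for c1, c2 in (
                (chains[k], chains[(k + 1) % 6]),
                (chains[(k + 1) % 6], chains[k]),
            ):
                xa = decorated_pore.select(chains=c1, residues=174).coords
                xb = decorated_pore.select(chains=c2, residues=171).coords
                for p in xa:
                    for q in xb:
                        best = min(best, float(np.linalg.norm(p - q)))
        assert rep.minimum == pytest.approx(best, abs=1e-9)

    def test_missing_residue_raises(self, ideal_pore):
        with pytest.raises(SelectionError):
            intersubunit_min_distance(ideal_pore, 500, 171)


class TestMetalBridge:
    def _sg_structure(self, coords):
        n = len(coords)
        return Structure(
            chain_ids=[chr(ord("A") + i) for i in range(n)],
            resids=[100] * n, resnames=["CYS"] * n, atom_names=["SG"] * n,
            elements=["S"] * n, coords=coords,
        )

    def test_two_sg_4A_apart_feasible(self):
        s = self._sg_structure([[0, 0, 0], [4.0, 0, 0]])
        rep = metal_bridge_feasibility(s, [("A", 100), ("B", 100)], bond_length=2.5)
        assert rep.feasible
        assert rep.minimax_radius == pytest.approx(2.0)
        assert np.allclose(rep.metal_position, [2.0, 0, 0])

    def test_two_sg_6A_apart_infeasible(self):
        s = self._sg_structure([[0, 0, 0], [6.0, 0, 0]])
        rep = metal_bridge_feasibility(s, [("A", 100), ("B", 100)], bond_length=2.5)
        assert not rep.feasible

    def test_random_triplets_match_grid_search(self, rng):
        for _ in range(15):
            pts = rng.uniform(-2.5, 2.5, size=(3, 3))
            s = self._sg_structure(pts)
            rep = metal_bridge_feasibility(
                s, [("A", 100), ("B", 100), ("C", 100)],
                bond_length=2.5, min_coordination=3,
            )
            # dense grid oracle (0.1 A)
            lo = pts.min(axis=0) - 0.3
            hi = pts.max(axis=0) + 0.3
            axes = [np.arange(l, h + 0.05, 0.1) for l, h in zip(lo, hi)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            grid = np.c_[gx.ravel(), gy.ravel(), gz.ravel()]
            dmax = np.max(
                np.linalg.norm(grid[:, None, :] - pts[None], axis=2), axis=1
            )
            grid_feasible = bool(dmax.min() <= 2.5)
            if abs(rep.minimax_radius - 2.5) > 0.1:  # away from grid resolution
                assert rep.feasible == grid_feasible

    def test_sgamma_modelled_along_cb_gamma(self, decorated_pore):
        sg = sgamma_coord(decorated_pore, "A", 171)
        cb = decorated_pore.atom_coord("A", 171, "CB")
        cg = decorated_pore.atom_coord("A", 171, "CG")
        assert np.linalg.norm(sg - cb) == pytest.approx(1.81, abs=1e-9)
        cross = np.cross(sg - cb, cg - cb)
        assert np.linalg.norm(cross) < 1e-9  # collinear with CB->CG

    def test_enclosing_ball_matches_pairwise_bound(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            centre, radius = smallest_enclosing_ball(pts)
            # radius is at least half the diameter and covers all points
            dmat = np.linalg.norm(pts[:, None] - pts[None], axis=2)
            assert radius >= dmat.max() / 2 - 1e-6
            assert np.linalg.norm(pts - centre, axis=1).max() <= radius + 1e-6

    def test_too_few_sites_rejected(self, decorated_pore):
        with pytest.raises(ParameterError):
            metal_bridge_feasibility(decorated_pore, [("A", 171)])


class TestExposureSwap:
    @staticmethod
    def _fine_grid_oracle(structure, pf, chain, conceal, reveal, threshold,
                          step=0.01, window=3):
        """Independent vectorized brute-force scan of the swap rotation."""
        ca = structure.select(chains=chain, atom_names="CA").coords
        axis = local_helix_axis(ca)
        if np.dot(axis, pf.axis) < 0:
            axis = -axis
        point = ca.mean(axis=0)

        def window_and_ca(res):
            w = np.array(
                [structure.atom_coord(chain, r, "CA")
                 for r in range(res - window, res + window + 1)]
            )
            return w, structure.atom_coord(chain, res, "CA")

        deltas = np.arange(-180.0, 180.0 + step / 2, step)
        t = np.radians(deltas)
        k = axis

        def rotate_all(p):  # Rodrigues, vectorized over deltas
            v = p - point
            kxv = np.cross(k, v)
            kkv = k * np.dot(k, v)
            return (
                point
                + np.outer(np.cos(t), v)
                + np.outer(np.sin(t), kxv)
                + np.outer(1 - np.cos(t), kkv)
            )

        def angles(res):
            w, ca_r = window_and_ca(res)
            m = np.mean([rotate_all(p) for p in w], axis=0)
            proj = ((m - pf.origin) @ pf.axis)[:, None] * pf.axis + pf.origin
            v1 = proj - m
            v2 = rotate_all(ca_r) - m
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

        ok = (angles(conceal) > threshold) & (angles(reveal) < threshold)
        if not ok.any():
            return None
        cand = deltas[ok]
        return float(cand[np.argmin(np.abs(cand))])

    def test_matches_fine_grid_oracle(self, ideal_pore):
        pf = pore_frame(ideal_pore)
        res = minimal_exposure_swap_rotation(
            ideal_pore, pf, "A", 150, 152, threshold_deg=90.0, step_deg=0.5
        )
        assert res.feasible
        fine = self._fine_grid_oracle(ideal_pore, pf, "A", 150, 152, 90.0)
        assert fine is not None
        assert abs(abs(res.rotation_deg) - abs(fine)) <= 0.5

    def test_already_satisfied_returns_zero(self, ideal_pore):
        pf = pore_frame(ideal_pore)
        # 152 is lipid-facing (160 deg), 150 pore-facing (0 deg)
        res = minimal_exposure_swap_rotation(
            ideal_pore, pf, "A", 152, 150, threshold_deg=90.0
        )
        assert res.feasible and res.rotation_deg == 0.0

    def test_invariant_under_global_rotation(self, ideal_pore, rng):
        pf = pore_frame(ideal_pore)
        base = minimal_exposure_swap_rotation(
            ideal_pore, pf, "A", 150, 152, threshold_deg=90.0
        )
        R, t = random_rigid_transform(rng)
        moved = transform_structure(ideal_pore, R, t)
        pf2 = pore_frame(moved)
        got = minimal_exposure_swap_rotation(
            moved, pf2, "A", 150, 152, threshold_deg=90.0
        )
        assert got.rotation_deg == pytest.approx(base.rotation_deg, abs=1e-6)

    def test_infeasible_reported_not_raised(self, ideal_pore):
        # a residue cannot be simultaneously concealed and revealed
        pf = pore_frame(ideal_pore)
        res = minimal_exposure_swap_rotation(
            ideal_pore, pf, "A", 150, 150, threshold_deg=90.0
        )
        assert not res.feasible and res.rotation_deg is None


class TestRadialAngleSeries:
    def test_sem_over_repeats_not_frames(self, ideal_spec):
        trajs = [
            generate_trajectory(
                SyntheticTrajectorySpec(
                    pore=ideal_spec, n_frames=10, coordinate_noise_sd=0.2,
                    seed=s, repeat_id=f"rep-{s}",
                )
            )
            for s in range(3)
        ]
        series = radial_angle_series(trajs, 171)
        assert len(series.per_repeat_mean) == 3
        assert series.sem is not None
        single = radial_angle_series(trajs[0], 171)
        assert single.sem is None

    def test_angles_within_0_180(self, ideal_spec):
        traj = generate_trajectory(
            SyntheticTrajectorySpec(pore=ideal_spec, n_frames=5,
                                    coordinate_noise_sd=0.3, seed=9)
        )
        series = radial_angle_series(traj, 171)
        a = series.values["angle_deg"]
        assert (a >= 0).all() and (a <= 180).all()


def test_local_helix_axis_exact_for_ideal_helix():
    ca = _ideal_helix_ca(7)
    axis = local_helix_axis(ca)
    assert np.abs(axis - [0, 0, 1]).max() < 1e-12
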