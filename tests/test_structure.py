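"""Superposition, displacement fields and pore profiling."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import amparkit as ak
from amparkit.errors import DegenerateSelectionError, WindowError
from amparkit.structure import OPEN_PORE_RADIUS, VDW_RADII
from conftest import build_system


def ca_system(coords, chain="A"):
    specs = [("CA", "C", i + 1, "ALA", chain) for i in range(len(coords))]
    return build_system(specs, [coords])


def rigid(coords, degrees, translation):
    R = Rotation.from_euler("xyz", degrees, degrees=True).as_matrix()
    return np.asarray(coords) @ R.T + np.asarray(translation)


class TestKabsch:
    def test_identity_on_identical_structures(self, rng):
        coords = rng.normal(size=(12, 3)) * 5
        a, b = ca_system(coords), ca_system(coords)
        result = ak.kabsch_align(a, b)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_recovers_applied_rigid_transform(self, rng):
        coords = rng.normal(size=(15, 3)) * 8
        moved = rigid(coords, [30, 0, 0], [1, -2, 5])
        result = ak.kabsch_align(ca_system(moved), ca_system(coords))
        assert result.rmsd < 1e-6
        # applying the recovered transform inverts the applied one
        back = moved @ result.rotation.T + result.translation
        np.testing.assert_allclose(back, coords, atol=1e-6)

    def test_rmsd_invariant_under_common_rigid_motion(self, rng):
        a = rng.normal(size=(20, 3)) * 6
        b = a + rng.normal(size=(20, 3)) * 0.5
        base = ak.kabsch(a, b)[2]
        for seed in range(3):
            r = np.random.default_rng(seed)
            deg = r.uniform(-180, 180, 3)
            t = r.uniform(-30, 30, 3)
            moved = ak.kabsch(rigid(a, deg, t), rigid(b, deg, t))[2]
            assert moved == pytest.approx(base, rel=1e-9)

    def test_self_consistent_rmsd(self, rng):
        a = rng.normal(size=(10, 3)) * 4
        b = a + rng.normal(size=(10, 3)) * 0.3
        R, t, rmsd = ak.kabsch(a, b)
        direct = np.sqrt(np.mean(np.sum((a @ R.T + t - b) ** 2, axis=1)))
        assert rmsd == pytest.approx(direct, rel=1e-12)

    def test_agrees_with_mdanalysis_superposition(self, rng):
        import MDAnalysis.analysis.align as mda_align
        a = rng.normal(size=(25, 3)) * 7
        b = rigid(a + rng.normal(size=(25, 3)) * 0.4, [40, -15, 70], [3, 1, -2])
        _, _, rmsd = ak.kabsch(b, a)
        _, mda_rmsd = mda_align.rotation_matrix(b - b.mean(0), a - a.mean(0))
        assert rmsd == pytest.approx(mda_rmsd, rel=1e-6)

    def test_degenerate_selections_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(DegenerateSelectionError, match="collinear"):
            ak.kabsch_align(ca_system(line), ca_system(line + 1))
        two = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        with pytest.raises(DegenerateSelectionError):
            ak.kabsch_align(ca_system(two), ca_system(two))

    def test_unpaired_atoms_dropped_with_warning(self, rng):
        coords = rng.normal(size=(8, 3)) * 5
        a = ca_system(coords)
        b = ca_system(coords[:6])
        with pytest.warns(UserWarning, match="no counterpart"):
            result = ak.kabsch_align(a, b)
        assert result.n_atoms == 6


class TestDisplacementField:
    def test_identical_structures_zero_vectors(self, rng):
        coords = rng.normal(size=(6, 3)) * 5
        field = ak.displacement_field(ca_system(coords), ca_system(coords))
        np.testing.assert_allclose(field.table.magnitude, 0.0, atol=1e-12)

    def test_uniform_shift_reported(self, rng):
        coords = rng.normal(size=(6, 3)) * 5
        shifted = coords.copy()
        shifted[:3] += [2.0, 0.0, 0.0]
        field = ak.displacement_field(ca_system(shifted), ca_system(coords))
        moved = field.table[field.table.residue_number <= 3]
        np.testing.assert_allclose(moved[["dx", "dy", "dz"]].to_numpy(),
                                   [[2, 0, 0]] * 3, atol=1e-12)
        rest = field.table[field.table.residue_number > 3]
        np.testing.assert_allclose(rest.magnitude, 0.0, atol=1e-12)

    def test_rotation_about_pivot_matches_analytic_magnitudes(self):
        # helix along z rotated 10° about the z-axis through the origin:
        # |displacement| = 2 sin(5°) * radial distance
        theta = np.deg2rad(10.0)
        t_param = np.linspace(0, 4 * np.pi, 20)
        coords = np.stack([(2 + t_param) * np.cos(t_param),
                           (2 + t_param) * np.sin(t_param),
                           t_param], axis=1)
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        field = ak.displacement_field(ca_system(coords @ rot.T),
                                      ca_system(coords))
        radial = np.hypot(coords[:, 0], coords[:, 1])
        order = field.table.sort_values("residue_number")
        np.testing.assert_allclose(order.magnitude.to_numpy(),
                                   2 * np.sin(theta / 2) * radial, rtol=1e-9)

    def test_missing_representative_atom_skipped(self, rng):
        coords = rng.normal(size=(4, 3))
        a = ca_system(coords)
        specs = [("CA", "C", 1, "ALA", "A"), ("CB", "C", 2, "ALA", "A"),
                 ("CA", "C", 3, "ALA", "A"), ("CA", "C", 4, "ALA", "A")]
        b = build_system(specs, [coords])
        with pytest.warns(UserWarning, match="skipped"):
            field = ak.displacement_field(a, b)
        assert len(field.table) == 3


def dense_grid_min_radius(system, z, extent=0.5, step=0.02):
    """Independent dense-grid oracle for the inscribed-sphere radius.

    The grid stays near the axis (the pore interior): outside the wall the
    objective is unbounded, and the probe is defined as the local optimum
    reached from the axis."""
    coords = system.frames[0]
    vdw = np.array([VDW_RADII[e] for e in system.atoms.element])
    best = -np.inf
    for cx in np.arange(-extent, extent + step / 2, step):
        for cy in np.arange(-extent, extent + step / 2, step):
            d = np.sqrt((coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
                        + (coords[:, 2] - z) ** 2) - vdw
            best = max(best, d.min())
    return best


Z_AXIS = (np.zeros(3), np.array([0.0, 0.0, 1.0]))


class TestPoreProfile:
    def test_uniform_cylinder(self):
        fixture = ak.make_toy_pore([(z, 2.0) for z in np.arange(-6, 6.1, 0.5)])
        profile = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-5, 5),
                                  step=0.25)
        np.testing.assert_allclose(profile.radius, 2.0, atol=0.1)

    def test_stepped_profile_minimum_in_narrow_band(self):
        zs = np.arange(-6, 6.1, 0.5)
        fixture = ak.make_toy_pore([(z, 3.0 if z < 0 else 1.0) for z in zs])
        profile = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-5, 5),
                                  step=0.25)
        z_min, r_min = ak.min_radius(profile)
        assert z_min >= 0.0
        assert r_min == pytest.approx(1.0, abs=0.1)

    def test_hourglass_minimum_matches_dense_grid_oracle(self):
        zs = np.arange(-5, 5.01, 0.25)
        fixture = ak.make_toy_pore([(z, 0.9 + 0.08 * z ** 2) for z in zs],
                                   wall_atom_spacing=0.8)
        profile = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-4, 4),
                                  step=0.25)
        z_min, r_min = ak.min_radius(profile)
        assert z_min == pytest.approx(0.0, abs=0.25)
        assert r_min == pytest.approx(0.9, abs=0.1)
        oracle = dense_grid_min_radius(fixture, z=0.0)
        assert r_min == pytest.approx(oracle, abs=0.02)

    def test_adding_atoms_never_widens(self, rng):
        zs = np.arange(-3, 3.01, 0.5)
        fixture = ak.make_toy_pore([(z, 2.0) for z in zs])
        prof1 = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-2, 2), step=0.5)
        extra = build_system(
            [("CA", "C", 999, "XTR", "X")], [[[1.0, 0.0, 0.0]]])
        atoms = fixture.atoms.copy()
        extra_atoms = extra.atoms.assign(atom_id=len(atoms))
        import pandas as pd
        merged = build_system(
            [(r.atom_name, r.element, r.residue_number, r.residue_name,
              r.chain_id)
             for r in pd.concat([atoms, extra_atoms]).itertuples()],
            np.concatenate([fixture.frames, extra.frames], axis=1))
        prof2 = ak.pore_profile(merged, axis=Z_AXIS, z_range=(-2, 2), step=0.5)
        assert np.all(prof2.radius <= prof1.radius + 1e-9)

    def test_far_atoms_do_not_change_profile(self):
        zs = np.arange(-3, 3.01, 0.5)
        rings = [(z, 2.0) for z in zs]
        fixture = ak.make_toy_pore(rings)
        shell = ak.make_toy_pore([(z, 40.0) for z in zs])  # beyond 15 Å
        shell_atoms = shell.atoms.assign(
            residue_number=shell.atoms.residue_number + 100)
        import pandas as pd
        combined = build_system(
            [(r.atom_name, r.element, r.residue_number, r.residue_name,
              r.chain_id)
             for r in pd.concat([fixture.atoms, shell_atoms]).itertuples()],
            np.concatenate([fixture.frames, shell.frames], axis=1))
        p1 = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-2, 2), step=0.5)
        p2 = ak.pore_profile(combined, axis=Z_AXIS, z_range=(-2, 2), step=0.5)
        np.testing.assert_allclose(p1.radius, p2.radius, atol=1e-6)

    def test_open_plane_reports_capped_radius(self):
        fixture = ak.make_toy_pore([(-20.0, 2.0), (20.0, 2.0)])
        profile = ak.pore_profile(fixture, axis=Z_AXIS, z_range=(-1, 1),
                                  step=1.0)
        assert np.all(profile.radius == OPEN_PORE_RADIUS)


class TestMinRadius:
    def make_profile(self, radii):
        z = np.arange(len(radii), dtype=float)
        return ak.PoreProfile(z=z, radius=np.asarray(radii, dtype=float),
                              centres=np.zeros((len(radii), 3)),
                              axis_origin=np.zeros(3),
                              axis_direction=np.array([0, 0, 1.0]))

    def test_monotone_profile_returns_window_boundary(self):
        profile = self.make_profile([5, 4, 3, 2, 1])
        assert ak.min_radius(profile, (0.0, 2.0)) == (2.0, 3.0)

    def test_whole_window_equals_unrestricted(self):
        profile = self.make_profile([3, 1, 4, 2])
        assert ak.min_radius(profile) == ak.min_radius(profile, (0.0, 3.0))

    def test_tie_returns_smallest_z(self):
        profile = self.make_profile([3, 1, 1, 2])
        assert ak.min_radius(profile) == (1.0, 1.0)

    def test_empty_window_rejected(self):
        profile = self.make_profile([3, 2, 1])
        with pytest.raises(WindowError):
            ak.min_radius(profile, (10.0, 20.0))
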