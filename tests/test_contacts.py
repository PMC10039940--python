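"""Contact detection, persistence, averaging, static neighbours and
centre-of-mass distance series."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import amparkit as ak
from amparkit.errors import CoverageError, MixingError, SelectionError
from amparkit.contacts import DistanceSeries
from conftest import brute_force_contacts, build_system, random_toy_system


def two_residue_system(distance, with_close_hydrogens=False):
    """One residue per chain; closest heavy atoms separated by `distance`."""
    specs = [("CA", "C", 1, "ALA", "A"), ("CB", "C", 1, "ALA", "A"),
             ("CA", "C", 1, "ALA", "B"), ("CB", "C", 1, "ALA", "B")]
    coords = [[0, 0, 0], [0, 2, 0], [distance, 0, 0], [distance, 2, 0]]
    if with_close_hydrogens:
        specs += [("HA", "H", 1, "ALA", "A"), ("HA", "H", 1, "ALA", "B")]
        mid = distance / 2
        coords += [[mid - 1.0, 0, 0], [mid + 1.0, 0, 0]]  # H–H at 2.0 Å
    return build_system(specs, [coords])


class TestFrameContacts:
    def test_below_cutoff_in_contact(self):
        system = two_residue_system(3.9)
        pairs = ak.frame_contacts(system, 0, "chain A", "chain B", cutoff=4.0)
        assert pairs == {(("A", 1, "ALA"), ("B", 1, "ALA"))}

    def test_above_cutoff_even_with_close_hydrogens(self):
        system = two_residue_system(4.1, with_close_hydrogens=True)
        assert ak.frame_contacts(system, 0, "chain A", "chain B", cutoff=4.0) == set()

    def test_exactly_at_cutoff_excluded(self):
        system = two_residue_system(4.0)
        assert ak.frame_contacts(system, 0, "chain A", "chain B", cutoff=4.0) == set()

    def test_empty_selection_rejected(self):
        system = two_residue_system(3.0)
        with pytest.raises(SelectionError):
            ak.frame_contacts(system, 0, "chain Z", "chain B")

    def test_overlapping_selections_rejected(self):
        system = two_residue_system(3.0)
        with pytest.raises(SelectionError, match="disjoint"):
            ak.frame_contacts(system, 0, "chain A", "chain A resid 1")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        system = random_toy_system(rng, max_residues=8, max_frames=5)
        oracle = brute_force_contacts(system, "A", "B", cutoff=4.0)
        for f in range(system.n_frames):
            got = ak.frame_contacts(system, f, "chain A", "chain B", cutoff=4.0)
            assert got == oracle[f]

    def test_kdtree_and_brute_agree(self, rng):
        system = random_toy_system(rng, max_residues=10, max_frames=3)
        for f in range(system.n_frames):
            a = ak.frame_contacts(system, f, "chain A", "chain B", method="brute")
            b = ak.frame_contacts(system, f, "chain A", "chain B", method="kdtree")
            assert a == b


class TestContactPersistence:
    def test_fraction_is_simple_count(self):
        # bound in the first 60 of 100 frames, unbound after
        specs = [("CA", "C", 1, "ALA", "A"), ("CA", "C", 1, "ALA", "B")]
        frames = np.zeros((100, 2, 3))
        frames[:, 1, 0] = np.where(np.arange(100) < 60, 3.5, 9.0)
        system = build_system(specs, frames, np.arange(100) * 0.1)
        cm = ak.contact_persistence(system, "chain A", "chain B",
                                    ak.RunConfig(exclude_time=0.0))
        assert cm.entries[(("A", 1, "ALA"), ("B", 1, "ALA"))] == pytest.approx(0.60)
        assert cm.n_frames_used == 100

    def test_contact_only_in_excluded_part_absent(self):
        specs = [("CA", "C", 1, "ALA", "A"), ("CA", "C", 1, "ALA", "B")]
        frames = np.zeros((150, 2, 3))
        frames[:, 1, 0] = np.where(np.arange(150) < 50, 3.5, 9.0)
        system = build_system(specs, frames, np.arange(150) * 1.0)  # 1 ns/frame
        cm = ak.contact_persistence(
            system, "chain A", "chain B",
            ak.RunConfig(exclude_time=50.0, stride_time=1000.0))
        assert cm.entries == {}

    def test_too_short_trajectory_raises(self):
        specs = [("CA", "C", 1, "ALA", "A"), ("CA", "C", 1, "ALA", "B")]
        system = build_system(specs, np.zeros((5, 2, 3)), np.arange(5) * 1.0)
        with pytest.raises(CoverageError):
            ak.contact_persistence(system, "chain A", "chain B",
                                   ak.RunConfig(exclude_time=100.0))

    def test_markov_ground_truth_recovered(self):
        spec = ak.PairDynamicsSpec(pair=(("A", 1), ("B", 1)), stationary_p=0.6,
                                   k_switch=0.05)
        system, truth = ak.simulate_contact_trajectory([spec], n_frames=4000,
                                                       frame_dt=100, seed=11)
        cm = ak.contact_persistence(system, "chain A", "chain B",
                                    ak.RunConfig(exclude_time=0.0))
        frac = cm.entries[(("A", 1, "ALA"), ("B", 1, "ALA"))]
        assert frac == pytest.approx(truth[spec.pair].mean())
        se = ak.markov_stationary_se(0.6, 0.05, 4000)
        assert abs(frac - 0.6) < 3 * se

    def test_hydrogen_removal_leaves_results_unchanged(self, rng):
        system = random_toy_system(rng, max_residues=8, max_frames=30)
        cfg = ak.RunConfig(exclude_time=0.0, stride_time=100.0)
        with_h = ak.contact_persistence(system, "chain A", "chain B", cfg)
        heavy = system.atoms.is_heavy.to_numpy()
        stripped = build_system(
            [(r.atom_name, r.element, r.residue_number, r.residue_name,
              r.chain_id) for r in system.atoms[heavy].itertuples()],
            system.frames[:, heavy, :], system.frame_times)
        without_h = ak.contact_persistence(stripped, "chain A", "chain B", cfg)
        assert with_h.entries == without_h.entries


class TestAverageMaps:
    @staticmethod
    def make_map(entries, **prov):
        base = dict(cutoff=4.0, exclude_time=100.0, stride_time=100.0)
        base.update(prov)
        return ak.ContactMap(interface=("selA", "selB"), entries=entries,
                             n_frames_used=100, provenance=base)

    def test_replicate_mean(self):
        pair = (("A", 1, "ALA"), ("B", 2, "ALA"))
        m1 = self.make_map({pair: 0.4})
        m2 = self.make_map({pair: 0.6})
        out = ak.average_maps([m1, m2], ak.EquivalenceMap())
        assert out.entries[pair] == pytest.approx(0.5)

    def test_absent_equivalent_copy_counts_as_zero(self):
        equiv = ak.EquivalenceMap(groups=[["A", "C"], ["B", "D"]])
        m = self.make_map({(("A", 1, "ALA"), ("B", 2, "ALA")): 0.5})
        out = ak.average_maps([m], equiv)
        assert out.entries[(("A", 1, "ALA"), ("B", 2, "ALA"))] == pytest.approx(0.25)

    def test_matches_hand_computed_mean(self, rng):
        equiv = ak.EquivalenceMap(groups=[["A", "C"], ["B", "D"]])
        pairs_a = [(("A", i, "ALA"), ("B", i, "ALA")) for i in range(1, 4)]
        pairs_c = [(("C", i, "ALA"), ("D", i, "ALA")) for i in range(1, 4)]
        maps = []
        expected = {i: 0.0 for i in range(1, 4)}
        for _ in range(3):  # three replicates, two subunit copies
            entries = {}
            for i, (pa, pc) in enumerate(zip(pairs_a, pairs_c), start=1):
                fa, fc = rng.uniform(0, 1, 2).round(3)
                entries[pa] = fa
                entries[pc] = fc
                expected[i] += fa + fc
            maps.append(self.make_map(entries))
        out = ak.average_maps(maps, equiv)
        for i in range(1, 4):
            got = out.entries[(("A", i, "ALA"), ("B", i, "ALA"))]
            assert got == pytest.approx(expected[i] / 6.0)

    def test_inconsistent_provenance_rejected(self):
        pair = (("A", 1, "ALA"), ("B", 2, "ALA"))
        m1 = self.make_map({pair: 0.4})
        m2 = self.make_map({pair: 0.6}, cutoff=4.5)
        with pytest.raises(MixingError):
            ak.average_maps([m1, m2], ak.EquivalenceMap())


class TestStaticNeighborContacts:
    def test_counts_contributing_atoms(self):
        # residue A:1 with 8 heavy atoms, 3 of which sit near chain B
        specs = [(f"C{i}", "C", 1, "ARG", "A") for i in range(1, 9)]
        specs += [("CA", "C", 1, "ALA", "B")]
        coords = [[float(i * 10), 0, 0] for i in range(8)] + [[0, 0, 0]]
        coords[0] = [3.0, 0, 0]
        coords[1] = [0, 4.0, 0]
        coords[2] = [0, 0, 2.0]
        system = build_system(specs, [coords])
        counts = ak.static_neighbor_contacts(system, "chain A", "chain B",
                                             cutoff=4.5)
        assert counts == {("A", 1, "ARG"): 3}

    def test_residues_beyond_cutoff_omitted(self):
        system = two_residue_system(20.0)
        assert ak.static_neighbor_contacts(system, "chain A", "chain B") == {}

    def test_matches_brute_force(self, rng):
        system = random_toy_system(rng, max_residues=10, max_frames=1)
        counts = ak.static_neighbor_contacts(system, "chain A", "chain B",
                                             cutoff=4.5)
        atoms = system.atoms
        coords = system.frames[0]
        expected = {}
        for ra in atoms[(atoms.chain_id == "A") & atoms.is_heavy].itertuples():
            hits = 0
            for rb in atoms[(atoms.chain_id == "B") & atoms.is_heavy].itertuples():
                if np.linalg.norm(coords[ra.atom_id] - coords[rb.atom_id]) < 4.5:
                    hits = 1
                    break
            if hits:
                key = (ra.chain_id, int(ra.residue_number), ra.residue_name)
                expected[key] = expected.get(key, 0) + 1
        assert counts == expected


class TestComDistanceSeries:
    def test_single_atom_residues_constant(self):
        specs = [("CA", "C", 1, "GLY", "A"), ("CA", "C", 2, "GLY", "A")]
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 5.0
        system = build_system(specs, frames, np.arange(4) * 0.1)
        series = ak.com_distance_series(system, ("A", 1), ("A", 2))
        np.testing.assert_allclose(series.distances, 5.0)

    def test_symmetric_residues_give_midpoint_separation(self):
        # two 2-atom residues, each straddling its centre symmetrically
        specs = [("C1", "C", 1, "GLY", "A"), ("C2", "C", 1, "GLY", "A"),
                 ("C1", "C", 2, "GLY", "A"), ("C2", "C", 2, "GLY", "A")]
        coords = [[-1, 0, 0], [1, 0, 0], [6, 1, 0], [8, -1, 0]]
        system = build_system(specs, [coords])
        series = ak.com_distance_series(system, ("A", 1), ("A", 2))
        assert series.distances[0] == pytest.approx(7.0)

    def test_oscillating_pair_tracks_prescribed_sinusoid(self):
        specs = [("CA", "C", 1, "GLY", "A"), ("CA", "C", 2, "GLY", "A")]
        n = 200
        d = 6.0 + np.sin(np.arange(n) / 10.0)
        frames = np.zeros((n, 2, 3))
        frames[:, 1, 0] = d
        system = build_system(specs, frames, np.arange(n) * 0.1)
        series = ak.com_distance_series(system, ("A", 1), ("A", 2))
        np.testing.assert_allclose(series.distances, d, atol=1e-12)

    def test_side_chain_scope_excludes_backbone(self):
        specs = [("N", "N", 1, "SER", "A"), ("CA", "C", 1, "SER", "A"),
                 ("CB", "C", 1, "SER", "A"), ("CA", "C", 2, "GLY", "A")]
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]]
        system = build_system(specs, [coords])
        full = ak.com_distance_series(system, ("A", 1), ("A", 2))
        side = ak.com_distance_series(system, ("A", 1), ("A", 2),
                                      com_scope="side-chain-heavy")
        assert side.distances[0] == pytest.approx(8.0)
        assert full.distances[0] > side.distances[0]

    def test_missing_residue_raises(self):
        system = two_residue_system(5.0)
        with pytest.raises(SelectionError):
            ak.com_distance_series(system, ("A", 1), ("A", 99))


class TestOccupancy:
    def test_all_below_and_all_above(self):
        series = DistanceSeries(pair=(("A", 1, "G"), ("A", 2, "G")),
                                times=np.arange(4.0),
                                distances=np.array([1.0, 2.0, 3.0, 3.9]))
        assert ak.occupancy(series, 4.0) == 1.0
        assert ak.occupancy(series, 0.5) == 0.0

    @given(cut_lo=st.floats(0.1, 20), cut_hi=st.floats(0.1, 20),
           seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, cut_lo, cut_hi, seed):
        rng = np.random.default_rng(seed)
        series = DistanceSeries(pair=(("A", 1, "G"), ("A", 2, "G")),
                                times=np.arange(50.0),
                                distances=rng.uniform(0.5, 15.0, 50))
        lo, hi = sorted([cut_lo, cut_hi])
        assert ak.occupancy(series, lo) <= ak.occupancy(series, hi)
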