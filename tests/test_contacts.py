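"""Contact detection, aggregation identities, and lifetime statistics."""

from __future__ import annotations

import numpy as np
import pytest

from lipocontact.contacts import (
    ContactLifetimeStats,
    _events_from_bool,
    _pairs_brute,
    _pairs_cell_list,
    atom_pair_contacts,
    contact_count_series,
    contact_lifetimes,
    contact_ratio_table,
    contact_time_heatmap,
    contacts_by_residue,
    residue_atom_contact_map,
)
from lipocontact.core import Atom, Segment, Topology, Trajectory, assign_acyl_groups
from lipocontact.errors import OverlappingSelectionError
from lipocontact.selection import AtomSelection, select
from lipocontact.synthetic import (
    SyntheticSystemSpec,
    build_toy_system,
    chain_atom_names,
    sample_chain_trajectory,
)

from conftest import make_topology, selection_of


class TestAtomPairContacts:
    @pytest.mark.parametrize(
        "distance,n_pairs", [(4.999, 1), (5.000, 1), (5.001, 0)]
    )
    def test_inclusive_boundary(self, pair_system, distance, n_pairs):
        topo, build = pair_system
        traj = build([distance, distance])
        a = selection_of(topo, [0])
        b = selection_of(topo, [1])
        assert len(atom_pair_contacts(traj[0], a, b)) == n_pairs

    def test_complete_bipartite_count(self):
        topo = make_topology(
            [("CA", "C", 1, "ALA", "A", "protein")] * 2
            + [("c1", "C", 9, "LIG", "L", "ligand")] * 3
        )
        # all five atoms within 1 A of each other
        frame = np.random.default_rng(0).uniform(0, 0.5, (5, 3))
        pairs = atom_pair_contacts(frame, selection_of(topo, [0, 1]), selection_of(topo, [2, 3, 4]))
        assert len(pairs) == 6

    def test_overlapping_selections_rejected(self, pair_system):
        topo, build = pair_system
        traj = build([1.0])
        with pytest.raises(OverlappingSelectionError):
            atom_pair_contacts(traj[0], selection_of(topo, [0]), selection_of(topo, [0, 1]))

    @pytest.mark.parametrize("seed", range(10))
    def test_cell_list_equals_brute_force(self, seed):
        """Cell-list search is bit-identical to the O(N^2) oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 500))
        points = rng.uniform(0, 30, (n, 3))
        split = int(rng.integers(10, n - 10))
        a, b = points[:split], points[split:]
        got = _pairs_cell_list(a, b, 5.0)
        expected = _pairs_brute(a, b, 5.0)
        order = np.lexsort((expected[:, 1], expected[:, 0]))
        np.testing.assert_array_equal(got, expected[order])

    def test_monotone_in_cutoff_and_symmetric(self):
        rng = np.random.default_rng(3)
        topo = make_topology(
            [("CA", "C", 1, "ALA", "A", "protein")] * 40
            + [("c1", "C", 9, "LIG", "L", "ligand")] * 40
        )
        frame = rng.uniform(0, 15, (80, 3))
        a = selection_of(topo, range(40))
        b = selection_of(topo, range(40, 80))
        previous = 0
        for cutoff in (2.0, 4.0, 6.0, 8.0):
            n_pairs = len(atom_pair_contacts(frame, a, b, cutoff))
            assert n_pairs >= previous
            previous = n_pairs
        ab = atom_pair_contacts(frame, a, b, 5.0)
        ba = atom_pair_contacts(frame, b, a, 5.0)
        assert {tuple(p) for p in ab} == {(j, i) for i, j in ba}


class TestContactCountSeries:
    def test_static_frames_have_zero_sd(self, pair_system):
        topo, build = pair_system
        traj = build([3.0] * 10)
        out = contact_count_series(traj, selection_of(topo, [0]), selection_of(topo, [1]))
        assert out["mean"] == 1.0 and out["sd"] == 0.0

    def test_mean_and_population_sd(self):
        # 2 frames: 10 then 20 ligand atoms in range -> mean 15, SD 5
        topo = make_topology(
            [("CA", "C", 1, "ALA", "A", "protein")]
            + [("c1", "C", 9, "LIG", "L", "ligand")] * 20
        )
        frames = np.zeros((2, 21, 3))
        frames[0, 11:, 0] = 100.0  # frame 0: 10 far away
        traj = Trajectory(topo, frames, [0.0, 0.1])
        out = contact_count_series(
            traj, selection_of(topo, [0]), selection_of(topo, range(1, 21))
        )
        assert out["mean"] == 15.0 and out["sd"] == 5.0

    def test_empty_trajectory_rejected(self, pair_system):
        topo, build = pair_system
        with pytest.raises(ValueError):
            traj = build([])
            contact_count_series(traj, selection_of(topo, [0]), selection_of(topo, [1]))

    def test_uniform_bead_volume_fraction(self):
        """Estimated contact probability within 3 SE of the sphere/box ratio."""
        spec = SyntheticSystemSpec(
            chains=(1,), dynamics="uniform_bead", n_frames=4000, rng_seed=11
        )
        traj = sample_chain_trajectory(spec)
        prot = select(traj.topology, "segment protein")
        lig = select(traj.topology, "segment ligand")
        out = contact_count_series(traj, prot, lig)
        p = (4 / 3) * np.pi * 5.0**3 / 20.0**3
        se = np.sqrt(p * (1 - p) / spec.n_frames)
        assert abs(out["mean"] - p) < 3 * se


class TestContactsByResidue:
    def test_single_pair_assigns_to_one_residue(self, pair_system):
        topo, build = pair_system
        traj = build([4.0])
        df = contacts_by_residue(traj, selection_of(topo, [1]))
        assert df.loc[df.residue_id == 172, "mean"].item() == 1.0

    def test_confined_chain_touches_only_groove(self):
        """Anchored chain cannot reach residues far down the ridges."""
        spec = SyntheticSystemSpec(chains=(4,), n_frames=300, rng_seed=2)
        traj = sample_chain_trajectory(spec)
        lig = select(traj.topology, "segment ligand")
        df = contacts_by_residue(traj, lig)
        # reach from anchor: |anchor| + 4 bonds; residues farther than that stay 0
        anchor = np.array([0.0, 0.0, spec.anchor_height])
        reach = 4 * spec.bond_length + spec.contact_cutoff
        _, coords = build_toy_system(spec)
        for row in df.itertuples():
            atoms = [
                a.index for a in traj.topology.atoms
                if a.residue_id == row.residue_id and a.segment == Segment.PROTEIN
            ]
            min_dist = min(np.linalg.norm(coords[i] - anchor) for i in atoms)
            if min_dist > reach:
                assert row.mean == 0.0

    def test_zero_rows_are_retained(self, pair_system):
        topo, build = pair_system
        traj = build([50.0])
        df = contacts_by_residue(traj, selection_of(topo, [1]))
        assert len(df) == 1 and df["mean"].item() == 0.0

    def test_atom_duplication_doubles_counts(self):
        spec = SyntheticSystemSpec(chains=(4,), n_frames=50, rng_seed=5)
        traj = sample_chain_trajectory(spec)
        lig = select(traj.topology, "segment ligand")
        df = contacts_by_residue(traj, lig)
        # duplicate every protein atom exactly
        atoms = list(traj.topology.atoms)
        n0 = len(atoms)
        extra = [
            Atom(n0 + k, a.name + "X", a.element, a.residue_id, a.residue_name,
                 a.chain_id, a.segment)
            for k, a in enumerate(atoms)
            if a.segment == Segment.PROTEIN
        ]
        topo2 = Topology(atoms + extra)
        prot_idx = [a.index for a in atoms if a.segment == Segment.PROTEIN]
        coords2 = np.concatenate(
            [traj.coordinates, traj.coordinates[:, prot_idx]], axis=1
        )
        traj2 = Trajectory(topo2, coords2, traj.times)
        lig2 = AtomSelection(topo2, lig.indices, "ligand")
        df2 = contacts_by_residue(traj2, lig2)
        np.testing.assert_allclose(df2["mean"].to_numpy(), 2 * df["mean"].to_numpy())


@pytest.fixture
def labeled_c4_trajectory():
    spec = SyntheticSystemSpec(
        chains=(4,), n_frames=80, rng_seed=9, pseudo_hydrogens=True
    )
    traj = sample_chain_trajectory(spec)
    from lipocontact.core import acyl_atom_order

    order = acyl_atom_order(traj.topology, chain_atom_names(spec)["F1"])
    return traj, order


class TestResidueAtomContactMap:
    def test_c4_has_ten_columns_in_map_order(self, labeled_c4_trajectory):
        traj, order = labeled_c4_trajectory
        df = residue_atom_contact_map(traj, order)
        # 4 beads: 3 CH2-like columns x3 + terminal CH3 x4... here c1..c4 with
        # 2 H each except terminal 3 H -> 3+3+3+4 = 13; published C4 layout
        # (c2..c4) is checked via the explicit name order below.
        assert list(df.columns) == [traj.topology.atoms[i].name for i in order]
        names = list(df.columns)
        assert names[:3] == ["c1", "h1a", "h1b"]
        assert names[-4:] == ["c4", "h4a", "h4b", "h4c"]

    def test_single_close_pair_single_cell(self):
        topo = make_topology(
            [
                ("CA", "C", 197, "PHE", "A", "protein"),
                ("CA", "C", 172, "LEU", "B", "protein"),
                ("c4", "C", 901, "LIG", "L", "ligand"),
                ("c5", "C", 901, "LIG", "L", "ligand"),
            ]
        )
        assign_acyl_groups(topo, {"F1": ["c4", "c5"]})
        frames = np.array([[[0, 0, 0], [50, 0, 0], [4, 0, 0], [100, 0, 0]]], float)
        traj = Trajectory(topo, frames, [0.0])
        df = residue_atom_contact_map(traj, [2, 3])
        assert df.loc["F197", "c4"] == 1.0
        assert df.to_numpy().sum() == 1.0

    def test_column_sum_reproduces_per_residue_means(self, labeled_c4_trajectory):
        traj, order = labeled_c4_trajectory
        df = residue_atom_contact_map(traj, order)
        per_res = contacts_by_residue(
            traj, AtomSelection(traj.topology, np.array(order), "acyl")
        )
        np.testing.assert_allclose(
            df.sum(axis=1).to_numpy(), per_res["mean"].to_numpy(), atol=1e-12
        )

    def test_unlabeled_atom_rejected(self, pair_system):
        topo, build = pair_system
        traj = build([3.0])
        with pytest.raises(ValueError):
            residue_atom_contact_map(traj, [1])


class TestContactTimeHeatmap:
    def test_constant_trajectory_uniform_windows(self, pair_system):
        topo, build = pair_system
        traj = build([3.0] * 40)
        df = contact_time_heatmap(traj, selection_of(topo, [1]), window_ns=1.0)
        assert df.shape[1] == 4
        assert (df.to_numpy() == 1.0).all()

    def test_two_regime_schedule_localized_in_time(self):
        spec = SyntheticSystemSpec(
            chains=(6,), dynamics="two_state_schedule", n_frames=400,
            rng_seed=13, switching_prob=0.05,
        )
        traj = sample_chain_trajectory(spec)
        # force a clean two-regime split: first half in groove, second half out
        half = traj.n_frames // 2
        shifted = traj.coordinates.copy()
        lig_idx = traj.topology.indices(Segment.LIGAND)
        shifted[half:, lig_idx, 2] += 200.0
        traj2 = Trajectory(traj.topology, shifted, traj.times)
        lig = select(traj2.topology, "segment ligand")
        df = contact_time_heatmap(traj2, lig, window_ns=2.0)
        n_windows = df.shape[1]
        second_half = df.iloc[:, n_windows // 2:]
        assert second_half.to_numpy().sum() == 0.0
        assert df.to_numpy().sum() > 0.0

    def test_full_duration_window_equals_per_residue_means(self):
        spec = SyntheticSystemSpec(chains=(6,), n_frames=60, rng_seed=4)
        traj = sample_chain_trajectory(spec)
        lig = select(traj.topology, "segment ligand")
        df = contact_time_heatmap(traj, lig, window_ns=60 * 0.1 + 1)
        per_res = contacts_by_residue(traj, lig)
        assert df.shape[1] == 1
        np.testing.assert_allclose(
            df.iloc[:, 0].to_numpy(), per_res["mean"].to_numpy(), atol=1e-12
        )

    def test_partial_window_flagged(self, pair_system):
        topo, build = pair_system
        traj = build([3.0] * 25)  # 2.5 ns at 0.1 ns spacing
        df = contact_time_heatmap(traj, selection_of(topo, [1]), window_ns=1.0)
        assert df.attrs["partial_windows"] == [2]
        assert df.columns[-1].endswith("*")

    def test_window_below_frame_spacing_rejected(self, pair_system):
        topo, build = pair_system
        traj = build([3.0] * 10)
        with pytest.raises(ValueError):
            contact_time_heatmap(traj, selection_of(topo, [1]), window_ns=0.01)


class TestContactLifetimes:
    def test_event_enumeration_gap0(self, pair_system):
        topo, build = pair_system
        traj = build([3, 3, 3, 10, 10, 3])
        stats = contact_lifetimes(traj, selection_of(topo, [1]), "residue", 0)
        assert sorted(stats.event_lengths_frames) == [1, 3]
        assert stats.mean_lifetime_frames == 2.0
        np.testing.assert_allclose(stats.mean_lifetime_ns, 0.2)

    def test_gap_tolerance_merges_events(self, pair_system):
        topo, build = pair_system
        traj = build([3, 3, 3, 10, 10, 3])
        stats = contact_lifetimes(traj, selection_of(topo, [1]), "residue", 2)
        assert stats.events == [(0, 5)]
        assert stats.mean_lifetime_frames == 6.0

    def test_atom_pair_level(self, pair_system):
        topo, build = pair_system
        traj = build([3, 10, 3])
        stats = contact_lifetimes(traj, selection_of(topo, [1]), "atom_pair", 0)
        assert stats.entity_of_event == [(0, 1), (0, 1)]
        assert list(stats.event_lengths_frames) == [1, 1]

    def test_gap0_conserves_positive_frames(self):
        rng = np.random.default_rng(21)
        series = rng.random(500) < 0.3
        events = _events_from_bool(series, 0)
        assert sum(e - s + 1 for s, e in events) == series.sum()

    def test_markov_chain_mean_lifetime(self):
        """Two-state stay probability q: run lengths geometric, mean 1/(1-q)."""
        spec = SyntheticSystemSpec(
            chains=(6,), dynamics="two_state_schedule", n_frames=6000,
            rng_seed=17, switching_prob=0.2,
        )
        traj = sample_chain_trajectory(spec)
        lig = select(traj.topology, "segment ligand")
        stats = contact_lifetimes(traj, lig, "residue", 0)
        lengths = [
            e - s + 1
            for (s, e), owner in zip(stats.events, stats.entity_of_event)
            if owner == "L172"
        ]
        expected = 1.0 / spec.switching_prob
        se = np.std(lengths, ddof=1) / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - expected) < 3 * se


class TestContactRatioTable:
    def test_reported_cell_and_diagonal(self):
        df = contact_ratio_table({"C4": 100.0, "C8": 159.0})
        assert df.loc["C8", "C4"] == pytest.approx(1.59)
        assert df.loc["C4", "C4"] == 1.0 and df.loc["C8", "C8"] == 1.0

    def test_ratio_transitivity(self):
        means = {"C4": 123.4, "C8": 211.0, "C18": 333.3}
        df = contact_ratio_table(means)
        assert df.loc["C18", "C4"] == pytest.approx(
            df.loc["C18", "C8"] * df.loc["C8", "C4"], abs=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            contact_ratio_table({"C4": 0.0, "C8": 10.0})
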