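"""Superposition, RMSF, SASA, dynamical networks, communities, interfaces."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from oligomerkit import (
    Structure,
    Trajectory,
    TrajectoryBundle,
    TrajTruth,
    analysis_frame_count,
    build_network,
    communities,
    generate_trajectory,
    interface_residues,
    rmsf,
    sasa,
    superpose,
)
from oligomerkit.errors import InvalidInputError, NumericalDegeneracyError
from oligomerkit.structures import make_atom_table
from oligomerkit.trajnet import DynamicNetwork, superpose_coords


def _structure(coords, chain=None, res_id=None, element=None, atom_name=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = make_atom_table(
        chain=chain or ["A"] * n,
        res_id=res_id if res_id is not None else np.arange(1, n + 1),
        res_name=["GLY"] * n,
        atom_name=atom_name or ["CA"] * n,
        element=element or ["C"] * n,
    )
    return Structure(atoms, coords)


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


class TestSuperpose:
    def test_identical_structures_zero_rmsd(self, rng):
        s = _structure(rng.standard_normal((10, 3)))
        _, r = superpose(s, s)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self, rng):
        ref = _structure(rng.standard_normal((10, 3)) * 5)
        rot = _random_rotation(rng)
        moved = ref.with_coords(ref.coords @ rot.T + np.array([3.0, -7.0, 11.0]))
        aligned, r = superpose(moved, ref)
        assert r == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(aligned.coords, ref.coords, atol=1e-8)

    def test_rmsd_symmetric(self, rng):
        a = _structure(rng.standard_normal((8, 3)) * 4)
        b = _structure(a.coords + rng.standard_normal((8, 3)) * 0.5)
        _, rab = superpose(a, b)
        _, rba = superpose(b, a)
        assert rab == pytest.approx(rba, rel=1e-9)

    def test_displaced_atom_matches_brute_force_optimum(self, rng):
        """Our closed-form optimum matches a brute-force search over rotations."""
        ref = np.array([[1.0, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]])
        mob = ref.copy()
        mob[0, 2] += 2.0  # one atom displaced by 2 Å
        _, ours = superpose_coords(mob, ref)

        from scipy.spatial.transform import Rotation

        rots = Rotation.random(20_000, rng=np.random.default_rng(0)).as_matrix()
        p = mob @ rots.transpose(0, 2, 1)
        p = p - p.mean(axis=1, keepdims=True) + ref.mean(axis=0)  # optimal translation per rotation
        best = float(np.sqrt(((p - ref) ** 2).sum(axis=2).mean(axis=1)).min())
        assert ours <= best + 1e-9
        assert ours == pytest.approx(best, abs=0.03)

    def test_count_mismatch_rejected(self, rng):
        a = _structure(rng.standard_normal((5, 3)))
        b = _structure(rng.standard_normal((6, 3)))
        with pytest.raises(InvalidInputError):
            superpose(a, b)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(NumericalDegeneracyError):
            superpose_coords(line, line + 1.0)


class TestRmsf:
    def test_static_trajectory_zero(self):
        ref = _structure(np.random.default_rng(0).standard_normal((6, 3)))
        traj = Trajectory(ref.atoms, np.repeat(ref.coords[None], 10, axis=0))
        bundle = TrajectoryBundle([traj], ref)
        df = rmsf(bundle, burn_in_fraction=0.0)
        np.testing.assert_allclose(df["rmsf"], 0.0, atol=1e-10)

    def test_invariant_under_global_rigid_motion(self, rng):
        bundle = generate_trajectory(TrajTruth(frames=200, replicates=1, seed=3))
        base = rmsf(bundle, burn_in_fraction=0.0)
        rot = _random_rotation(rng)
        moved = Trajectory(
            bundle.atoms, bundle.replicates[0].coords @ rot.T + np.array([5.0, 6.0, 7.0])
        )
        again = rmsf(TrajectoryBundle([moved], bundle.reference), burn_in_fraction=0.0)
        np.testing.assert_allclose(again["rmsf"], base["rmsf"], rtol=1e-8)

    def test_burn_in_removes_frames(self):
        bundle = generate_trajectory(TrajTruth(frames=12, replicates=1, seed=1))
        from oligomerkit.errors import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            rmsf(bundle, burn_in_fraction=0.95)

    def test_production_analysis_frame_count(self):
        """3 replicates × 250 ns analyzed at 50 ps sampling = 15,000 frames."""
        assert analysis_frame_count(replicates=3, total_ns=300, burn_in_ns=50, sampling_ps=50) == 15_000


class TestSasa:
    def test_isolated_sphere_analytic(self):
        s = _structure([[0.0, 0.0, 0.0]], element=["X"])
        with pytest.warns(UserWarning, match="unknown element"):
            out = sasa(s, probe_radius=1.4, sphere_points=960, default_radius=1.9)
        want = 4 * math.pi * (1.9 + 1.4) ** 2  # ≈ 136.8 Å²
        assert out["sasa"][0] == pytest.approx(want, rel=0.02)

    def test_distant_atoms_additive(self):
        s = _structure([[0.0, 0, 0], [100.0, 0, 0]], res_id=[1, 2])
        out = sasa(s, sphere_points=500)
        iso = 4 * math.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(out["sasa"], iso, rtol=1e-9)

    def test_fully_buried_atom_zero(self):
        # icosahedral shell of carbons at 1 Å fully covers the central atom
        phi = (1 + math.sqrt(5)) / 2
        verts = np.array(list(itertools.product([-1, 1], [-phi, phi], [0, 0])))
        ico = []
        for a, b in itertools.product([-1.0, 1.0], [-phi, phi]):
            ico += [[0, a, b], [a, b, 0], [b, 0, a]]
        shell = np.array(ico) / np.linalg.norm(ico[0])
        coords = np.vstack([[[0.0, 0, 0]], shell])
        s = _structure(coords, res_id=[1] + [2] * len(shell))
        out = sasa(s, sphere_points=960)
        assert out.loc[out["res_id"] == 1, "sasa"].iloc[0] == 0.0

    def test_bounded_and_convergent(self, rng):
        coords = rng.standard_normal((8, 3)) * 2.0
        s = _structure(coords, res_id=np.arange(1, 9))
        coarse = sasa(s, sphere_points=240)["sasa"].to_numpy()
        fine = sasa(s, sphere_points=3000)["sasa"].to_numpy()
        iso = 4 * math.pi * (1.70 + 1.4) ** 2
        assert np.all(coarse >= 0) and np.all(coarse <= iso + 1e-9)
        np.testing.assert_allclose(coarse, fine, atol=0.05 * iso)

    def test_matches_biotite_oracle(self, rng):
        """Independent cross-check against biotite's Shrake–Rupley on one cluster."""
        import biotite.structure as struc

        coords = rng.standard_normal((12, 3)) * 2.5
        arr = struc.AtomArray(12)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 13)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=np.full(12, 1.70), point_number=2000)
        ours = sasa(
            _structure(arr.coord, res_id=np.arange(1, 13)), probe_radius=1.4, sphere_points=2000,
            per_atom=True,
        )
        np.testing.assert_allclose(ours, ref, rtol=0.05, atol=1.0)


def _bundle_from_frames(frames, res_id=None):
    frames = np.asarray(frames, dtype=float)
    s = _structure(frames[0], res_id=res_id)
    return TrajectoryBundle([Trajectory(s.atoms, frames)], s)


class TestBuildNetwork:
    def _designed_bundle(self, n_frames=100, far_fraction=0.2, rng_seed=0):
        """4 residues on a line; pair (1,3) leaves contact in a set fraction of frames."""
        rng = np.random.default_rng(rng_seed)
        frames = []
        n_far = int(round(n_frames * far_fraction))
        for i in range(n_frames):
            jitter = rng.standard_normal((4, 3)) * 0.01
            x3 = 10.0 if i < n_far else 4.0  # residue 3 relative to residue 1
            base = np.array([[0.0, 0, 0], [2.0, 0, 0], [x3, 0.0, 0.5], [6.0, 3.0, 0]])
            frames.append(base + jitter)
        return _bundle_from_frames(frames)

    def test_persistence_above_threshold_creates_edge(self):
        net = build_network(self._designed_bundle(far_fraction=0.2), cutoff=4.51, persistence=0.75, burn_in_fraction=0.0)
        assert net.graph.has_edge(0, 2)

    def test_persistence_below_threshold_no_edge(self):
        net = build_network(self._designed_bundle(far_fraction=0.26), cutoff=4.51, persistence=0.75, burn_in_fraction=0.0)
        assert not net.graph.has_edge(0, 2)

    def test_consecutive_residues_never_joined(self):
        net = build_network(self._designed_bundle(), cutoff=4.51, persistence=0.5, burn_in_fraction=0.0)
        assert not net.graph.has_edge(0, 1)  # always within 2 Å but bonded

    def test_correlations_bounded(self):
        bundle = generate_trajectory(TrajTruth(seed=4, frames=300))
        net = build_network(bundle)
        corr = [abs(d["correlation"]) for _, _, d in net.graph.edges(data=True)]
        assert corr and max(corr) <= 1.0
        pers = [d["persistence"] for _, _, d in net.graph.edges(data=True)]
        assert min(pers) >= 0.75

    def test_edges_shrink_with_stricter_parameters(self):
        bundle = generate_trajectory(TrajTruth(seed=4, frames=300))
        loose = build_network(bundle, cutoff=4.5, persistence=0.6)
        tight_cut = build_network(bundle, cutoff=4.0, persistence=0.6)
        tight_per = build_network(bundle, cutoff=4.5, persistence=0.9)
        assert set(tight_cut.graph.edges) <= set(loose.graph.edges)
        assert set(tight_per.graph.edges) <= set(loose.graph.edges)

    def test_heavy_atom_criterion_agrees_on_ca_only_chain(self):
        bundle = generate_trajectory(TrajTruth(seed=5, frames=100))
        ca = build_network(bundle, burn_in_fraction=0.0)
        heavy = build_network(bundle, burn_in_fraction=0.0, contact_atoms="heavy")
        assert set(ca.graph.edges) == set(heavy.graph.edges)


class TestCommunities:
    def _network_from_graph(self, g):
        import pandas as pd

        nodes = pd.DataFrame({"node": sorted(g), "chain": "A", "res_id": sorted(g)})
        return DynamicNetwork(graph=g, nodes=nodes, cutoff=4.5, persistence_threshold=0.75)

    def test_two_cliques_split_matches_brute_force(self):
        """Girvan–Newman on two 5-cliques + bridge equals the best 2-partition."""
        g = nx.Graph()
        for base in (0, 5):
            for i, j in itertools.combinations(range(base, base + 5), 2):
                g.add_edge(i, j, weight=0.105, correlation=0.9, abs_correlation=0.9)
        g.add_edge(4, 5, weight=2.3, correlation=0.1, abs_correlation=0.1)
        part = communities(self._network_from_graph(g))
        assert part.n_communities == 2
        got = frozenset(frozenset(n for n, c in part.assignment.items() if c == k) for k in {0, 1})
        # brute-force best 2-partition by modularity
        best, best_q = None, -np.inf
        for bits in range(1, 2**9, 2):  # node 0 fixed in part A
            a = {n for n in range(10) if (bits >> n) & 1}
            b = set(range(10)) - a
            if not b:
                continue
            q = nx.community.modularity(g, [a, b], weight="abs_correlation")
            if q > best_q:
                best, best_q = frozenset({frozenset(a), frozenset(b)}), q
        assert got == best

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(6)
        for _, _, d in g.edges(data=True):
            d.update(weight=0.1, correlation=0.9, abs_correlation=0.9)
        part = communities(self._network_from_graph(g))
        assert part.n_communities == 1

    def test_fixed_k_partition(self):
        g = nx.complete_graph(6)
        for _, _, d in g.edges(data=True):
            d.update(weight=0.1, correlation=0.9, abs_correlation=0.9)
        part = communities(self._network_from_graph(g), k=2)
        assert part.n_communities == 2

    def test_planted_two_community_recovery(self):
        truth = TrajTruth(seed=0)
        bundle = generate_trajectory(truth)
        part = communities(build_network(bundle))
        planted = truth.community_assignment
        got = np.array([part.assignment[i] for i in range(truth.n_residues)])
        # exact recovery up to label permutation
        assert len(set(zip(got, planted))) == 2
        assert part.n_communities == 2

    def test_empty_network_rejected(self):
        import pandas as pd

        net = DynamicNetwork(nx.Graph(), pd.DataFrame(columns=["node", "chain", "res_id"]), 4.5, 0.75)
        with pytest.raises(InvalidInputError):
            communities(net)

    def test_deterministic(self):
        bundle = generate_trajectory(TrajTruth(seed=7))
        net = build_network(bundle)
        a = communities(net)
        b = communities(net)
        assert a.assignment == b.assignment and a.modularity == b.modularity


class TestInterfaceResidues:
    def _dimer(self, gap):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5 + gap, 0, 0], [3.0 + gap, 0, 0]])
        return _structure(coords, chain=["A", "A", "B", "B"], res_id=[1, 2, 1, 2])

    def test_contact_within_cutoff_included(self):
        pairs = interface_residues(self._dimer(3.9), "A", "B", cutoff=4.0)
        assert (2, 1) in pairs

    def test_contact_beyond_cutoff_excluded(self):
        pairs = interface_residues(self._dimer(4.1), "A", "B", cutoff=4.0)
        assert pairs == []

    def test_distant_chains_empty(self):
        assert interface_residues(self._dimer(100.0), "A", "B") == []

    def test_missing_chain_rejected(self):
        with pytest.raises(InvalidInputError):
            interface_residues(self._dimer(3.0), "A", "C")

    def test_pairs_sorted(self):
        s = self._dimer(3.0)
        pairs = interface_residues(s, "A", "B", cutoff=10.0)
        assert pairs == sorted(pairs)
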