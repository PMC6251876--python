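"""Order parameters, reweighting, grids, path search, and representatives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import bellman_ford

from memfold.constants import K_B
from memfold.fixtures import (
    REDUCED_T,
    make_random_grid,
    make_toy_grid,
    make_two_basin_landscape_ensemble,
)
from memfold.landscape import (
    PerturbationSpec,
    compute_order_params,
    dijkstra_path,
    force_tilt_kT,
    free_energy_grid,
    mbar_weights,
    path_barrier,
    path_profile,
    perturbed_reduced_energy,
    rate_limiting_extension_change,
    sample_set_grid,
    superpose,
)
from memfold.model_io import Conformation


class TestOrderParams:
    def test_native_conformation_is_fully_native(self, hairpin):
        conf, topo = hairpin
        op = compute_order_params(conf, topo)
        assert op.q == 1.0
        assert op.d == pytest.approx(
            np.linalg.norm(conf.ca_xyz[-1] - conf.ca_xyz[0])
        )

    def test_two_bead_chain_geometry(self, hairpin):
        _, topo = hairpin
        ca = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])
        conf = Conformation(np.array([1, 2]), ca, np.full((2, 3), np.nan))
        # build a 2-residue topology on the fly for D/Z only
        from memfold.model_io import SBMParams, build_native_topology

        topo2 = build_native_topology(conf, "GG", [], "CC", SBMParams(s_min=1))
        op = compute_order_params(conf, topo2)
        assert op.d == pytest.approx(50.0)
        assert op.z == pytest.approx(25.0)

    def test_uniform_distance_inflation_destroys_q(self, hairpin):
        conf, topo = hairpin
        # scaling all coordinates stretches every pairwise distance beyond 1 Å
        blown = Conformation(conf.residue_ids, conf.ca_xyz * 1.6, conf.cb_xyz * 1.6)
        op = compute_order_params(blown, topo)
        assert op.q == 0.0

    def test_tm56_variants_restrict_to_last_two_helices(self, hairpin):
        conf, topo = hairpin
        op = compute_order_params(conf, topo)
        rng56 = sorted(topo.tm_helices)[-2][0], sorted(topo.tm_helices)[-1][1]
        idx = topo.helix_residue_indices(*rng56)
        sub = conf.ca_xyz[idx]
        assert op.d_tm56 == pytest.approx(np.linalg.norm(sub[-1] - sub[0]))
        assert op.z_tm56 == pytest.approx(sub[:, 2].mean())


class TestPerturbedReducedEnergy:
    def _frames(self):
        return pd.DataFrame({
            "v_unbiased": [10.0, 12.0],
            "v_boost_region": [-4.0, -5.0],
            "d": [100.0, 120.0],
        })

    def test_identity_perturbation_reproduces_unbiased(self):
        frames = self._frames()
        u = perturbed_reduced_energy(frames, PerturbationSpec(), 373.0)
        np.testing.assert_allclose(
            u, frames["v_unbiased"].to_numpy() / (K_B * 373.0)
        )

    def test_boost_without_contacts_in_window_changes_nothing(self):
        frames = self._frames()
        frames["v_boost_region"] = 0.0
        pert = PerturbationSpec(contact_boost_factor=1.2, boosted_range=(1, 10))
        u = perturbed_reduced_energy(frames, pert, 373.0)
        np.testing.assert_allclose(
            u, frames["v_unbiased"].to_numpy() / (K_B * 373.0)
        )

    def test_pulling_tilt_shifts_by_force_times_distance(self):
        frames = self._frames()
        u0 = perturbed_reduced_energy(frames, PerturbationSpec(), 373.0)
        u1 = perturbed_reduced_energy(
            frames, PerturbationSpec(k_force=0.1), 373.0
        )
        # at D = 100 Å the shift is -10 kcal/mol in reduced units
        assert u1[0] - u0[0] == pytest.approx(-10.0 / (K_B * 373.0), rel=1e-12)

    def test_missing_bookkeeping_column_is_actionable(self):
        frames = self._frames().drop(columns=["v_boost_region"])
        pert = PerturbationSpec(contact_boost_factor=1.2, boosted_range=(1, 10))
        with pytest.raises(ValueError, match="v_boost_region"):
            perturbed_reduced_energy(frames, pert, 373.0)

    def test_boost_scales_window_contacts_by_twenty_percent(self):
        frames = self._frames()
        pert = PerturbationSpec(contact_boost_factor=1.2, boosted_range=(1, 10))
        u = perturbed_reduced_energy(frames, pert, 373.0)
        expected = (10.0 + 0.2 * (-4.0)) / (K_B * 373.0)
        assert u[0] == pytest.approx(expected, rel=1e-12)


class TestFreeEnergyGrid:
    def test_equal_weights_give_equal_bins(self):
        d = np.array([0.5, 2.5])
        z = np.array([0.5, 0.5])
        w = np.array([0.5, 0.5])
        grid = free_energy_grid(d, z, w, d_bin=2.0, z_bin=1.0, d_range=(0, 4), z_range=(0, 1))
        vals = grid.f[grid.occupied]
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_log_weight_ratio_sets_free_energy_gap(self):
        d = np.array([0.5, 2.5])
        z = np.array([0.5, 0.5])
        w = np.array([1.0, np.exp(-1.0)])
        grid = free_energy_grid(d, z, w, d_bin=2.0, z_bin=1.0, d_range=(0, 4), z_range=(0, 1))
        vals = np.sort(grid.f[grid.occupied])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(1.0, rel=1e-12)

    def test_unbiased_single_state_matches_histogram_oracle(self):
        rng = np.random.default_rng(4)
        d = rng.normal(50.0, 5.0, 4000)
        z = rng.normal(0.0, 2.0, 4000)
        w = np.full(4000, 1 / 4000)
        grid = free_energy_grid(d, z, w, d_bin=2.0, z_bin=1.0)
        hist, _, _ = np.histogram2d(d, z, bins=[grid.d_edges, grid.z_edges])
        mask = hist > 0
        f_ref = -np.log(hist[mask] / 4000)
        f_ref -= f_ref.min()
        np.testing.assert_allclose(grid.f[mask], f_ref, atol=1e-10)
        assert np.all(~grid.occupied == ~mask)

    def test_empty_bins_are_masked_not_capped(self):
        d = np.array([0.5, 4.5])
        z = np.array([0.5, 0.5])
        grid = free_energy_grid(d, z, np.array([0.5, 0.5]), d_bin=1.0, z_bin=1.0,
                                d_range=(0, 5), z_range=(0, 1))
        assert np.isinf(grid.f[2, 0])
        assert not grid.occupied[2, 0]


def independent_shortest_cost(grid, start_bin, end_bin):
    """Bellman-Ford on the same lattice/weights via scipy (independent route)."""
    n_d, n_z = grid.f.shape
    idx = {(i, j): k for k, (i, j) in enumerate(
        (i, j) for i in range(n_d) for j in range(n_z) if grid.occupied[i, j]
    )}
    w_node = np.exp(grid.f)
    mat = lil_matrix((len(idx), len(idx)))
    for (i, j), k in idx.items():
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = (i + di, j + dj)
                if nb in idx:
                    mat[k, idx[nb]] = 0.5 * (w_node[i, j] + w_node[nb])
    # both edge directions are stored explicitly above
    dist = bellman_ford(mat.tocsr(), directed=True, indices=idx[start_bin])
    return dist[idx[end_bin]]


def exhaustive_shortest_cost(grid, start_bin, end_bin):
    """Enumerate every simple path on a small grid (brute-force oracle)."""
    n_d, n_z = grid.f.shape
    nodes = [(i, j) for i in range(n_d) for j in range(n_z) if grid.occupied[i, j]]
    w_node = {n: np.exp(grid.f[n]) for n in nodes}
    best = [np.inf]

    def neighbors(n):
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if di == dj == 0:
                continue
            nb = (n[0] + di, n[1] + dj)
            if nb in w_node:
                yield nb

    def walk(node, visited, cost):
        if cost >= best[0]:
            return
        if node == end_bin:
            best[0] = cost
            return
        for nb in neighbors(node):
            if nb not in visited:
                walk(nb, visited | {nb}, cost + 0.5 * (w_node[node] + w_node[nb]))

    walk(start_bin, {start_bin}, 0.0)
    return best[0]


class TestDijkstra:
    def test_uniform_grid_takes_minimal_edge_count(self):
        grid = make_toy_grid((5, 5), base_f=1.0)
        path = dijkstra_path(grid, (0.5, 0.5), (4.5, 4.5))
        assert len(path.nodes) == 5  # diagonal, 4 edges
        assert path.cost == pytest.approx(4 * np.exp(0.0), rel=1e-12)

    def test_wall_with_gap_forces_the_detour(self):
        grid = make_toy_grid((5, 5), wall_col=2, gap_row=4, base_f=1.0)
        path = dijkstra_path(grid, (0.5, 0.5), (4.5, 0.5))
        assert (2, 4) in path.nodes
        assert path.cost == pytest.approx(
            exhaustive_shortest_cost(grid, (0, 0), (4, 0)), rel=1e-12
        )

    def test_degenerate_single_node_path(self):
        grid = make_toy_grid((3, 3))
        path = dijkstra_path(grid, (0.5, 0.5), (0.5, 0.5))
        assert path.nodes == [(0, 0)]
        assert path.cost == 0.0

    def test_unreachable_start_is_an_error(self):
        grid = make_toy_grid((5, 5), wall_col=2)
        with pytest.raises(ValueError, match="unoccupied"):
            dijkstra_path(grid, (2.5, 2.5), (4.5, 4.5))

    def test_disconnected_regions_raise(self):
        grid = make_toy_grid((5, 5), wall_col=2)  # wall with no gap
        with pytest.raises(ValueError, match="no path"):
            dijkstra_path(grid, (0.5, 0.5), (4.5, 4.5))

    @pytest.mark.parametrize("shape", [(3, 3), (3, 4)])
    def test_exhaustive_enumeration_agreement_on_small_grids(self, shape):
        for seed in range(5):
            grid = make_random_grid(shape, seed=seed)
            start, end = (0, 0), (shape[0] - 1, shape[1] - 1)
            path = dijkstra_path(
                grid,
                (grid.d_centers[start[0]], grid.z_centers[start[1]]),
                (grid.d_centers[end[0]], grid.z_centers[end[1]]),
            )
            assert path.cost == pytest.approx(
                exhaustive_shortest_cost(grid, start, end), rel=1e-10
            )

    def test_independent_solver_agreement_on_random_6x6(self):
        for seed in range(30):
            grid = make_random_grid((6, 6), seed=seed)
            path = dijkstra_path(
                grid, (grid.d_centers[0], grid.z_centers[0]),
                (grid.d_centers[-1], grid.z_centers[-1]),
            )
            ref = independent_shortest_cost(grid, (0, 0), (5, 5))
            assert path.cost == pytest.approx(ref, rel=1e-10)


class TestPathProfile:
    def test_monotone_path_has_zero_forward_barrier(self):
        profile = pd.DataFrame({"d": [0, 1, 2], "z": [0, 0, 0], "f_kt": [3.0, 2.0, 1.0]})
        b = path_barrier(profile)
        assert b["barrier_forward"] == 0.0

    def test_constructed_double_well_barrier(self):
        f = np.array([0.0, 2.0, 5.0, 2.0, 1.0])
        profile = pd.DataFrame({"d": np.arange(5), "z": np.zeros(5), "f_kt": f})
        b = path_barrier(profile)
        assert b["barrier_forward"] == pytest.approx(5.0)
        assert b["barrier_reverse"] == pytest.approx(4.0)

    def test_single_point_profile(self):
        profile = pd.DataFrame({"d": [1.0], "z": [0.0], "f_kt": [2.0]})
        b = path_barrier(profile)
        assert b["barrier_forward"] == 0.0


class TestReweightingProperties:
    def test_boost_to_one_and_zero_force_reproduce_unperturbed_grid(self):
        samples = make_two_basin_landscape_ensemble(barrier=3.0, seed=8)
        g0 = sample_set_grid(samples, PerturbationSpec(), REDUCED_T, d_bin=2.0, z_bin=1.0)
        g1 = sample_set_grid(
            samples,
            PerturbationSpec(contact_boost_factor=1.0, k_force=0.0,
                             boosted_range=(1, 10)),
            REDUCED_T, d_bin=2.0, z_bin=1.0,
        )
        np.testing.assert_allclose(
            g0.f[g0.occupied], g1.f[g1.occupied], atol=1e-6
        )

    def test_small_tilt_obeys_linear_response(self):
        """A -k*D tilt shifts basin free-energy gaps by k*dD (in kT)."""
        samples = make_two_basin_landscape_ensemble(barrier=3.0, seed=9)
        d = samples.frames["d"].to_numpy()
        split = 65.0
        k_force = 0.005  # kT/Å in reduced units (k_B*T = 1)
        from scipy.special import logsumexp

        def basin_gap(pert):
            w = mbar_weights(samples, pert, REDUCED_T)
            lw = np.log(np.maximum(w, 1e-300))
            return (-logsumexp(lw[d > split])) - (-logsumexp(lw[d <= split]))

        gap0 = basin_gap(PerturbationSpec())
        gap1 = basin_gap(PerturbationSpec(k_force=k_force * K_B * REDUCED_T))

        w0 = mbar_weights(samples, PerturbationSpec(), REDUCED_T)
        d_ext = np.sum(w0[d > split] * d[d > split]) / np.sum(w0[d > split])
        d_cmp = np.sum(w0[d <= split] * d[d <= split]) / np.sum(w0[d <= split])
        predicted_shift = -k_force * (d_ext - d_cmp)
        assert gap1 - gap0 == pytest.approx(predicted_shift, abs=0.05)

    def test_tilt_monotonically_favors_extension(self):
        samples = make_two_basin_landscape_ensemble(barrier=3.0, seed=10)
        d = samples.frames["d"].to_numpy()
        means = []
        for k_force in (0.0, 0.01, 0.02, 0.04):
            w = mbar_weights(
                samples, PerturbationSpec(k_force=k_force * K_B * REDUCED_T), REDUCED_T
            )
            means.append(float(np.sum(w * d)))
        assert np.all(np.diff(means) > 0)


class TestSuperposition:
    def test_self_superposition_is_exact(self, hairpin):
        conf, _ = hairpin
        _, rmsd = superpose(conf.ca_xyz, conf.ca_xyz)
        assert rmsd < 1e-12

    def test_rotated_copy_recovers_zero_rmsd(self, hairpin):
        conf, _ = hairpin
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [1.0, -0.4, 2.2])
        moved = rot.apply(conf.ca_xyz) + np.array([5.0, 6.0, 7.0])
        _, rmsd = superpose(moved, conf.ca_xyz)
        assert rmsd < 1e-6


@pytest.fixture(scope="module")
def sampled(hairpin, hairpin_model, hairpin_native_beads):
    from memfold.dynamics import BiasSpec, SimulationConfig, langevin_run
    from memfold.landscape import build_sample_set

    bias = BiasSpec(d_center=15.0)
    cfg = SimulationConfig(n_steps=4000, save_every=100, rng_seed=6)
    traj = langevin_run(hairpin_native_beads, hairpin_model, cfg, 373.0, bias)
    return build_sample_set(
        [(bias, 373.0, traj)], equilibration_fraction=0.0, keep_coords=True
    )


class TestRepresentatives:
    def test_lowest_energy_frames_selected_and_sorted(self, sampled, hairpin):
        from memfold.landscape import select_representatives

        _, topo = hairpin
        df = sampled.frames
        box_d = (df["d"].min() - 1, df["d"].max() + 1)
        box_z = (df["z"].min() - 1, df["z"].max() + 1)
        selected, coords = select_representatives(sampled, topo, box_d, box_z, n=3)
        assert len(selected) == 3
        assert coords.shape == (3, topo.n_beads, 3)
        energies = selected["v_unbiased"].to_numpy()
        assert np.all(np.diff(energies) >= 0)
        assert energies[0] == df["v_unbiased"].min()
        # superposed copies stay close to the reference frame
        is_ca = ~topo.bead_is_cb
        for k in (1, 2):
            rmsd = np.sqrt(np.mean(np.sum(
                (coords[k][is_ca] - coords[0][is_ca]) ** 2, axis=1)))
            assert rmsd < 10.0

    def test_empty_region_is_an_error(self, sampled, hairpin):
        from memfold.landscape import select_representatives

        _, topo = hairpin
        with pytest.raises(ValueError, match="no frames"):
            select_representatives(sampled, topo, (900.0, 950.0), (-1.0, 1.0), n=1)


class TestForceBookkeeping:
    def test_five_piconewtons_over_250_angstroms(self):
        assert force_tilt_kT(5.0, 250.0, 300.0) == pytest.approx(30.0, abs=0.5)

    def test_zero_force_zero_tilt(self):
        assert force_tilt_kT(0.0, 123.0, 300.0) == 0.0

    def test_one_kt_calibration_point(self):
        assert force_tilt_kT(1.0, 41.42, 300.0) == pytest.approx(1.0, abs=0.01)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            force_tilt_kT(1.0, 1.0, -5.0)

    def test_transition_distances_add_up(self):
        assert rate_limiting_extension_change(14.8, 35.6) == pytest.approx(50.4)
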