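"""Volume-conductor solver: analytic oracles and physical invariants."""

import numpy as np
import pytest

from ttfplan import (
    SolveSettings,
    VoxelGrid,
    build_phantom,
    combine_channels,
    compute_field,
    field_magnitude,
    solve_channel,
    total_current,
)
from ttfplan.phantom import Tissue, mini_spec
from ttfplan.pipeline import solve_configuration
from ttfplan.solver import SolverError, _face_conductance


def _voltage_settings(v=1.0):
    return SolveSettings(target_current=None, applied_voltage=v)


class TestAnalyticSlabs:
    def test_parallel_plate_uniform_field(self, fixtures):
        """Homogeneous cuboid with ΔV=1 V across L=0.1 m gives |E|=10 V/m."""
        slab = fixtures["slab"]
        sol = solve_channel(
            slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
            _voltage_settings(),
        )
        L = 10 * 10.0e-3
        mag = field_magnitude(sol)
        assert np.max(np.abs(mag - 1.0 / L)) / (1.0 / L) < 1e-6

    def test_parallel_plate_ohms_law_current(self, fixtures):
        slab = fixtures["slab"]
        sol = solve_channel(
            slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
            _voltage_settings(),
        )
        area = 8 * 8 * (10.0e-3) ** 2
        expected = 0.3 * area * 1.0 / (10 * 10.0e-3)
        assert sol.current == pytest.approx(expected, rel=1e-6)

    def test_two_layer_series_field_ratio_and_j_continuity(self, fixtures):
        """σ1 = 2 σ2 in series: |E2|/|E1| = 2 and normal J continuous."""
        tl = fixtures["two_layer"]
        sol = solve_channel(
            tl["sigma"], tl["grid"], tl["anode"], tl["cathode"], _voltage_settings()
        )
        e1 = abs(sol.E[2, 4, 4, 0])  # interior of the σ=0.4 layer
        e2 = abs(sol.E[8, 4, 4, 0])  # interior of the σ=0.2 layer
        assert e2 / e1 == pytest.approx(2.0, rel=1e-6)
        j1 = abs(sol.J[2, 4, 4, 0])
        j2 = abs(sol.J[8, 4, 4, 0])
        assert j1 == pytest.approx(j2, rel=1e-6)

    def test_current_normalization_linearity(self, fixtures):
        """Doubling the target current exactly doubles φ, E and J."""
        slab = fixtures["slab"]
        a = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                          SolveSettings(target_current=0.5))
        b = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                          SolveSettings(target_current=1.0))
        assert np.allclose(b.phi, 2.0 * a.phi)
        assert np.allclose(b.E, 2.0 * a.E)
        assert np.allclose(b.J, 2.0 * a.J)
        assert b.applied_voltage == pytest.approx(2.0 * a.applied_voltage)

    def test_anode_cathode_currents_balance(self, fixtures):
        slab = fixtures["slab"]
        sol = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                            SolveSettings(target_current=0.9))
        assert abs(sol.anode_current + sol.cathode_current) / sol.anode_current < 1e-4
        assert sol.current == pytest.approx(0.9)

    def test_unenergized_patch_carries_no_net_current(self, fixtures):
        slab = fixtures["slab"]
        sol = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                            _voltage_settings())
        side = np.array([(5, 0, k) for k in range(8)])  # passive side wall strip
        i_side = total_current(slab["sigma"], sol.phi, slab["grid"], side)
        assert abs(i_side) < 1e-10 * sol.current + 1e-12


class TestComputeField:
    def test_linear_potential_gives_constant_field(self):
        grid = VoxelGrid((9, 5, 5), (10.0, 10.0, 10.0), (0.0, 0.0, 0.0))
        xs = grid.axes()[0] * 1.0e-3
        phi = np.broadcast_to(-5.0 * xs[:, None, None], grid.shape).copy()
        E = compute_field(phi, grid)
        assert np.allclose(E[..., 0], 5.0)
        assert np.allclose(E[..., 1:], 0.0)

    def test_constant_potential_gives_zero_field(self):
        grid = VoxelGrid((6, 6, 6), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        assert np.all(compute_field(np.full(grid.shape, 3.0), grid) == 0.0)

    def test_matches_brute_force_stencil(self, fixtures):
        """Vectorized gradient equals a literal loop over the stencil rules."""
        grid = fixtures["random_phi"]["grid"]
        phi = fixtures["random_phi"]["phi"]
        E = compute_field(phi, grid)
        h = grid.spacing[0] * 1.0e-3
        n = grid.shape[0]
        expected = np.zeros(E.shape)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    for axis, (di, dj, dk) in enumerate(
                        ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                    ):
                        idx = (i, j, k)
                        up = (i + di, j + dj, k + dk)
                        dn = (i - di, j - dj, k - dk)
                        has_up = up[axis] < n
                        has_dn = dn[axis] >= 0
                        if has_up and has_dn:
                            g = (phi[up] - phi[dn]) / (2 * h)
                        elif has_up:
                            g = (phi[up] - phi[idx]) / h
                        else:
                            g = (phi[idx] - phi[dn]) / h
                        expected[idx + (axis,)] = -g
        assert np.allclose(E, expected)


class TestCombineChannels:
    def test_average_of_identical_solutions_is_identity(self, fixtures):
        slab = fixtures["slab"]
        sol = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                            _voltage_settings())
        avg = combine_channels(sol, sol, "average")
        assert np.allclose(avg, field_magnitude(sol))

    def test_max_dominates_average(self, fixtures):
        slab = fixtures["slab"]
        a = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                          SolveSettings(target_current=0.5))
        b = solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["cathode"],
                          SolveSettings(target_current=1.0))
        assert np.all(
            combine_channels(a, b, "max") >= combine_channels(a, b, "average") - 1e-15
        )

    def test_orthogonal_uniform_fields_average(self):
        """Uniform 3 and 4 V/m fields average to 3.5 V/m everywhere."""
        from ttfplan.solver import ChannelSolution

        grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

        def uniform(mag, axis):
            E = np.zeros(grid.shape + (3,))
            E[..., axis] = mag
            return ChannelSolution(
                channel="C", grid=grid, phi=np.zeros(grid.shape), E=E, J=E,
                applied_voltage=1.0, current=1.0, anode_current=1.0,
                cathode_current=-1.0, iterations=0, residual=0.0,
            )

        avg = combine_channels(uniform(3.0, 0), uniform(4.0, 1), "average")
        assert np.allclose(avg, 3.5)

    def test_grid_mismatch_rejected(self, fixtures):
        from ttfplan.solver import ChannelSolution

        g1 = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        g2 = VoxelGrid((5, 4, 4), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

        def dummy(grid):
            z = np.zeros(grid.shape)
            return ChannelSolution("C", grid, z, np.zeros(grid.shape + (3,)),
                                   np.zeros(grid.shape + (3,)), 1.0, 1.0, 1.0, -1.0, 0, 0.0)

        with pytest.raises(ValueError, match="grid"):
            combine_channels(dummy(g1), dummy(g2))


class TestHeadSolveInvariants:
    def test_maximum_principle(self, full_run):
        sol_ap, sol_lr = full_run["configs"]["SUPRATENTORIAL"]["solutions"]
        for sol in (sol_ap, sol_lr):
            v = sol.applied_voltage / 2.0
            assert sol.phi.min() >= -v - 1e-9
            assert sol.phi.max() <= v + 1e-9

    def test_field_zero_in_air(self, full_run):
        volume = full_run["volume"]
        model = full_run["configs"]["SUPRATENTORIAL"]["model"]
        air = model.volume.labels == Tissue.AIR
        for sol in full_run["configs"]["SUPRATENTORIAL"]["solutions"]:
            assert np.all(field_magnitude(sol)[air] == 0.0)
        assert volume.grid.same_geometry(model.volume.grid)

    def test_j_equals_sigma_e_voxelwise(self, full_run):
        from ttfplan.phantom import assign_conductivity

        model = full_run["configs"]["SUPRATENTORIAL"]["model"]
        sigma = assign_conductivity(model.volume)
        sol = full_run["configs"]["SUPRATENTORIAL"]["solutions"][0]
        assert np.allclose(sol.J, sigma[..., None] * sol.E)

    def test_current_balance_on_head(self, full_run):
        for sol in full_run["configs"]["SUPRATENTORIAL"]["solutions"]:
            assert abs(sol.anode_current + sol.cathode_current) / sol.anode_current < 1e-4

    def test_discrete_interior_conservation(self, full_run):
        """Net J-flux out of every non-electrode domain voxel ≈ 0."""
        from ttfplan.phantom import assign_conductivity

        model = full_run["configs"]["SUPRATENTORIAL"]["model"]
        sol = full_run["configs"]["SUPRATENTORIAL"]["solutions"][0]
        sigma = assign_conductivity(model.volume)
        grid = sol.grid
        net = np.zeros(grid.shape)
        for axis in range(3):
            g = _face_conductance(sigma, grid, axis)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            flux = g * (sol.phi[lo] - sol.phi[hi])  # current from lo cell to hi cell
            net[lo] += flux
            net[hi] -= flux
        interior = (sigma > 0) & (model.volume.labels != Tissue.ELECTRODE)
        assert np.abs(net[interior]).max() / sol.current < 1e-6

    def test_midsagittal_mirror_symmetry(self, full_run):
        """Symmetric phantom + symmetric montage: |E| mirrors about x = 0."""
        e_mag = full_run["configs"]["SUPRATENTORIAL"]["e_mag"]
        flipped = e_mag[::-1, :, :]
        scale = e_mag.max()
        assert np.abs(e_mag - flipped).max() / scale < 1e-6

    def test_mirrored_layouts_give_mirrored_fields(self, full_run):
        left = full_run["configs"]["PA_HORIZONTAL_LEFT"]["e_mag"]
        right = full_run["configs"]["PA_HORIZONTAL_RIGHT"]["e_mag"]
        assert np.abs(left - right[::-1, :, :]).max() / right.max() < 1e-6


class TestSolverErrors:
    def test_disconnected_electrodes_rejected(self):
        grid = VoxelGrid((7, 3, 3), (10.0, 10.0, 10.0), (0.0, 0.0, 0.0))
        sigma = np.full(grid.shape, 0.3)
        sigma[3] = 0.0  # air gap splits the domain
        anode = np.array([(0, j, k) for j in range(3) for k in range(3)])
        cathode = np.array([(6, j, k) for j in range(3) for k in range(3)])
        with pytest.raises(SolverError):
            solve_channel(sigma, grid, anode, cathode)

    def test_empty_patch_rejected(self, fixtures):
        slab = fixtures["slab"]
        with pytest.raises(ValueError, match="non-empty"):
            solve_channel(slab["sigma"], slab["grid"], np.empty((0, 3)), slab["cathode"])
        with pytest.raises(ValueError, match="empty"):
            total_current(slab["sigma"], np.zeros(slab["grid"].shape), slab["grid"],
                          np.empty((0, 3)))

    def test_overlapping_electrode_patches_rejected(self, fixtures):
        slab = fixtures["slab"]
        with pytest.raises(ValueError, match="overlap"):
            solve_channel(slab["sigma"], slab["grid"], slab["anode"], slab["anode"])


class TestGridConsistency:
    def test_field_distribution_stable_under_refinement(self):
        """The GTV/cerebellum mean-|E| ratio is grid-stable from 4 to 2 mm.

        The absolute intracranial field scale shifts with resolution
        (the staircased low-conductivity skull shell dominates the
        transcranial impedance), but the spatial distribution of the
        field — summarized by the GTV-to-cerebellum mean ratio — must
        not: the package claims comparative, not absolute, quantities.
        """
        ratios = []
        for spacing in (4.0, 2.0):
            vol, masks = build_phantom(mini_spec().with_spacing(spacing))
            _, _, sol_ap, sol_lr = solve_configuration(vol, "SUPRATENTORIAL")
            e = combine_channels(sol_ap, sol_lr, "average", "E")
            ratios.append(
                e[masks["GTV"].member].mean() / e[masks["CEREBELLUM"].member].mean()
            )
        assert abs(ratios[1] - ratios[0]) / ratios[1] < 0.05
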