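"""WHAM estimator, activation free energies, path tracing, profiles."""
import numpy as np
import pytest

import pmfkit as pk
from pmfkit.sampling import UmbrellaWindow, WindowSet
from pmfkit.wham import (
    WHAM,
    ConvergenceError,
    DisconnectedHistogramError,
    FreeEnergyProfile,
    PMFGrid,
    StationaryPoint,
)


def flat_window(n=10_000):
    """Uniform, unbiased samples on [0, 1]."""
    samples = (np.arange(n) + 0.5) / n
    return WindowSet([UmbrellaWindow(center=0.5, k=0.0, temperature=310.0,
                                     samples=samples)])


class TestWham1D:
    def test_flat_density_gives_zero_pmf(self):
        # bin centers aligned with the uniform sample lattice
        centers = np.arange(0.05, 0.9999, 0.1)
        pmf = pk.wham(flat_window(), bins=centers)
        assert pmf.ndim == 1
        assert np.allclose(pmf.values[pmf.covered], 0.0, atol=1e-9)

    def test_default_tolerance(self):
        assert WHAM().tolerance == 1e-3

    def test_double_well_barrier_vs_boltzmann_oracle(self, dw_windows, dw_pmf):
        # 31 stiff-spring windows recover the 5 kcal/mol barrier
        i0 = np.argmin(np.abs(dw_pmf.axes[0]))
        ref = pk.boltzmann_pmf(pk.make_double_well(5, 1), dw_pmf.axes[0], 310.0)
        barrier = dw_pmf.values[i0] - np.nanmin(dw_pmf.values)
        ref_barrier = ref[i0] - ref.min()
        assert barrier == pytest.approx(ref_barrier, abs=0.3)

    def test_min_referenced(self, dw_pmf):
        assert np.nanmin(dw_pmf.values[dw_pmf.covered]) == 0.0

    def test_convergence_metadata(self, dw_pmf):
        assert dw_pmf.final_change < 1e-3
        assert dw_pmf.n_iter >= 1

    def test_window_reordering_invariance(self, dw_windows):
        reordered = WindowSet(list(reversed(dw_windows.windows)))
        a = pk.wham(dw_windows, bins=97)
        b = pk.wham(reordered, bins=97)
        assert np.allclose(a.values[a.covered], b.values[b.covered], atol=1e-6)

    def test_disconnected_windows_raise(self):
        rng = np.random.default_rng(0)
        w1 = UmbrellaWindow(center=0.0, k=500.0, temperature=310.0,
                            samples=rng.normal(0.0, 0.03, 2000))
        w2 = UmbrellaWindow(center=5.0, k=500.0, temperature=310.0,
                            samples=rng.normal(5.0, 0.03, 2000))
        with pytest.raises(DisconnectedHistogramError, match="disconnected"):
            pk.wham(WindowSet([w1, w2]), bins=100)

    def test_nonconvergence_carries_last_profile(self, dw_windows):
        with pytest.raises(ConvergenceError) as err:
            pk.wham(dw_windows, bins=97, tolerance=0.0, max_iter=3)
        assert isinstance(err.value.pmf, PMFGrid)

    def test_halving_samples_degrades_accuracy_on_average(self, double_well):
        # RMS deviation from the Boltzmann reference grows when each window
        # keeps only half its samples (averaged over 10 seeds)
        grid = pk.grid_scan(double_well, [(-1.2, 1.2, 0.12)])
        plan = pk.build_windows(grid, k=150.0)
        errs_full, errs_half = [], []
        for seed in range(10):
            ws = pk.sample_windows(double_well, plan, n_samples=2000,
                                   n_equilibration=400, seed=seed)
            half = WindowSet([
                UmbrellaWindow(center=w.center, k=w.k, temperature=w.temperature,
                               samples=w.samples[:1000])
                for w in ws
            ])
            for windows, sink in ((ws, errs_full), (half, errs_half)):
                pmf = pk.wham(windows, bins=60)
                ref = pk.boltzmann_pmf(double_well, pmf.axes[0], 310.0)
                cov = pmf.covered
                resid = (pmf.values - ref)[cov]
                resid -= resid.mean()
                sink.append(np.sqrt(np.mean(resid**2)))
        assert np.mean(errs_half) > np.mean(errs_full)


class TestWham2D:
    def test_separability(self, sep2d_pmf):
        # W(x, y) − Wx(x) − Wy(y) is constant on a separable surface;
        # compared over adequately sampled bins (sparse edge bins carry
        # order-1 statistical noise in W and are excluded)
        cov = sep2d_pmf.counts >= 1000
        wx = pk.boltzmann_pmf(pk.make_double_well(5, 1), sep2d_pmf.axes[0], 310.0)
        wy = pk.boltzmann_pmf(pk.make_harmonic(10.0), sep2d_pmf.axes[1], 310.0)
        resid = sep2d_pmf.values - wx[:, None] - wy[None, :]
        vals = resid[cov] - resid[cov].mean()
        assert vals.max() - vals.min() < 0.6  # residuals within ±0.3 band
        assert vals.std() < 0.15

    def test_flat_single_window_constant(self):
        n = 200
        g = np.stack(np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n)),
                     axis=-1).reshape(-1, 2)
        ws = WindowSet([UmbrellaWindow(center=[0.5, 0.5], k=[0.0, 0.0],
                                       temperature=310.0, samples=g)])
        pmf = pk.wham2d(ws, bins_x=10, bins_y=10)
        assert np.allclose(pmf.values[pmf.covered], 0.0, atol=1e-9)

    def test_traced_path_barrier(self, sep2d_pmf):
        xs, ys = sep2d_pmf.axes
        start = (int(np.argmin(np.abs(xs + 1))), int(np.argmin(np.abs(ys))))
        end = (int(np.argmin(np.abs(xs - 1))), int(np.argmin(np.abs(ys))))
        path, profile = pk.trace_path(sep2d_pmf, start, end)
        assert profile.max() == pytest.approx(5.0, abs=0.3)
        # the route hugs the y-minimum line
        j0 = np.argmin(np.abs(ys))
        j_path = np.array([j for _, j in path])
        assert np.all(np.abs(j_path - j0) <= 1)

    def test_coupled_saddle_near_origin(self):
        # double well along x, harmonic restoring term in y, bilinear
        # coupling: a single channel whose saddle sits at the origin by
        # the (x,y) → (−x,−y) symmetry of the surface
        surf = pk.make_coupled_2d(pk.make_double_well(5, 1),
                                  pk.make_harmonic(10.0), c=2.0)
        grid = pk.grid_scan(surf, [(-1.4, 1.4, 0.28), (-0.9, 0.9, 0.3)])
        plan = pk.build_windows(grid, k=40.0)
        ws = pk.sample_windows(surf, plan, n_samples=3000, n_equilibration=600,
                               seed=21)
        pmf = pk.wham2d(ws)
        xs, ys = pmf.axes
        # minima sit near (±1, ∓c/κ)
        start = (int(np.argmin(np.abs(xs + 1))), int(np.argmin(np.abs(ys - 0.2))))
        end = (int(np.argmin(np.abs(xs - 1))), int(np.argmin(np.abs(ys + 0.2))))
        path, profile = pk.trace_path(pmf, start, end)
        i, j = path[int(np.argmax(profile))]
        wx = xs[1] - xs[0]
        wy = ys[1] - ys[0]
        assert abs(xs[i]) <= wx + 1e-9
        assert abs(ys[j]) <= wy + 1e-9


class TestTracePathContracts:
    @pytest.fixture
    def flat_grid(self):
        axes = (np.linspace(0, 1, 11), np.linspace(0, 1, 11))
        values = np.zeros((11, 11))
        counts = np.ones((11, 11), dtype=int)
        return PMFGrid(axes=axes, values=values, counts=counts, temperature=310.0)

    def test_start_equals_end(self, flat_grid):
        path, profile = pk.trace_path(flat_grid, (3, 3), (3, 3))
        assert path == [(3, 3)]
        assert profile.shape == (1,)
        assert profile[0] == 0.0

    def test_deterministic_tie_break(self, flat_grid):
        p1, _ = pk.trace_path(flat_grid, (0, 5), (10, 5))
        p2, _ = pk.trace_path(flat_grid, (0, 5), (10, 5))
        assert p1 == p2

    def test_uncovered_region_blocks_route(self):
        axes = (np.linspace(0, 1, 11), np.linspace(0, 1, 11))
        values = np.zeros((11, 11))
        counts = np.ones((11, 11), dtype=int)
        counts[5, :] = 0  # impassable wall
        values[5, :] = np.nan
        grid = PMFGrid(axes=axes, values=values, counts=counts, temperature=310.0)
        with pytest.raises(DisconnectedHistogramError):
            pk.trace_path(grid, (0, 5), (10, 5))


class TestActivationFreeEnergy:
    def make_1d(self, values):
        values = np.asarray(values, dtype=float)
        axes = (np.linspace(0, 1, values.size),)
        return PMFGrid(axes=axes, values=values - values.min(),
                       counts=np.ones(values.size, dtype=int), temperature=310.0)

    def test_flat_grid_zero(self):
        grid = self.make_1d(np.zeros(21))
        assert pk.activation_free_energy(grid, (0.0, 0.2), (0.4, 0.6)) == 0.0

    def test_monotone_ramp_end_minus_start(self):
        grid = self.make_1d(np.linspace(0.0, 3.0, 31))
        dg = pk.activation_free_energy(grid, (0.0, 0.05), (0.95, 1.0))
        assert dg == pytest.approx(3.0)

    def test_double_well_recovery(self, dw_pmf):
        dg = pk.activation_free_energy(dw_pmf, (-1.1, -0.9), (-0.1, 0.1))
        assert dg == pytest.approx(5.0, abs=0.3)

    def test_uncovered_region_raises(self):
        grid = self.make_1d(np.zeros(11))
        with pytest.raises(ValueError):
            pk.activation_free_energy(grid, (5.0, 6.0), (0.4, 0.6))


# Stationary states of the covalent-inhibition profile with the relative
# free energies reported for homobelactosin C: the rate-limiting
# nucleophilic-attack barrier (TS1, 24.9), the near-isoenergetic
# ring-opened intermediate (E-I2, 1.9), the double-proton-transfer barrier
# (19.1 above E-I2, so TS3 sits at 21.0) and the product complex 15.6
# below the non-covalent state.
HBELC_SEGMENTS = [
    [("E•I", 0.0), ("TS1", 24.9), ("E-I2", 1.9)],
    [("E-I2", 1.9), ("TS3", 21.0), ("E-PC", -15.6)],
]


class TestProfiles:
    def test_assemble_preserves_ordering(self):
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        assert profile.labels == ["E•I", "TS1", "E-I2", "TS3", "E-PC"]
        assert profile["E•I"].value == 0.0
        assert profile["E-PC"].value == pytest.approx(-15.6)

    def test_single_segment_identity(self):
        seg = [("A", 0.0), ("TS", 2.0), ("B", 1.0)]
        profile = pk.assemble_profile([seg])
        assert [(p.label, p.value) for p in profile.points] == seg

    def test_junction_value_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            pk.assemble_profile([
                [("A", 0.0), ("TS", 2.0), ("B", 1.0)],
                [("B", 1.0 + 1e-6), ("TS2", 3.0), ("C", 0.5)],
            ])

    def test_junction_label_mismatch_raises(self):
        with pytest.raises(ValueError, match="junction"):
            pk.assemble_profile([
                [("A", 0.0), ("TS", 2.0), ("B", 1.0)],
                [("X", 1.0), ("TS2", 3.0), ("C", 0.5)],
            ])

    def test_forward_barrier(self):
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        assert pk.barrier_query(profile, "E•I", "E-I2") == pytest.approx(24.9)

    def test_third_step_barrier(self):
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        assert pk.barrier_query(profile, "E-I2", "E-PC") == pytest.approx(19.1)

    def test_reverse_barrier_from_product(self):
        # E-PC → E•I must climb back over the highest saddle: 24.9 − (−15.6)
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        assert pk.barrier_query(profile, "E-PC", "E•I") == pytest.approx(40.5)

    def test_self_barrier_zero(self):
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        assert pk.barrier_query(profile, "E-I2", "E-I2") == 0.0

    def test_unknown_state_raises(self):
        profile = pk.assemble_profile(HBELC_SEGMENTS)
        with pytest.raises(KeyError):
            pk.barrier_query(profile, "E•I", "nope")

    def test_alternation_enforced(self):
        with pytest.raises(ValueError, match="alternate"):
            FreeEnergyProfile(
                points=[StationaryPoint("A", 0.0, "saddle"),
                        StationaryPoint("B", 1.0, "minimum")],
                reference="A",
            )

    def test_saddle_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="below"):
            FreeEnergyProfile(
                points=[StationaryPoint("A", 0.0, "minimum"),
                        StationaryPoint("TS", -1.0, "saddle"),
                        StationaryPoint("B", -2.0, "minimum")],
                reference="A",
            )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pk.assemble_profile([[("A", 0.0), ("TS", 2.0), ("A", 1.0)]])
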