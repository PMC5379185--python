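"""Well-tempered metadynamics engine: sampler, estimators, basin analysis."""

import math

import numpy as np
import pytest

from switchscape.core import KT_300
from switchscape.errors import BiasError, SpecError, SurfaceError
from switchscape.metad import (
    BiasPotential,
    DihedralChain,
    DoubleWell1D,
    FreeEnergySurface,
    Harmonic1D,
    HillRecord,
    IdentityCV,
    MuellerLike2D,
    SquareCV,
    SSimilarityCV,
    delta_g_convergence,
    fes_from_bias,
    find_basins_barriers,
    integrated_delta_g,
    langevin_sample,
    reweight,
    wt_metad,
)


class TestLangevin:
    def test_harmonic_equipartition(self):
        """Sample variance in a harmonic well = kT/k within 3 SE, and
        <U> = kT/2 per mode."""
        k, kT = 5.0, KT_300
        pot = Harmonic1D(k=k)
        traj = langevin_sample(pot, kT=kT, dt=0.005, n_steps=200_000,
                               friction=1.0, seed=4, record_stride=5)
        x = traj.states[2000:, 0]  # drop equilibration
        var = x.var()
        # effective sample size from the OU autocorrelation time
        tau_steps = 1.0 / (k * 0.005)
        n_eff = len(x) * 5 / (2 * tau_steps)
        se = var * math.sqrt(2.0 / n_eff)
        assert abs(var - kT / k) < 3 * se
        mean_u = np.mean(0.5 * k * x ** 2)
        assert abs(mean_u - 0.5 * kT) < 3 * se * k

    def test_zero_temperature_stays_at_minimum(self):
        pot = Harmonic1D(k=2.0, x0=1.5)
        traj = langevin_sample(pot, kT=0.0, dt=0.01, n_steps=500, seed=0,
                               x0=1.5)
        np.testing.assert_allclose(traj.states[:, 0], 1.5, atol=1e-12)

    def test_seed_determinism(self):
        pot = DoubleWell1D()
        t1 = langevin_sample(pot, kT=KT_300, dt=0.002, n_steps=2000, seed=9,
                             x0=-1.0)
        t2 = langevin_sample(pot, kT=KT_300, dt=0.002, n_steps=2000, seed=9,
                             x0=-1.0)
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_seed_is_mandatory(self):
        with pytest.raises(SpecError):
            langevin_sample(DoubleWell1D(), n_steps=10)


class TestWtMetad:
    def test_infinite_bias_factor_keeps_heights_constant(self):
        pot = DoubleWell1D()
        _, bias = wt_metad(pot, [IdentityCV(pot.domain)], W=0.1, widths=0.1,
                           stride_ps=0.2, bias_factor=math.inf, kT=KT_300,
                           dt=0.002, n_steps=20_000, seed=1, x0=-1.0)
        heights = np.array([h.height for h in bias.hills])
        np.testing.assert_allclose(heights, 0.1, atol=1e-15)

    def test_heights_bounded_and_tempered(self, double_well_run):
        _, _, bias = double_well_run
        _, centers, _, heights = bias.arrays()
        assert np.all(heights > 0)
        assert np.all(heights <= bias.initial_height + 1e-15)
        # well-tempered property: heights on repeated visits to the same
        # narrow CV bin never increase beyond the within-bin variation of
        # the accumulated bias (0.01-wide bins, tolerance ~W * sigma_bin)
        bins = np.digitize(centers[:, 0], np.linspace(-2, 2, 401))
        for b in np.unique(bins):
            h = heights[bins == b]
            assert np.all(np.diff(h) <= 2e-3)

    def test_bad_stride_raises(self):
        with pytest.raises(SpecError):
            wt_metad(DoubleWell1D(), [IdentityCV()], stride_ps=0.003,
                     dt=0.002, n_steps=10, seed=0)

    def test_bad_bias_factor_raises(self):
        with pytest.raises(BiasError):
            wt_metad(DoubleWell1D(), [IdentityCV()], bias_factor=0.5,
                     stride_ps=0.2, dt=0.002, n_steps=10, seed=0)

    def test_hill_deposition_rate_decays_like_inverse_time(self):
        """Well-tempered asymptotics: hill heights at a revisited basin
        decay ~ 1/t, i.e. the deposited bias grows ~ log t."""
        pot = DoubleWell1D(barrier=1.5, delta_g=0.0)
        _, bias = wt_metad(pot, [IdentityCV(pot.domain)], W=0.1, widths=0.1,
                           stride_ps=0.25, bias_factor=5.0, kT=KT_300,
                           dt=0.002, n_steps=800_000, seed=13, x0=-1.0)
        times, centers, _, heights = bias.arrays()
        # late-time window over basin visits (the 1/t law is asymptotic)
        keep = (times > times[-1] * 0.4) & (np.abs(np.abs(centers[:, 0]) - 1.0)
                                            < 0.4)
        slope = np.polyfit(np.log(times[keep]), np.log(heights[keep]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)


class TestEstimators:
    def test_single_hill_surface(self):
        hill = HillRecord(1.0, (0.5,), (0.2,), 0.08)
        bias = BiasPotential([hill], bias_factor=10.0, temperature=300.0,
                             initial_height=0.1)
        edges = [np.linspace(-1, 2, 121)]
        fes = fes_from_bias(bias, edges)
        centers = fes.centers()[0]
        live = ~fes.mask
        # minimum at the hill center, min-shifted to 0
        assert fes.values[live].min() == 0.0
        assert abs(centers[np.argmin(np.where(live, fes.values, np.inf))]
                   - 0.5) < 0.02
        # inverted scaled Gaussian shape on the unmasked region
        expected = (10.0 / 9.0) * 0.08 * (
            1.0 - np.exp(-0.5 * ((centers - 0.5) / 0.2) ** 2))
        np.testing.assert_allclose(fes.values[live],
                                   (expected - expected[live].min())[live],
                                   atol=1e-10)

    def test_empty_bias_raises(self):
        with pytest.raises(BiasError):
            fes_from_bias(BiasPotential([], 10.0, 300.0, 0.1),
                          [np.linspace(-1, 1, 11)])

    def test_double_well_argmin_matches_analytic(self, double_well_run,
                                                 fes_grid):
        pot, _, bias = double_well_run
        fes = fes_from_bias(bias, fes_grid)
        centers = fes.centers()[0]
        left, right = pot.minima()
        vals = np.where(fes.mask, np.inf, fes.values)
        bin_w = centers[1] - centers[0]
        assert abs(centers[np.argmin(vals)] - left) <= 2 * bin_w

    def test_estimators_recover_delta_g_and_agree(self, double_well_run,
                                                  fes_grid):
        pot, traj, bias = double_well_run
        fes_b = fes_from_bias(bias, fes_grid)
        fes_r = reweight(traj, bias, fes_grid, kT=KT_300)
        dg_true = pot.free_energy_difference(KT_300)
        dg_b = integrated_delta_g(fes_b, KT_300)
        dg_r = integrated_delta_g(fes_r, KT_300)
        assert dg_b == pytest.approx(dg_true, abs=0.3)
        assert dg_r == pytest.approx(dg_true, abs=0.3)
        assert dg_b == pytest.approx(dg_r, abs=0.2)

    def test_run_is_converged(self, double_well_run, fes_grid):
        _, _, bias = double_well_run
        early, late = delta_g_convergence(bias, fes_grid, KT_300,
                                          fractions=(0.8, 1.0))
        assert abs(late - early) < 0.15

    def test_null_bias_reduces_to_histogram(self):
        pot = Harmonic1D(k=3.0)
        traj = langevin_sample(pot, kT=KT_300, dt=0.005, n_steps=50_000,
                               seed=21, record_stride=5)
        traj.cvs = traj.states.copy()
        edges = [np.linspace(-1.2, 1.2, 41)]
        fes = reweight(traj, None, edges, kT=KT_300)
        hist, _ = np.histogram(traj.states[:, 0], bins=edges[0])
        ref = -KT_300 * np.log(np.where(hist > 0, hist, 1))
        ref -= ref[hist > 0].min()
        np.testing.assert_allclose(fes.values[~fes.mask], ref[hist > 0],
                                   atol=1e-9)
        assert np.array_equal(fes.mask, hist == 0)

    def test_reweight_onto_unbiased_observable(self):
        """Biasing s = x^2 and reweighting onto x itself reproduces the
        unbiased distribution (KS distance < 0.05)."""
        pot = DoubleWell1D(barrier=1.2, delta_g=0.0)
        traj_b, bias = wt_metad(pot, [SquareCV((0.0, 4.0))], W=0.05,
                                widths=0.1, stride_ps=0.5, bias_factor=8.0,
                                kT=KT_300, dt=0.002, n_steps=400_000, seed=3,
                                x0=-1.0, record_stride=10)
        traj_u = langevin_sample(pot, kT=KT_300, dt=0.002, n_steps=400_000,
                                 seed=4, x0=-1.0, record_stride=10)
        edges = [np.linspace(0.0, 3.0, 61)]
        x_edges = [np.linspace(-1.8, 1.8, 73)]
        fes = reweight(traj_b, bias, edges, kT=KT_300,
                       observable=traj_b.states[:, 0],
                       observable_edges=x_edges)
        p_rw = np.where(fes.mask, 0.0, np.exp(-fes.values / KT_300))
        p_rw /= p_rw.sum()
        hist_u, _ = np.histogram(traj_u.states[:, 0], bins=x_edges[0])
        p_u = hist_u / hist_u.sum()
        ks = np.max(np.abs(np.cumsum(p_rw) - np.cumsum(p_u)))
        assert ks < 0.05


class TestBasins:
    def _analytic_fes(self, pot, n=161, lo=-2.0, hi=2.0):
        edges = np.linspace(lo, hi, n)
        centers = 0.5 * (edges[1:] + edges[:-1])
        vals = pot.fes_exact(centers)
        return FreeEnergySurface([edges], vals, np.zeros(len(centers), bool))

    def test_symmetric_double_well(self):
        pot = DoubleWell1D(barrier=3.0, delta_g=0.0)
        fes = self._analytic_fes(pot)
        basins, barriers, dg = find_basins_barriers(fes, min_depth=0.5)
        assert len(basins) == 2
        bin_w = 4.0 / 160
        assert barriers[0, 1] == pytest.approx(3.0, abs=0.1)
        assert dg[0, 1] == pytest.approx(0.0, abs=0.1)
        assert {b[0] for b in basins} == {"A", "B"}

    def test_tilted_well_delta_g(self):
        """A 0.7 kcal/mol tilt is recovered as the basin dG within the
        bin resolution."""
        pot = DoubleWell1D(barrier=3.0, delta_g=0.7)
        fes = self._analytic_fes(pot, n=201)
        basins, barriers, dg = find_basins_barriers(fes, min_depth=0.3)
        assert len(basins) == 2
        # A = global minimum (left), B the higher basin
        assert dg[0, 1] == pytest.approx(0.7, abs=0.05)
        assert basins[0][2] == 0.0

    def test_min_depth_filters_shallow_minima(self):
        edges = np.linspace(0, 10, 101)
        centers = 0.5 * (edges[1:] + edges[:-1])
        vals = np.cos(centers * 2.5) * 0.3 + 0.002 * (centers - 5) ** 2 + 0.3
        deep = 4.0 * np.exp(-((centers - 5.0) / 0.4) ** 2)
        fes = FreeEnergySurface([edges], vals - deep,
                                np.zeros(len(centers), bool))
        basins, _, _ = find_basins_barriers(fes, min_depth=1.0)
        assert len(basins) == 1

    def test_flood_fill_matches_exhaustive_minimax_oracle(self):
        """On random 20x20 grids the flood-fill saddle equals the
        exhaustive minimax path level (threshold + connectivity oracle)."""
        rng = np.random.default_rng(17)
        for trial in range(5):
            vals = rng.normal(size=(20, 20)).cumsum(axis=0)
            vals = (vals - vals.min()) / (vals.max() - vals.min()) * 5.0
            # carve two unambiguous minima
            vals[3, 3] = -1.0
            vals[16, 16] = -0.5
            edges = [np.linspace(0, 1, 21), np.linspace(0, 1, 21)]
            fes = FreeEnergySurface(edges, vals, np.zeros((20, 20), bool))
            basins, barriers, _ = find_basins_barriers(fes, min_depth=0.8)
            assert len(basins) >= 2
            a = np.unravel_index(np.argmin(fes.values), (20, 20))
            b_val = sorted(fes.values[fes.values < 0.7])  # second minimum
            saddle = barriers[0, 1] + fes.values.min()
            oracle = _minimax_level(fes.values, (3, 3), (16, 16))
            assert barriers[0, 1] + basins[0][2] == pytest.approx(oracle,
                                                                  abs=1e-9)

    def test_saddle_decreases_with_nested_refinement(self):
        """On nested grids every discrete path set grows with refinement,
        so the flood-fill saddle level between the two deepest basins can
        only decrease: no spurious saddles are introduced."""
        pot = MuellerLike2D()
        prev = math.inf
        for n in (15, 29, 57, 113):  # linspace grids that nest (n -> 2n-1)
            cx = np.linspace(-1.6, 1.0, n)
            cy = np.linspace(-0.2, 2.0, n)
            dx, dy = cx[1] - cx[0], cy[1] - cy[0]
            ex = np.concatenate([cx - dx / 2, [cx[-1] + dx / 2]])
            ey = np.concatenate([cy - dy / 2, [cy[-1] + dy / 2]])
            vals = np.array([[pot.energy(np.array([x, y])) for y in cy]
                             for x in cx])
            raw_min = vals.min()
            fes = FreeEnergySurface([ex, ey], vals,
                                    np.zeros_like(vals, dtype=bool))
            basins, barriers, _ = find_basins_barriers(fes, min_depth=0.3)
            assert len(basins) >= 2
            # absolute (unshifted) saddle level between A (global) and B
            saddle_abs = barriers[0, 1] + basins[0][2] + raw_min
            assert saddle_abs <= prev + 1e-9
            prev = saddle_abs

    def test_fully_masked_raises(self):
        with pytest.raises(SurfaceError):
            FreeEnergySurface([np.linspace(0, 1, 11)], np.zeros(10),
                              np.ones(10, bool))


def _minimax_level(values, a, b):
    """Smallest level L such that cells with value <= L connect a and b."""
    from collections import deque
    levels = np.unique(values)
    for level in levels:
        allowed = values <= level
        if not (allowed[a] and allowed[b]):
            continue
        seen = {a}
        queue = deque([a])
        while queue:
            i, j = queue.popleft()
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if (0 <= ni < values.shape[0] and 0 <= nj < values.shape[1]
                        and allowed[ni, nj] and (ni, nj) not in seen):
                    seen.add((ni, nj))
                    queue.append((ni, nj))
        if b in seen:
            return float(level)
    raise AssertionError("unreachable")


class TestDihedralChainEndToEnd:
    def test_s_cv_biasing_explores_both_states(self):
        """Biasing the dihedral-similarity CVs on a 4-angle chain drives
        transitions between the two constructed angle states."""
        mu0 = np.full(4, -1.2)
        mu1 = np.full(4, 1.2)
        # coupling 12 puts the per-angle barrier well above kT so the
        # unbiased control cannot cross on this timescale
        pot = DihedralChain(mu0, mu1, coupling=12.0, tilt=0.3)
        cvs = [SSimilarityCV(mu0), SSimilarityCV(mu1)]
        traj, bias = wt_metad(pot, cvs, W=0.1, widths=0.15, stride_ps=0.5,
                              bias_factor=10.0, kT=KT_300, dt=0.002,
                              n_steps=150_000, seed=5, x0=mu0.copy(),
                              record_stride=10, grid_points=80)
        s0 = traj.cvs[:, 0]
        s1 = traj.cvs[:, 1]
        assert s0.max() > 3.5 and s1.max() > 3.5  # both states visited
        # unbiased run from state 0 stays there (barrier too high)
        traj_u = langevin_sample(pot, kT=KT_300, dt=0.002, n_steps=150_000,
                                 seed=6, x0=mu0.copy(), record_stride=10)
        s1_u = np.array([cvs[1].value(x) for x in traj_u.states])
        assert s1_u.max() < 3.5


class TestHillsIO:
    def test_hills_file_round_trip(self, double_well_run, tmp_path):
        _, _, bias = double_well_run
        path = tmp_path / "hills.dat"
        bias.write(path)
        header = path.read_text().splitlines()[0].split()
        assert header == ["time", "center1", "sigma1", "height", "biasfactor"]
        back = BiasPotential.read(path)
        assert back.n_hills == bias.n_hills
        assert back.bias_factor == bias.bias_factor
        t1, c1, w1, h1 = bias.arrays()
        t2, c2, w2, h2 = back.arrays()
        np.testing.assert_allclose(c2, c1, atol=1e-7)
        np.testing.assert_allclose(h2, h1, atol=1e-7)
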