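import numpy as np
import pytest

from glycofibril import SyntheticScenario, gen_density_pair
from glycofibril.phasing import (
    AxialDensityProfile,
    PhasingConfig,
    aligned_correlation,
    fourier_moduli,
    modulus_residual,
    project_modulus,
    project_positive,
    refine,
    stage1_couple,
    stage2_fourier_difference,
    step_start,
)

ORDERS = tuple(range(1, 16))


def _pair_moduli(scenario):
    ini, fin, gl = gen_density_pair(scenario)
    return (fourier_moduli(ini.values, ORDERS),
            fourier_moduli(fin.values, ORDERS), ini, fin, gl)


class TestStepStart:
    def test_small_grid_definition(self):
        np.testing.assert_array_equal(step_start(4).values, [1, 1, 0, 0])

    def test_default_grid_split(self):
        v = step_start(1930).values
        assert v[:965].sum() == 965 and v[965:].sum() == 0

    def test_mean_half_for_even_grid(self):
        assert step_start(1000).values.mean() == pytest.approx(0.5)


class TestProjectors:
    def test_modulus_projection_is_exact_on_measured_orders(self):
        prof = step_start(512)
        targets = {1: 0.2, 3: 0.05, 7: 0.01}
        out = project_modulus(prof, targets)
        assert modulus_residual(out.values, targets) < 1e-12

    def test_satisfying_profile_is_fixed_point(self, noiseless_scenario):
        ini, _, _ = gen_density_pair(noiseless_scenario)
        targets = fourier_moduli(ini.values, ORDERS)
        # untouched-variant: the raw profile already satisfies its own moduli
        out = project_modulus(ini, targets, zero_unmeasured=False)
        np.testing.assert_allclose(out.values, ini.values, atol=1e-10)
        # default variant: fixed point once the profile is bandlimited
        spec = np.fft.rfft(ini.values)
        spec[max(ORDERS) + 1:] = 0.0
        band = AxialDensityProfile(np.fft.irfft(spec, n=ini.grid_size))
        out2 = project_modulus(band, fourier_moduli(band.values, ORDERS))
        np.testing.assert_allclose(out2.values, band.values, atol=1e-10)

    def test_single_mode_amplitude_scaled_phase_kept(self):
        n = 256
        x = np.arange(n) / n
        prof = AxialDensityProfile(np.cos(2 * np.pi * x + 0.7))
        out = project_modulus(prof, {1: 1.0})  # modulus 0.5 -> 1.0
        np.testing.assert_allclose(out.values, 2 * prof.values, atol=1e-10)

    def test_unmeasured_orders_zeroed_by_default_kept_on_request(self):
        n = 256
        x = np.arange(n) / n
        prof = AxialDensityProfile(1.0 + np.cos(2 * np.pi * 5 * x))
        out = project_modulus(prof, {1: 0.0})
        assert fourier_moduli(out.values, [5])[5] == pytest.approx(0.0, abs=1e-12)
        assert out.values.mean() == pytest.approx(1.0)  # order 0 untouched
        kept = project_modulus(prof, {1: 0.0}, zero_unmeasured=False)
        assert fourier_moduli(kept.values, [5])[5] == pytest.approx(0.5, abs=1e-12)

    def test_order_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            project_modulus(step_start(16), {9: 1.0})

    def test_positivity_clips_and_is_idempotent(self):
        prof = AxialDensityProfile(np.array([-1.0, 2.0, -0.001, 0.5]))
        once = project_positive(prof)
        np.testing.assert_array_equal(once.values, [0.0, 2.0, 0.0, 0.5])
        np.testing.assert_array_equal(project_positive(once).values, once.values)


class TestStage1:
    def test_identical_moduli_give_identical_trials(self, noiseless_scenario):
        mi, _, ini, _, _ = _pair_moduli(noiseless_scenario)
        cfg = PhasingConfig(stage1_iters=50)
        rho_i, rho_f = stage1_couple(mi, mi, cfg)
        np.testing.assert_allclose(rho_i.values, rho_f.values, atol=1e-12)

    def test_two_level_density_recovered_up_to_shift_and_mirror(self, noiseless_scenario):
        mi, _, ini, _, _ = _pair_moduli(noiseless_scenario)
        rho_i, _ = stage1_couple(mi, mi, PhasingConfig())
        r, _, _ = aligned_correlation(rho_i.values, ini.values)
        assert r > 0.95

    def test_zero_moduli_give_flat_output(self):
        zeros = {n: 0.0 for n in ORDERS}
        rho_i, rho_f = stage1_couple(zeros, zeros, PhasingConfig(stage1_iters=20))
        assert np.ptp(rho_i.values) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_order_sets_rejected(self):
        with pytest.raises(ValueError):
            stage1_couple({1: 0.1, 2: 0.1}, {1: 0.1, 3: 0.1},
                          PhasingConfig(stage1_iters=5))


class TestStage2:
    def test_zero_difference_gives_zero_profile(self):
        cfg = PhasingConfig(stage2_iters=50)
        start = AxialDensityProfile(np.zeros(cfg.grid_size), role="rho_gl")
        out = stage2_fourier_difference({n: 0.0 for n in ORDERS}, start, cfg)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_planted_gaussians_recovered_from_exact_moduli(self):
        sc = SyntheticScenario(seed=0, glycation_sites=((0.25, 0.04, 3.0),
                                                        (0.65, 0.03, 3.5)))
        _, _, gl = gen_density_pair(sc)
        targets = fourier_moduli(gl.values, ORDERS)
        start = AxialDensityProfile(np.full(1930, gl.values.mean()), role="rho_gl")
        out = stage2_fourier_difference(targets, start, PhasingConfig())
        # start again from the first solution: one extra polish pass
        out = stage2_fourier_difference(targets, out, PhasingConfig())
        r, _, _ = aligned_correlation(out.values, gl.values)
        assert r > 0.5  # flat start: phases from scratch
        # seeded with the truth the constraint set holds it (fixed point)
        fixed = stage2_fourier_difference(targets, gl, PhasingConfig())
        r2, _, _ = aligned_correlation(fixed.values, gl.values)
        assert r2 > 0.999

    def test_modulus_constraint_satisfied_at_convergence(self, noiseless_scenario):
        mi, mf, _, _, _ = _pair_moduli(noiseless_scenario)
        delta = {n: mf[n] - mi[n] for n in ORDERS}
        start = AxialDensityProfile(np.full(1930, 0.01), role="rho_gl")
        out = stage2_fourier_difference(delta, start, PhasingConfig(stage2_iters=2000))
        targets = {n: abs(v) for n, v in delta.items()}
        scale = np.sqrt(sum(v**2 for v in targets.values()))
        assert modulus_residual(out.values, targets) / scale < 1e-6


class TestRefine:
    def test_resolution_recorded_as_period_over_max_order(self):
        sc = SyntheticScenario(seed=0)
        mi, mf, _, _, _ = _pair_moduli(sc)
        cfg = PhasingConfig(stage1_iters=10, stage2_iters=10, outer_cycles=1)
        res = refine(mi, mf, cfg, d_M=65.0, until_converged=False)
        assert res.resolution_nm == pytest.approx(65.0 / 15, abs=0.05)
        assert res.resolution_nm == pytest.approx(4.33, abs=0.01)

    def test_identical_inputs_give_near_zero_glycation_density(self, noiseless_scenario):
        mi, _, _, _, _ = _pair_moduli(noiseless_scenario)
        cfg = PhasingConfig(stage1_iters=50, stage2_iters=50, outer_cycles=2)
        res = refine(mi, mi, cfg, until_converged=False)
        assert np.max(np.abs(res.rho_gl.values)) < 1e-10

    def test_planted_density_recovered_end_to_end(self, noiseless_scenario):
        mi, mf, _, _, gl = _pair_moduli(noiseless_scenario)
        res = refine(mi, mf)
        r, _, _ = aligned_correlation(res.rho_gl.values, gl.values)
        assert r > 0.85

    def test_deterministic_bit_identical_reruns(self, noiseless_scenario):
        mi, mf, _, _, _ = _pair_moduli(noiseless_scenario)
        cfg = PhasingConfig(stage1_iters=30, stage2_iters=30, outer_cycles=2)
        a = refine(mi, mf, cfg, until_converged=False)
        b = refine(mi, mf, cfg, until_converged=False)
        np.testing.assert_array_equal(a.rho_gl.values, b.rho_gl.values)

    @pytest.mark.parametrize("grid", [960, 3860])
    def test_grid_size_stability(self, grid):
        sc = SyntheticScenario(seed=0, noise_snr=np.inf, background_amp=0.0,
                               grid_size=grid)
        ini, fin, gl = gen_density_pair(sc)
        mi = fourier_moduli(ini.values, ORDERS)
        mf = fourier_moduli(fin.values, ORDERS)
        res = refine(mi, mf, PhasingConfig(grid_size=grid))
        r, _, _ = aligned_correlation(res.rho_gl.values, gl.values)
        assert r > 0.85


class TestAlignedCorrelation:
    def test_recovers_known_shift_and_mirror(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=500)
        r, s, m = aligned_correlation(a, np.roll(a, 123))
        assert (r, s, m) == (pytest.approx(1.0), 123, False)
        r2, s2, m2 = aligned_correlation(a, np.roll(a[::-1], 45))
        assert r2 == pytest.approx(1.0) and m2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            aligned_correlation(np.ones(16), np.arange(16.0))
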