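import numpy as np
import pytest
from scipy.special import k0 as bessel_k0

from matesim import (
    ExtracellularField,
    Grid,
    SourceSpec,
    build_scenario,
    effective_alpha_decay,
    extract_membrane_curve,
    init_circle_levelset,
    membrane_source_field,
    qss_solve,
    region_masks,
    sample_and_normalize,
    step_field,
)
from matesim.fields import SOURCE_AMPLITUDE, QssSolver, sample_membrane
from matesim.levelset import CFLViolationError
from matesim.simulation import Simulation

A = SOURCE_AMPLITUDE


class TestMembraneSource:
    def test_peak_value_on_membrane(self, grid08, circle_ls, circle_curve):
        # polarized source at a membrane point where u2 = u2max:
        # S = 1000/sqrt(2 pi) exactly
        u2 = np.ones(200)
        masks = region_masks([circle_ls], grid08)
        S = membrane_source_field(circle_ls, circle_curve, u2,
                                  SourceSpec(mode="polarized"), masks.bands[0])
        # at every band node S must equal the printed formula exactly (with
        # u2 = u2max the polarization factor is 1); at the node closest to
        # the membrane this approaches the amplitude A itself
        band = masks.bands[0]
        np.testing.assert_allclose(
            S[band], A * np.exp(-100.0 * circle_ls.phi[band] ** 2), rtol=1e-12)
        phimin = np.abs(circle_ls.phi[band]).min()
        assert S[band].max() == pytest.approx(A * np.exp(-100 * phimin**2), rel=1e-9)
        assert S[band].max() > 0.9 * A

    def test_isotropic_gaussian_decay_off_membrane(self, grid08, circle_ls):
        masks = region_masks([circle_ls], grid08)
        S = membrane_source_field(circle_ls, None, None,
                                  SourceSpec(mode="isotropic"), masks.bands[0])
        # the source follows A exp(-100 phi^2) exactly at every band node;
        # at phi ~ 0.3 um it has dropped to ~ A e^-9 ~ 4.9e-2
        band = masks.bands[0]
        np.testing.assert_allclose(
            S[band], A * np.exp(-100.0 * circle_ls.phi[band] ** 2), rtol=1e-12)
        i = np.unravel_index(np.argmin(np.abs(circle_ls.phi - 0.3)), S.shape)
        assert abs(circle_ls.phi[i] - 0.3) < 0.03
        assert S[i] < 0.05 * A  # more than e^-3 below any near-membrane value
        assert S[i] == pytest.approx(A * np.exp(-100 * circle_ls.phi[i] ** 2))

    def test_polarized_source_negligible_away_from_polarisome(
            self, grid08, circle_ls, circle_curve, circle_theta):
        # u2 profile peaked at theta=0; where u2 = 0.2 u2max the source
        # carries the factor exp(-12.8) < 1% of peak
        u2 = np.exp(-circle_theta**2 / (2 * 0.4**2))
        masks = region_masks([circle_ls], grid08)
        S = membrane_source_field(circle_ls, circle_curve, u2,
                                  SourceSpec(mode="polarized"), masks.bands[0])
        on_membrane = grid08.interp(S, circle_curve.points)
        back = np.abs(np.abs(circle_theta) - np.pi / 2) < 0.1  # u2 ~ 0.2 max
        assert on_membrane[back].max() < 0.01 * on_membrane.max()

    def test_polarized_falls_back_to_isotropic_without_u2(self, grid08, circle_ls,
                                                          circle_curve):
        masks = region_masks([circle_ls], grid08)
        spec = SourceSpec(mode="polarized")
        S_no_u2 = membrane_source_field(circle_ls, circle_curve, np.zeros(200),
                                        spec, masks.bands[0])
        S_iso = membrane_source_field(circle_ls, None, None,
                                      SourceSpec(mode="isotropic"), masks.bands[0])
        np.testing.assert_allclose(S_no_u2, S_iso)


class TestStepField:
    def test_pure_decay_closed_form(self):
        g = Grid(0, 1, 0, 1, 0.1)
        ext = np.ones(g.shape, bool)
        fld = ExtracellularField(g, np.ones(g.shape), 0.0, 1.0, 0.0)
        dt, n = 4e-4, 2500  # total time 1.0
        for _ in range(n):
            fld = step_field(fld, np.zeros(g.shape), ext, dt)
        np.testing.assert_allclose(fld.values, np.exp(-1.0), rtol=5e-4)

    def test_mass_conservation_no_flux(self, grid08, circle_ls):
        # diffusion only around an interior obstacle: total exterior mass
        # conserved to 1e-6 relative over 1000 steps
        masks = region_masks([circle_ls], grid08)
        rng = np.random.default_rng(0)
        vals = np.where(masks.exterior, 1.0 + 0.5 * rng.random(grid08.shape), 0.0)
        fld = ExtracellularField(grid08, vals, 3.0, 1e-12, 0.0)
        m0 = fld.values.sum()
        for _ in range(1000):
            fld = step_field(fld, np.zeros(grid08.shape), masks.exterior, 4e-4)
        assert fld.values.sum() == pytest.approx(m0, rel=1e-6)

    def test_multiplicative_noise_preserves_ensemble_mean(self):
        # Euler-Maruyama with drift 0 and noise kappa1 f dW is a martingale
        g = Grid(0, 0.7, 0, 0.7, 0.1)
        ext = np.ones(g.shape, bool)
        rng = np.random.default_rng(123)
        means = []
        for _ in range(400):
            fld = ExtracellularField(g, np.ones(g.shape), 0.5, 1e-12, 1.0)
            for _ in range(50):
                fld = step_field(fld, np.zeros(g.shape), ext, 1e-3, rng)
            means.append(fld.values.mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.03)

    def test_clamp_rate_below_threshold_at_default_noise(self, grid08, circle_ls):
        masks = region_masks([circle_ls], grid08)
        spec = SourceSpec(mode="isotropic")
        S = membrane_source_field(circle_ls, None, None, spec, masks.bands[0])
        rng = np.random.default_rng(5)
        # D comfortably inside the stability region (4 D dt / h^2 = 0.5)
        fld = ExtracellularField(grid08, np.zeros(grid08.shape), 2.0, 100.0,
                                 kappa1=5.0)
        for _ in range(200):
            fld = step_field(fld, S, masks.exterior, 4e-4, rng)
        assert fld.clamp_events / fld.node_steps < 1e-3

    def test_cfl_violation_raises(self, grid08):
        ext = np.ones(grid08.shape, bool)
        fld = ExtracellularField(grid08, np.ones(grid08.shape), 1e4, 1.0, 0.0)
        with pytest.raises(CFLViolationError):
            step_field(fld, np.zeros(grid08.shape), ext, 4e-4)


class TestEffectiveDecay:
    def test_no_protease_gives_basal_rate(self):
        assert effective_alpha_decay(2.0, 20.0, None) == 2.0
        z = effective_alpha_decay(2.0, 20.0, np.zeros((4, 4)))
        np.testing.assert_allclose(z, 2.0)

    def test_uniform_protease_adds_full_rate(self):
        B = np.ones((4, 4))
        rate = effective_alpha_decay(2.0, 20.0, B, eps=1e-6)
        np.testing.assert_allclose(rate, 22.0, rtol=1e-5)

    def test_monotone_in_protease(self):
        rng = np.random.default_rng(1)
        B = rng.random((10, 10))
        rate = effective_alpha_decay(2.0, 20.0, B)
        order = np.argsort(B.ravel())
        assert np.all(np.diff(rate.ravel()[order]) >= 0)
        assert rate.ravel()[order[-1]] == rate.max()


class TestQss:
    def test_uniform_source_balance(self):
        g = Grid(0, 1, 0, 1, 0.1)
        ext = np.ones(g.shape, bool)
        f = qss_solve(g, ext, 2.0, 4.0, np.full(g.shape, 8.0))
        np.testing.assert_allclose(f, 2.0, rtol=1e-10)

    def test_zero_source_gives_zero(self):
        g = Grid(0, 1, 0, 1, 0.1)
        ext = np.ones(g.shape, bool)
        f = qss_solve(g, ext, 2.0, 4.0, np.zeros(g.shape))
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_singular_without_decay(self):
        g = Grid(0, 1, 0, 1, 0.1)
        ext = np.ones(g.shape, bool)
        with pytest.raises(ValueError, match="k_eff"):
            qss_solve(g, ext, 2.0, 0.0, np.ones(g.shape))

    def test_far_field_matches_bessel_k0(self):
        # screened diffusion from a compact source decays as K0(r/lambda)
        g = Grid(-3.6, 3.6, -3.6, 3.6, 0.08)
        ls = init_circle_levelset((0.0, 0.0), 1.0, g)
        masks = region_masks([ls], g)
        S = membrane_source_field(ls, None, None, SourceSpec(mode="isotropic"),
                                  masks.bands[0])
        D, k = 400.0, 400.0  # lambda = 1 um
        f = qss_solve(g, masks.exterior, D, k, S)
        X, Y = g.meshgrid()
        r = np.hypot(X, Y)
        # window away from both the ring source (band ends ~1.5) and the
        # no-flux outer boundary
        sel = ((r > 1.8) & (r < 2.4) & masks.exterior
               & (np.abs(X) < 3.0) & (np.abs(Y) < 3.0))
        model = bessel_k0(r[sel])
        amp = np.sum(model * f[sel]) / np.sum(model**2)
        resid = np.abs(f[sel] - amp * model) / (amp * model)
        assert resid.max() < 0.05


def _two_cell_field_fixture():
    g = Grid(-1.8, 1.8, -1.2, 1.2, 0.12)
    a = init_circle_levelset((-0.75, 0.0), 0.45, g, "a")
    b = init_circle_levelset((0.75, 0.0), 0.45, g, "b")
    masks = region_masks([a, b], g)
    S = membrane_source_field(a, None, None, SourceSpec(mode="isotropic"),
                              masks.bands[0])
    return g, masks, S


class TestQssExplicitEquivalence:
    def test_qss_matches_explicit_steady_state(self):
        # noise-free explicit stepping to steady state on a two-cell fixture
        # must agree with the sparse QSS solve within 1%
        g, masks, S = _two_cell_field_fixture()
        D, k = 6.0, 100.0
        f_qss = qss_solve(g, masks.exterior, D, k, S)
        fld = ExtracellularField(g, np.zeros(g.shape), D, k, 0.0)
        for _ in range(750):  # 0.3 time units >> 1/k
            fld = step_field(fld, S, masks.exterior, 4e-4)
        sel = masks.exterior & (f_qss > 1e-3 * f_qss.max())
        rel = np.abs(fld.values[sel] - f_qss[sel]) / f_qss[sel]
        assert rel.max() < 0.01


class TestSampling:
    def test_uniform_field_normalizes_to_1p1(self, grid08, circle_ls, circle_curve):
        masks = region_masks([circle_ls], grid08)
        fld = ExtracellularField(grid08,
                                 np.where(masks.exterior, 5.0, 0.0), 1.0, 1.0)
        ft = sample_and_normalize(fld, circle_curve, masks.exterior)
        np.testing.assert_allclose(ft, 1.1, atol=1e-9)

    def test_half_maximum_maps_to_0p6(self):
        from matesim.fields import normalize_ligand
        ft = normalize_ligand(np.array([1.0, 2.0]))
        np.testing.assert_allclose(ft, [0.6, 1.1])

    def test_zero_field_guard(self, grid08, circle_ls, circle_curve):
        masks = region_masks([circle_ls], grid08)
        fld = ExtracellularField(grid08, np.zeros(grid08.shape), 1.0, 1.0)
        ft = sample_and_normalize(fld, circle_curve, masks.exterior)
        np.testing.assert_allclose(ft, 0.1)


class TestBar1GradientShaping:
    def test_bar1_steepens_alpha_gradient_at_high_background(self):
        # with background alpha-factor C = 50, a Bar1+ a-cell senses a
        # steeper (larger relative range) alpha-factor profile than bar1-delta
        contrasts = {}
        for bar1 in (False, True):
            cells = [dict(mating_type="a", center0=(-2.0, 0.0), bar1=bar1),
                     dict(mating_type="alpha", center0=(2.0, 0.0))]
            cfg = build_scenario(
                "two_cell", h=0.08, n_markers=200, background_C=50.0,
                kappa1=0.0, kappa2=0.0, kappa3=0.0, cells=cells,
            )
            sim = Simulation(cfg, seed=0)
            sim.update_fields(0.05)
            a = sim.cells[0]
            f = sample_membrane(sim.f_alpha, sim.grid, a.curve, sim.masks.exterior)
            contrasts[bar1] = (f.max() - f.min()) / f.max()
        assert contrasts[True] > contrasts[False]
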