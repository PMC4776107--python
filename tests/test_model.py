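"""Analytical reflectance model: limits, oracles, transforms, assembly."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import j0

import subdiffuse as sd
from subdiffuse.model import (
    _single_turn_return, _glory_depth_integral, ballistic_plateau,
)


@pytest.fixture(scope="module")
def props():
    saa = sd.SaaPhaseParams(0.0188, 0.4539)
    return sd.OpticalProperties(mu_s=1.0, mu_a=0.0, mu_b=0.00332,
                                saa=saa, g=0.9163)


@pytest.fixture(scope="module")
def props_abs():
    saa = sd.SaaPhaseParams(0.0182, 0.4501)
    return sd.OpticalProperties(mu_s=1.0, mu_a=0.0130, mu_b=0.00306,
                                saa=saa, g=0.9174, psi_b=0.026)


# -- spread function --------------------------------------------------------

def test_spread_zero_frequency(props_abs):
    z = 2.7
    expect = np.exp(-(props_abs.mu_a + 2 * props_abs.saa.p_b
                      * props_abs.mu_s) * z)
    assert sd.spread_function(0.0, z, props_abs) == pytest.approx(expect,
                                                                  rel=1e-12)


def test_spread_no_scattering_limit():
    saa = sd.SaaPhaseParams(0.02, 0.45)
    p = sd.OpticalProperties(mu_s=1e-9, mu_a=0.05, mu_b=1e-12, saa=saa, g=0.5)
    assert sd.spread_function(3.0, 2.0, p) == pytest.approx(
        np.exp(-0.05 * 2.0), rel=1e-8)


@pytest.mark.parametrize("q,z", [(0.7, 1.3), (4.0, 0.5), (12.0, 2.0)])
def test_spread_against_depth_integral_oracle(props_abs, q, z):
    # independent evaluation of the defining z'-integral with the Gaussian
    # angular transform chi(v) = (1 - 2 p_b) exp(-v^2 Theta^2/4)
    pars = props_abs.saa
    chi_int, _ = quad(
        lambda u: (1 - 2 * pars.p_b)
        * np.exp(-(q * u * pars.Theta) ** 2 / 4.0), 0.0, z, limit=200)
    expect = np.exp(-props_abs.mu_t * z + props_abs.mu_s * chi_int)
    assert sd.spread_function(q, z, props_abs) == pytest.approx(expect,
                                                                rel=1e-6)


def test_spread_rejects_negative_depth(props):
    with pytest.raises(ValueError):
        sd.spread_function(1.0, -0.1, props)


def test_oblique_geometry_rejected(props):
    with pytest.raises(NotImplementedError):
        sd.spread_function(1.0, 1.0, props, s_perp=0.2)
    with pytest.raises(NotImplementedError):
        sd.reflectance_saa_q(1.0, props, s_perp=0.1)


# -- SAA reflectance --------------------------------------------------------

@pytest.mark.parametrize("q", [0.4, 2.0, 11.0])
def test_single_turn_return_against_brute_quadrature(q):
    # 2-D oracle: depth x exit-cosine quadrature of the defining integral
    mu_iso, mu_a = 0.0376, 0.013
    mu = mu_iso + mu_a

    def inner(z):
        val, _ = quad(lambda u: np.exp(-mu * z / u)
                      * j0(q * z * np.sqrt(1 - u * u) / u),
                      0.0, 1.0, limit=200)
        return 0.5 * val * mu_iso * np.exp(-mu * z)

    oracle, _ = quad(inner, 0.0, 60.0 / mu, limit=200)
    assert _single_turn_return(q, mu_iso, mu_a) == pytest.approx(oracle,
                                                                 rel=1e-3)


def test_saa_small_scattering_limit():
    # mu_s -> 0: attenuation is purely absorptive and the depth integrals
    # collapse: the floor return tends to (mu_iso/2 mu_a)(1 - ln 2) and
    # the glory excess to mu_b^x/(2 mu_a)
    saa = sd.SaaPhaseParams(0.02, 0.45)
    p = sd.OpticalProperties(mu_s=1e-6, mu_a=0.05, mu_b=1e-6 * 0.003,
                             saa=saa, g=0.0)
    expect = (p.mu_iso / (2 * (p.mu_iso + p.mu_a)) * (1 - np.log(2))
              + p.mu_b_excess / (2 * p.mu_a))
    assert sd.reflectance_saa_q(1e-9, p) == pytest.approx(expect, rel=1e-4)


def test_saa_divergence_guard():
    saa = sd.SaaPhaseParams(0.0, 0.45)
    p = sd.OpticalProperties(mu_s=1.0, mu_a=0.0, mu_b=0.003, saa=saa, g=0.9)
    with pytest.raises(ValueError):
        sd.reflectance_saa_q(0.5, p)


def test_highq_limit_convergence(props_abs):
    # the closed high-q form is the narrow-lobe (psi_b -> 0) limit and
    # converges onto the full expression from above
    from dataclasses import replace
    p = replace(props_abs, psi_b=None)
    for qf, tol in ((20, 0.01), (40, 0.004)):
        q = qf / p.l_theta
        full = sd.reflectance_saa_q(q, p)
        lim = sd.reflectance_saa_highq(q, p)
        assert abs(lim / full - 1) < tol


def test_highq_rejects_zero_frequency(props):
    with pytest.raises(ValueError):
        sd.reflectance_saa_highq(0.0, props)


def test_highq_approaches_ballistic_plateau(props_abs):
    lim = sd.reflectance_saa_highq(1e6, props_abs)
    tail = _single_turn_return(1e6, props_abs.mu_iso, props_abs.mu_a)
    assert lim - tail == pytest.approx(ballistic_plateau(props_abs),
                                       rel=1e-4)


# -- snake and diffuse ------------------------------------------------------

def test_snake_absorption_monotonicity(props):
    qs = np.array([0.05, 0.2, 0.6])
    base = sd.reflectance_snake_q(qs, props)
    for mu_a in (0.005, 0.02):
        p = sd.OpticalProperties(1.0, mu_a, props.mu_b, props.saa, props.g)
        vals = sd.reflectance_snake_q(qs, p)
        assert np.all(vals < base)
        assert np.all(vals > 0)


def test_flux_conservation_without_absorption(props):
    # at q -> 0 and mu_a = 0 every photon escapes: the three populations
    # must sum to unity (to the ladder's grid resolution)
    total = (sd.reflectance_saa_q(1e-6, props)
             + sd.reflectance_snake_q(1e-6, props)
             + sd.reflectance_diffuse_q(1e-6, props))
    assert total == pytest.approx(1.0, abs=0.04)


def test_diffusion_theory_oracle_conservative_limit(props):
    # the diffusion-theory reflectance the diffuse term approaches at
    # q -> 0: in the conservative limit both equal total reflectance 1
    val = sd.diffusion_theory_reflectance(1e-9, props)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_diffusion_theory_decreases_with_absorption(props):
    vals = [sd.diffusion_theory_reflectance(
        0.01, sd.OpticalProperties(1.0, mu_a, props.mu_b, props.saa, props.g))
        for mu_a in (0.0, 0.005, 0.02)]
    assert np.all(np.diff(vals) < 0)


def test_mismatched_boundary_rejected(props):
    with pytest.raises(NotImplementedError):
        sd.BoundaryModel(matched=False).z_e(props)


# -- total assembly ---------------------------------------------------------

def test_sum_assembly_components(props_abs):
    q = np.linspace(0.05, 20, 12)
    prof = sd.reflectance_total_q(q, props_abs)
    np.testing.assert_allclose(
        prof.total,
        prof.components["saa"] + prof.components["snake"]
        + prof.components["diffuse"], rtol=1e-12)
    for name in ("saa", "snake", "diffuse", "total"):
        assert np.all(prof.components[name] >= 0)


def test_split_assembly_continuity(props_abs):
    prof = sd.reflectance_total_q(np.linspace(0.05, 20, 12), props_abs,
                                  assembly="split")
    q_c = prof.q_c
    assert q_c is not None
    low = (sd.reflectance_snake_q(q_c, props_abs)
           + sd.reflectance_diffuse_q(q_c, props_abs)
           + ballistic_plateau(props_abs))
    high = sd.reflectance_saa_q(q_c, props_abs)
    assert abs(low / high - 1) < 1e-6
    # crossover sits near its analytic estimate 2 pi beta
    assert 0.1 * 2 * np.pi * props_abs.beta < q_c < 10 * 2 * np.pi * props_abs.beta


def test_scale_invariance(props_abs):
    # expressing lengths in units of 1/mu_s leaves the profile unchanged
    s = 1.7
    scaled = sd.OpticalProperties(
        mu_s=s, mu_a=s * props_abs.mu_a, mu_b=s * props_abs.mu_b,
        saa=props_abs.saa, g=props_abs.g, psi_b=props_abs.psi_b)
    q = np.array([0.1, 0.7, 3.0, 15.0])
    a = sd.reflectance_total_q(q, props_abs).total
    b = sd.reflectance_total_q(q * s, scaled).total
    np.testing.assert_allclose(a, b, rtol=1e-10)


def test_nonnegative_over_parameter_box():
    for g, ratio in ((0.7, 0.0), (0.9, 0.02), (0.98, 0.05)):
        saa = sd.SaaPhaseParams(0.03, 0.6)
        p = sd.OpticalProperties(1.0, ratio, 0.004, saa, g)
        prof = sd.reflectance_total_q(np.array([0.05, 0.5, 5.0, 30.0]), p)
        assert np.all(prof.total > 0)


# -- transforms -------------------------------------------------------------

def test_hankel_gaussian_pair():
    # exp(-q^2 a^2/4) <-> (1/(pi a^2)) exp(-rho^2/a^2)
    a = 0.8
    q = np.linspace(0, 40 / a, 4000)
    f = np.exp(-(q * a) ** 2 / 4)
    rho = np.array([0.0, 0.3, 0.9, 1.8])
    got = sd.hankel_transform(q, f, rho, direction="inverse")
    expect = np.exp(-(rho / a) ** 2) / (np.pi * a**2)
    np.testing.assert_allclose(got, expect, rtol=2e-3)


def test_real_space_round_trip():
    # transform-pair identity on a synthetic profile: a Gaussian plus a
    # constant plateau; the plateau must come back as the delta weight and
    # the Gaussian must survive the q -> rho -> q round trip
    a, plateau = 0.6, 2e-3
    q = np.linspace(0.0, 50.0 / a, 3000)
    gauss = 0.05 * np.exp(-(q * a) ** 2 / 4)
    prof = sd.ReflectanceProfile(
        "q", q, {"total": gauss + plateau,
                 "ballistic": np.full(q.size, plateau)})
    rho = np.linspace(0.0, 6.0 * a, 400)
    rprof = sd.to_real_space(prof, rho)
    assert rprof.delta_weight == pytest.approx(plateau)
    expect = 0.05 * np.exp(-(rho / a) ** 2) / (np.pi * a**2)
    np.testing.assert_allclose(rprof.total, expect, atol=2e-3 * expect[0])
    back = sd.hankel_transform(rho, rprof.total, q[10:800:80],
                               direction="forward") + plateau
    np.testing.assert_allclose(back, prof.total[10:800:80], rtol=1e-3)


def test_real_space_truncation_guard(props_abs):
    q = np.linspace(0.01, 3.0, 200)   # hopelessly short of 50 mu_t
    prof = sd.reflectance_total_q(q, props_abs)
    with pytest.raises(ValueError):
        sd.to_real_space(prof, np.array([0.01, 0.1]))


def test_rho_highq_against_adaptive_oracle(props_abs):
    rho = np.array([0.2, 1.0])
    cont, weight = sd.reflectance_saa_rho_highq(rho, props_abs)
    assert weight == pytest.approx(ballistic_plateau(props_abs))
    q_sw = 20.0 / props_abs.l_theta

    def integrand(q, r):
        f = (sd.reflectance_saa_q(q, props_abs) if q < q_sw
             else sd.reflectance_saa_highq(q, props_abs))
        return (f - ballistic_plateau(props_abs)) * j0(q * r) * q

    for r, got in zip(rho, cont):
        v1, _ = quad(integrand, 1e-3 / props_abs.l_theta, q_sw, args=(r,),
                     limit=800)
        v2, _ = quad(integrand, q_sw, 400.0 / props_abs.l_theta, args=(r,),
                     limit=2000)
        assert got == pytest.approx((v1 + v2) / (2 * np.pi), rel=2e-3)


def test_rho_highq_monotone_tail(props_abs):
    rho = props_abs.l_theta * np.array([2.0, 3.0, 5.0, 8.0])
    cont, _ = sd.reflectance_saa_rho_highq(rho, props_abs)
    assert np.all(np.diff(cont) < 0)
    assert np.all(cont > 0)
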