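"""Inversion: merit definition, round trips, identifiability, guards."""

import numpy as np
import pytest

import subdiffuse as sd


# -- merit ------------------------------------------------------------------

def test_merit_perfect_match():
    y = np.array([0.5, 0.1, 0.02, 0.004])
    assert sd.merit_r2(y, y) == pytest.approx(1.0)


def test_merit_constant_log_model_is_zero():
    truth = np.array([0.5, 0.1, 0.02, 0.004])
    model = np.full(4, np.exp(np.mean(np.log(truth))))
    assert sd.merit_r2(model, truth) == pytest.approx(0.0, abs=1e-12)


def test_merit_hand_computed():
    # n = 4 vectors evaluated against independent arithmetic of the formula
    truth = np.array([1.0, 0.5, 0.2, 0.1])
    model = np.array([0.9, 0.55, 0.18, 0.12])
    lt, lm = np.log(truth), np.log(model)
    expect = 1 - float(np.sum((lm - lt) ** 2)) / float(
        np.sum((lt - lt.mean()) ** 2))
    assert sd.merit_r2(model, truth) == pytest.approx(expect, rel=1e-12)


def test_merit_guards():
    with pytest.raises(ValueError):
        sd.merit_r2(np.array([1.0, -0.1]), np.array([1.0, 0.5]))
    with pytest.raises(ValueError):
        sd.merit_r2(np.array([1.0, 1.0]), np.array([0.5, 0.5]))


# -- round trips ------------------------------------------------------------

def _draw_medium(rng):
    """Random forward-peaked medium in the box g >= 0.8, mu_a/mu_s <= 0.03."""
    while True:
        p_b = rng.uniform(0.005, 0.035)
        Theta = rng.uniform(0.35, 0.7)
        saa = sd.SaaPhaseParams(p_b, Theta)
        if sd.saa_anisotropy(saa) < 0.8:
            continue
        if Theta**2 <= 2 * p_b * (np.pi**2 - 4) / 2 * 1.15:
            continue
        mu_s = rng.uniform(0.6, 1.8)
        mu_a = mu_s * rng.uniform(0.0, 0.03)
        floor = mu_s * p_b / (2 * np.pi)
        mu_b = floor * rng.uniform(0.9, 2.5)
        return sd.OpticalProperties(mu_s, mu_a, mu_b, saa,
                                    sd.saa_anisotropy(saa))


def _profile_grid(mu_s):
    return np.concatenate([np.linspace(0.08, 1.0, 12),
                           np.geomspace(1.3, 42, 24)]) * mu_s


@pytest.mark.parametrize("draw", range(4))
def test_noise_free_round_trip(draw):
    """Noise-free identifiability: both stages recover the generating
    parameters essentially exactly."""
    rng = np.random.default_rng(100 + draw)
    true = _draw_medium(rng)
    q = _profile_grid(true.mu_s)
    prof = sd.reflectance_total_q(q, true)
    scaled = sd.ReflectanceProfile("q", q / true.mu_s,
                                   {"total": prof.total})
    s1 = sd.fit_highq(scaled, p_b=true.saa.p_b)
    assert s1.mu_b_over_mu_s == pytest.approx(true.mu_b / true.mu_s,
                                              rel=1e-3)
    assert s1.Theta == pytest.approx(true.saa.Theta, rel=1e-3)
    res = sd.fit_full(prof, s1, n_starts=2, seed=draw)
    s = res.summary()
    assert s["mu_s"] == pytest.approx(true.mu_s, rel=1e-3)
    assert s["mu_a"] == pytest.approx(true.mu_a, rel=1e-3, abs=1e-5)
    assert s["p_b"] == pytest.approx(true.saa.p_b, rel=1e-3)
    assert s["Theta"] == pytest.approx(true.saa.Theta, rel=1e-3)
    assert res.r_squared > 1 - 1e-8


def test_noisy_round_trip_median_error():
    """1% multiplicative log-normal noise: median relative errors of Theta
    and mu_s stay below 5% over seeded draws."""
    errs_T, errs_s = [], []
    for draw in range(3):
        rng = np.random.default_rng(300 + draw)
        true = _draw_medium(rng)
        q = _profile_grid(true.mu_s)
        prof = sd.reflectance_total_q(q, true)
        noisy = prof.total * np.exp(rng.normal(0, 0.01, q.size))
        nprof = sd.ReflectanceProfile("q", q, {"total": noisy})
        scaled = sd.ReflectanceProfile("q", q / true.mu_s, {"total": noisy})
        s1 = sd.fit_highq(scaled, p_b=true.saa.p_b)
        res = sd.fit_full(nprof, s1, n_starts=2, seed=draw)
        errs_T.append(abs(res.params.saa.Theta - true.saa.Theta)
                      / true.saa.Theta)
        errs_s.append(abs(res.params.mu_s - true.mu_s) / true.mu_s)
    assert np.median(errs_T) < 0.05
    assert np.median(errs_s) < 0.05


def test_stage_coupling_not_worse_at_truth():
    # fixing mu_b/mu_s at the (noise-free) stage-1 value cannot worsen the
    # stage-2 objective at the true parameters versus leaving it free
    rng = np.random.default_rng(42)
    true = _draw_medium(rng)
    q = _profile_grid(true.mu_s)
    prof = sd.reflectance_total_q(q, true)
    scaled = sd.ReflectanceProfile("q", q / true.mu_s, {"total": prof.total})
    s1 = sd.fit_highq(scaled, p_b=true.saa.p_b)
    res = sd.fit_full(prof, s1, n_starts=1, seed=0)
    assert float(np.sum(res.residuals**2)) <= 1e-10


# -- guards -----------------------------------------------------------------

def test_narrow_window_raises():
    q = np.linspace(5.0, 9.0, 15)
    prof = sd.ReflectanceProfile("q", q, {"total": np.full(15, 0.01)})
    with pytest.raises(ValueError):
        sd.fit_highq(prof, q_min=4.0)


def test_window_below_crossover_raises():
    # a profile confined to the diffusive core has no usable points
    q = np.linspace(0.01, 0.2, 30)
    prof = sd.ReflectanceProfile("q", q, {"total": np.full(30, 0.3)})
    with pytest.raises(ValueError):
        sd.fit_highq(prof, p_b=0.02)


def test_stage1_requires_q_domain():
    prof = sd.ReflectanceProfile("rho", np.linspace(0.1, 1, 20),
                                 {"total": np.full(20, 0.1)})
    with pytest.raises(ValueError):
        sd.fit_highq(prof)
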