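"""Shared fixtures: reference media, mapped parameters, and cached MC runs.

Everything is generated at test time from physics; the polystyrene-in-water
suspensions at 0.515 um (d = 1.50 um with and without absorption, d = 0.49
um) are the reference media used throughout.  Expensive artefacts (Mie
phase functions, Monte Carlo tallies, the transport-ladder kernel table)
are session-scoped so they are built once per run.
"""

from __future__ import annotations

import pytest

import subdiffuse as sd


@pytest.fixture(scope="session")
def suspensions():
    """The three reference suspensions keyed 'd15', 'd15a', 'd049'."""
    d15 = sd.polystyrene_in_water(1.50)
    return {
        "d15": d15,
        "d15a": sd.tune_absorption(d15, 0.0130),
        "d049": sd.polystyrene_in_water(0.49),
    }


@pytest.fixture(scope="session")
def phases(suspensions):
    return {k: sd.mie_phase_function(s, 4096) for k, s in suspensions.items()}


@pytest.fixture(scope="session")
def media(suspensions, phases):
    """OpticalProperties (mu_s = 1/cm) plus backscatter lobe widths."""
    out = {}
    for key, susp in suspensions.items():
        p = phases[key]
        bulk = sd.mie_bulk_properties(susp)
        pars = sd.map_phase_function(p)
        psi_b = sd.backward_lobe_width(p, pars.p_b)
        out[key] = sd.OpticalProperties(
            mu_s=1.0, mu_a=bulk["mu_a"], mu_b=bulk["mu_b"],
            saa=pars, g=bulk["g"], psi_b=psi_b)
    return out


#: standard merit grid: dense through the crossover, uniform to q = 10 mu_s
MERIT_Q = sd.merit_q_grid(1.0)


@pytest.fixture(scope="session")
def mc_small(phases, media):
    """1e5-photon MC tallies on the merit grid for the three media."""
    seeds = {"d15": 1301, "d15a": 1302, "d049": 1303}
    out = {}
    for key in ("d15", "d15a", "d049"):
        cfg = sd.McConfig(phase=phases[key], mu_s=1.0,
                          mu_a=media[key].mu_a, n_photons=100_000,
                          seed=seeds[key], q_grid=MERIT_Q)
        out[key] = sd.run_mc(cfg)
    return out
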