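"""Scalar Monte Carlo photon transport in a semi-infinite turbid medium.

Ground-truth reflectance for validating the analytical model: a pencil beam
enters a uniform half-space (matched refractive index, no Fresnel
reflection) at normal incidence; photons random-walk with exponential free
paths at the total attenuation mu_t, scatter through angles drawn from an
arbitrary tabulated phase function by inverse-CDF lookup, and are tallied
when they cross the surface.  Absorption is handled by implicit capture
(weight *= mu_s/mu_t per event) with Russian roulette below a weight
cutoff — much lower variance than analogue absorption for the weakly
absorbing media of interest.

Reflectance is scored two ways from the same escape events:

* radially, as a histogram density R(rho) per unit area per photon;
* in the spatial-frequency domain, scoring weight * J0(q rho_exit) per
  escape — the exact azimuthally averaged 2-D Fourier transform of the
  pencil-beam reflectance, free of binning bias.

Each photon runs on its own splitmix64 stream keyed by (seed, photon id),
so tallies are bit-reproducible for a fixed configuration and independent
of batching.

In a non-absorbing half-space every photon returns eventually, but the
return-time distribution is heavy-tailed; photons diving deeper than
``z_kill_lt`` transport mean free paths are terminated and reported in
``killed_fraction``.  The lost weight would re-emerge at radii of order the
kill depth, so it only depresses I(q) at q below roughly 1/z_kill — far
below the sub-diffusive window the simulations target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import PchipInterpolator
from scipy.special import j0

from subdiffuse.phase import TabulatedPhaseFunction

__all__ = ["McConfig", "McResult", "run_mc", "sample_phase_angle",
           "build_inverse_cdf"]


# ---------------------------------------------------------------------------
# Phase-angle sampling
# ---------------------------------------------------------------------------

def build_inverse_cdf(p: TabulatedPhaseFunction, n_table: int = 65536
                      ) -> np.ndarray:
    """Inverse CDF of the scattering angle on a uniform u-grid.

    The CDF is the cumulative trapezoid of 2 pi p(theta) sin(theta) on the
    tabulated grid; its monotone-cubic (PCHIP) inverse is evaluated on
    ``n_table`` uniform points of [0, 1] so the sampling kernel reduces to
    a linear table lookup.
    """
    theta = p.theta
    w = 2.0 * np.pi * p.value * np.sin(theta)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(theta))])
    cdf /= cdf[-1]
    # collapse zero-measure plateaus so the inverse is well defined
    keep = np.concatenate([[True], np.diff(cdf) > 1e-15])
    inv = PchipInterpolator(cdf[keep], theta[keep])
    u = np.linspace(0.0, 1.0, n_table)
    table = inv(u)
    table[0], table[-1] = 0.0, np.pi
    return np.ascontiguousarray(table)


def sample_phase_angle(p: TabulatedPhaseFunction, u) -> np.ndarray | float:
    """Inverse-CDF sample of the scattering angle: theta = F^{-1}(u).

    u = 0 maps to theta = 0 and u -> 1 to theta -> pi; an array of uniform
    variates returns the corresponding angles.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1.0) & (u != 1.0)) or np.any(u > 1.0):
        raise ValueError("u must lie in [0, 1]")
    table = build_inverse_cdf(p)
    idx = u * (table.size - 1)
    lo = np.minimum(idx.astype(np.int64), table.size - 2)
    frac = idx - lo
    out = table[lo] * (1.0 - frac) + table[lo + 1] * frac
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run configuration.

    ``phase`` is the full tabulated phase function of the medium (not the
    mapped SAA form); ``rho_edges`` are radial bin edges in cm and
    ``q_grid`` the spatial frequencies (rad/cm) to score.  ``z_kill_lt``
    is the termination depth in transport mean free paths.
    """

    phase: TabulatedPhaseFunction
    mu_s: float
    mu_a: float
    n_photons: int
    seed: int
    rho_edges: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-3, 300.0, 121))
    q_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 40.0, 80))
    weight_cutoff: float = 1e-4
    roulette_survival: float = 0.1
    z_kill_lt: float = 100.0
    max_events: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 10_000:
            raise ValueError("n_photons must be >= 1e4 for meaningful tallies")
        if self.mu_s <= 0 or self.mu_a < 0:
            raise ValueError("mu_s must be > 0 and mu_a >= 0")
        if not (0.0 < self.weight_cutoff < 1.0):
            raise ValueError("weight_cutoff must lie in (0, 1)")
        edges = np.asarray(self.rho_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("rho_edges must be strictly increasing")
        object.__setattr__(self, "rho_edges", edges)
        object.__setattr__(self, "q_grid",
                           np.asarray(self.q_grid, dtype=float))
        if abs(self.phase.norm() - 1.0) > 1e-3:
            raise ValueError("phase function must be normalized")


@dataclass
class McResult:
    """Tallies of a Monte Carlo run.

    ``R_rho``/``R_rho_err``: reflectance density per unit area per incident
    photon in each radial bin; ``I_q``/``I_q_err``: Fourier-domain
    reflectance; ``total_reflectance``: escaped weight fraction;
    ``killed_fraction``: weight terminated at the kill depth.
    """

    rho_centers: np.ndarray
    R_rho: np.ndarray
    R_rho_err: np.ndarray
    q_grid: np.ndarray
    I_q: np.ndarray
    I_q_err: np.ndarray
    total_reflectance: float
    killed_fraction: float
    n_photons: int
    seed: int
    exit_rho: np.ndarray
    exit_weight: np.ndarray
    exit_n_large: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _splitmix64(state):
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True, fastmath=True)
def _uniform(state):
    state, z = _splitmix64(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _transport(n_photons, seed, mu_t, albedo, inv_cdf, z_kill,
               weight_cutoff, survival, max_events):
    exit_rho = np.empty(n_photons)
    exit_w = np.empty(n_photons)
    status = np.zeros(n_photons, dtype=np.int8)  # 1 escaped, 2 killed, 3 absorbed
    n_large = np.zeros(n_photons, dtype=np.int32)  # events with theta > pi/2
    ntab = inv_cdf.size
    for i in range(n_photons):
        # per-photon stream: decorrelate (seed, photon id) with one mix round
        s0 = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
              + np.uint64(i + 1) * np.uint64(0xD1B54A32D192ED03)) \
            & np.uint64(0xFFFFFFFFFFFFFFFF)
        state, _ = _splitmix64(s0)
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        alive = True
        for _ev in range(max_events):
            state, u1 = _uniform(state)
            step = -np.log(1.0 - u1) / mu_t
            zn = z + uz * step
            if zn <= 0.0:
                # crosses the surface: escape
                s_b = -z / uz
                xe = x + ux * s_b
                ye = y + uy * s_b
                exit_rho[i] = np.sqrt(xe * xe + ye * ye)
                exit_w[i] = w
                status[i] = 1
                alive = False
                break
            x += ux * step
            y += uy * step
            z = zn
            if z > z_kill:
                status[i] = 2
                exit_rho[i] = 0.0
                exit_w[i] = w
                alive = False
                break
            # scattering event: implicit capture
            w *= albedo
            if w < weight_cutoff:
                state, u2 = _uniform(state)
                if u2 < survival:
                    w /= survival
                else:
                    status[i] = 3
                    exit_rho[i] = 0.0
                    exit_w[i] = 0.0
                    alive = False
                    break
            # sample deflection
            state, u3 = _uniform(state)
            fidx = u3 * (ntab - 1)
            j = int(fidx)
            if j > ntab - 2:
                j = ntab - 2
            th = inv_cdf[j] * (1.0 - (fidx - j)) + inv_cdf[j + 1] * (fidx - j)
            if th > 1.5707963267948966:
                n_large[i] += 1
            state, u4 = _uniform(state)
            phi = 2.0 * np.pi * u4
            ct = np.cos(th)
            st = np.sin(th)
            cp = np.cos(phi)
            sp = np.sin(phi)
            if uz > 0.99999 or uz < -0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz > 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                uxn = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uzn = -st * cp * den + uz * ct
                norm = np.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm
        if alive:
            # event budget exhausted: count as killed
            status[i] = 2
            exit_rho[i] = 0.0
            exit_w[i] = w
    return exit_rho, exit_w, status, n_large


def run_mc(config: McConfig) -> McResult:
    """Run the scalar Monte Carlo and tally R(rho), I(q).

    Deterministic for a fixed configuration: identical config and seed give
    bit-identical tallies.
    """
    g = config.phase.g
    l_t = 1.0 / ((1.0 - g) * config.mu_s)
    mu_t = config.mu_s + config.mu_a
    inv_cdf = build_inverse_cdf(config.phase)
    rho, w, status, n_large = _transport(
        config.n_photons, config.seed, mu_t, config.mu_s / mu_t, inv_cdf,
        config.z_kill_lt * l_t, config.weight_cutoff,
        config.roulette_survival, config.max_events)

    esc = status == 1
    n = config.n_photons
    rho_e = rho[esc]
    w_e = w[esc]
    total = float(w_e.sum() / n)
    killed = float(w[status == 2].sum() / n)

    edges = config.rho_edges
    areas = np.pi * np.diff(edges**2)
    wsum, _ = np.histogram(rho_e, bins=edges, weights=w_e)
    w2sum, _ = np.histogram(rho_e, bins=edges, weights=w_e**2)
    R = wsum / (n * areas)
    R_err = np.sqrt(np.maximum(w2sum, 0.0)) / (n * areas)

    q = config.q_grid
    scores = w_e[None, :] * j0(np.outer(q, rho_e))
    I_q = scores.sum(axis=1) / n
    I_err = np.sqrt(np.maximum((scores**2).sum(axis=1) / n - I_q**2, 0.0) / n)

    return McResult(
        rho_centers=0.5 * (edges[:-1] + edges[1:]),
        R_rho=R, R_rho_err=R_err,
        q_grid=q, I_q=I_q, I_q_err=I_err,
        total_reflectance=total, killed_fraction=killed,
        n_photons=n, seed=config.seed,
        exit_rho=rho_e, exit_weight=w_e,
        exit_n_large=n_large[esc],
    )
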