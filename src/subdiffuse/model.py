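"""Analytical reflectance of a uniform semi-infinite forward-peaked medium.

The model describes the angle-integrated reflectance ``I(q)`` of a normally
incident pencil beam (equivalently, the modulation transfer of spatially
modulated illumination at transverse spatial frequency ``q``) as the sum of
three photon populations, classified — as in radiative-transfer practice for
forward-peaked media — by their number of large-angle scattering events:

* **SAA photons** (exactly one large-angle event, dressed by multiple
  small-angle scattering).  With the mapped two-term phase function
  ``p_SAA = (1 - 2 p_b) p_Forward + p_b/(2 pi)``, large-angle redirection
  happens through the isotropic channel at the rate ``mu_iso = 2 p_b mu_s``
  while the forward cascade spreads but does not deplete the beam.  Their
  reflectance is

      I_SAA(q) = L1(q) + mu_b^x Int_0^inf S_eff(q, z) L_b(q z) dz,

  where ``L1`` is the single isotropic-turn return — descent attenuated by
  ``mu_iso + mu_a``, one isotropic scattering, angle-integrated oblique
  ballistic escape — which reduces to the exact one-dimensional integral

      L1(q) = (mu_iso/2) Int_0^1 u du /
              sqrt[(mu_iso + mu_a)^2 (1+u)^2 + q^2 (1 - u^2)],

  and the second term is the backscattering (glory) *excess* of the true
  phase function above the isotropic floor, ``mu_b^x = mu_b -
  mu_s p_b/(2 pi)``, returned quasi-ballistically: ``S_eff`` is the SAA
  spread function of the doubled medium (twice the absorption and
  scattering) in the closed erf form below, and ``L_b`` the Fourier factor
  of the excess lobe's finite angular width ``psi_b`` (Dirac retro-return
  in the ``psi_b -> 0`` limit).  Using the excess rather than mu_b itself
  avoids double counting the floor, which L1 already carries with its
  exact exit geometry.

* **Snake photons** (exactly two large-angle events): ladder order 2 of the
  same isotropic channel — descent, isotropic scattering, one ballistic
  propagator flight at attenuation ``mu_iso + mu_a``, a second scattering,
  angle-integrated escape.

* **Diffuse photons** (direction fully randomized): orders >= 3 of the
  similarity-reduced medium (isotropic scattering at ``mu_s' = (1-g)
  mu_s``), obtained from the exact resolvent (Neumann-series sum) of the
  ladder rather than the diffusion approximation, which degrades for
  ``q l_t >~ 1``; the extrapolated-boundary diffusion result is recovered
  in the q -> 0 limit and is available separately as an oracle.

The default total is the plain sum of the three populations.  A piecewise
``split`` assembly — low-frequency branch ``snake + diffuse + ballistic
plateau``, high-frequency branch ``I_SAA``, joined at the crossover ``q_c``
located by bisection around ``2 pi beta`` with ``beta = mu_iso + mu_a`` —
is also provided; it reproduces the classic two-regime description but
under-covers the single-turn population near the crossover.

The SAA spread function of a collimated beam (Gaussian forward lobe of
width Theta) is the closed erf form

    S(q, z; mu_a, mu_s) = exp[ -(mu_a + mu_s) z
        + mu_s (1 - 2 p_b) sqrt(pi) erf(q Theta z / 2) / (q Theta) ].
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy.special import erf, j0

from subdiffuse.phase import SaaPhaseParams

logger = logging.getLogger(__name__)

__all__ = [
    "OpticalProperties", "BoundaryModel", "ReflectanceProfile",
    "spread_function", "reflectance_saa_q", "reflectance_saa_highq",
    "reflectance_saa_rho_highq", "reflectance_snake_q",
    "reflectance_diffuse_q", "reflectance_total_q", "to_real_space",
    "hankel_transform", "ballistic_plateau", "diffusion_theory_reflectance",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Complete optical-property set of the medium.

    mu_s, mu_a, mu_b in 1/cm; ``saa`` the mapped phase pair (p_b, Theta);
    ``g`` the anisotropy factor of the *exact* phase function of the medium
    (for a Mie medium slightly different from the mapped ``saa.g_saa``; the
    diffuse transport scale l_t is governed by the true g, the sub-diffusive
    physics by p_b and Theta).
    """

    mu_s: float
    mu_a: float
    mu_b: float
    saa: SaaPhaseParams
    g: float
    psi_b: float | None = None

    def __post_init__(self) -> None:
        if self.mu_s <= 0:
            raise ValueError(f"mu_s must be positive, got {self.mu_s}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if self.mu_b <= 0:
            raise ValueError(f"mu_b must be positive, got {self.mu_b}")
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.psi_b is not None and not (0.0 <= self.psi_b <= np.pi / 2):
            raise ValueError("psi_b must lie in [0, pi/2] radians")

    # -- derived scales -----------------------------------------------------
    @property
    def mu_t(self) -> float:
        """Total attenuation mu_s + mu_a."""
        return self.mu_s + self.mu_a

    @property
    def mu_iso(self) -> float:
        """Isotropic-channel scattering rate 2 p_b mu_s."""
        return 2.0 * self.saa.p_b * self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering (1 - g) mu_s."""
        return (1.0 - self.g) * self.mu_s

    @property
    def l_t(self) -> float:
        """Transport mean free path 1/((1-g) mu_s)."""
        return 1.0 / self.mu_s_reduced

    @property
    def l_theta(self) -> float:
        """Sub-diffusive spreading length Theta/mu_s."""
        return self.saa.Theta / self.mu_s

    @property
    def beta(self) -> float:
        """Attenuation of the isotropic channel, mu_iso + mu_a: the inverse
        of the length scale beyond which the profile is phase-function
        independent; the two-regime crossover sits near q_c ~ 2 pi beta."""
        return self.mu_iso + self.mu_a

    @property
    def mu_b_excess(self) -> float:
        """Backscattering excess above the isotropic floor,
        mu_b - mu_s p_b / (2 pi); may be negative for a backward dip."""
        return self.mu_b - self.mu_s * self.saa.p_b / (2.0 * np.pi)


@dataclass(frozen=True)
class BoundaryModel:
    """Extrapolated-boundary model for the diffusion-theory oracle.

    For a matched interface the extrapolation length is z_e = (2/3) l_t
    (A = 1 convention); ``ze_factor`` scales it.  Mismatched interfaces are
    out of scope and rejected.
    """

    matched: bool = True
    ze_factor: float = 2.0 / 3.0

    def z_e(self, props: OpticalProperties) -> float:
        if not self.matched:
            raise NotImplementedError(
                "index-mismatched boundaries are not supported")
        return self.ze_factor * props.l_t


@dataclass
class ReflectanceProfile:
    """Reflectance vs spatial frequency q (rad/cm) or radius rho (cm).

    ``components`` maps {'saa','snake','diffuse','ballistic','total'} to
    per-point values; ``branch`` marks each point 'low' or 'high' relative
    to the crossover q_c; ``delta_weight`` carries the ballistic
    Dirac-delta weight of a real-space profile separately from the grid.
    """

    domain: str
    abscissa: np.ndarray
    components: dict = field(default_factory=dict)
    branch: np.ndarray | None = None
    q_c: float | None = None
    delta_weight: float | None = None
    stderr: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.domain not in ("q", "rho"):
            raise ValueError(f"domain must be 'q' or 'rho', got {self.domain!r}")
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        if np.any(np.diff(self.abscissa) <= 0) or np.any(self.abscissa < 0):
            raise ValueError("abscissa must be non-negative and increasing")

    @property
    def total(self) -> np.ndarray:
        return self.components["total"]


def _require_normal_incidence(s_perp) -> None:
    if s_perp is not None and np.any(np.asarray(s_perp) != 0):
        raise NotImplementedError(
            "oblique incidence/detection (s_perp != 0) is not implemented; "
            "only the normal geometry s_perp = 0 is supported")


# ---------------------------------------------------------------------------
# SAA photons
# ---------------------------------------------------------------------------

def _spread_exponent(q, z, mu_a, mu_s, pb, Theta):
    """log S for a medium (mu_a, mu_s) with the Gaussian SAA phase model."""
    q = np.asarray(q, dtype=float)
    z = np.asarray(z, dtype=float)
    x = q * Theta * z / 2.0
    qT = np.where(np.asarray(q * Theta) > 0, q * Theta, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spread = np.where(x > 1e-8,
                          np.sqrt(np.pi) * erf(x) / qT,
                          z * (1.0 - x * x / 3.0))
    return -(mu_a + mu_s) * z + mu_s * (1.0 - 2.0 * pb) * spread


def spread_function(q, z, props: OpticalProperties, s_perp=None):
    """SAA spread function S(q, z) of a collimated beam at depth z.

    Closed erf form for the Gaussian forward lobe; S(0, z) =
    exp(-(mu_a + 2 p_b mu_s) z) (only absorption and the isotropic channel
    attenuate at zero frequency) and S -> exp(-mu_a z) for mu_s -> 0.
    """
    _require_normal_incidence(s_perp)
    if np.any(np.asarray(z) < 0):
        raise ValueError("depth z must be non-negative")
    return np.exp(_spread_exponent(q, z, props.mu_a, props.mu_s,
                                   props.saa.p_b, props.saa.Theta))


_GL64 = np.polynomial.legendre.leggauss(64)


def _single_turn_return(q, mu_iso: float, mu_a: float):
    """L1(q): single isotropic-turn reflectance, exact closed 1-D integral.

    (mu_iso/2) Int_0^1 u du / sqrt[mu~^2 (1+u)^2 + q^2 (1-u^2)] with
    mu~ = mu_iso + mu_a: descent exp(-mu~ z), isotropic scattering at rate
    mu_iso, angle-integrated oblique ballistic escape with the transverse
    Fourier factor of the exit displacement (the z integral is analytic).
    """
    q = np.asarray(q, dtype=float)
    mu_t_iso = mu_iso + mu_a
    # substitute u = 1 - t^2: resolves the sqrt endpoint structure at u -> 1
    # that dominates for q >> mu (retro-reflected exits)
    x, w = _GL64
    t = 0.5 * (x + 1.0)
    wt = 0.5 * w
    u = 1.0 - t * t
    den = np.sqrt(mu_t_iso**2 * (1.0 + u[None, :])**2
                  + np.atleast_1d(q)[:, None]**2 * (1.0 - u[None, :]**2))
    vals = 0.5 * mu_iso * (((2.0 * t * u)[None, :] / den) @ wt)
    return vals if vals.size > 1 else float(vals[0])


def _saa_depth_nodes(props: OpticalProperties, n_per_seg: int = 16,
                     n_seg: int = 14):
    """Composite Gauss-Legendre nodes on geometrically graded depth segments.

    The glory-excess integrand decays at the rate 2(mu_a + 2 p_b mu_s) at
    worst (q = 0), so the outermost segment edge sits at 30 of those decay
    lengths.
    """
    rate = props.mu_a + 2.0 * props.saa.p_b * props.mu_s
    if rate <= 0:
        raise ValueError(
            "divergent SAA depth integral: mu_a = 0 and p_b = 0 leave no "
            "attenuation at zero spatial frequency")
    z_max = 30.0 / rate
    edges = np.concatenate([[0.0], np.geomspace(z_max / 3000.0, z_max, n_seg)])
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_per_seg)
    zs, ws = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        zs.append(0.5 * (b - a) * gl_x + 0.5 * (b + a))
        ws.append(0.5 * (b - a) * gl_w)
    return np.concatenate(zs), np.concatenate(ws)


def _glory_depth_integral(q, props: OpticalProperties):
    """Int_0^inf S_eff(q, z) L_b(q z) dz: doubled-medium spread function
    times the Fourier factor of the backscattering lobe's exit geometry.

    A lobe of mean-square angular half-width psi_b returns photons from
    depth z over a disc of radius ~ z psi_b, contributing the factor
    exp[-(q z psi_b / 2)^2]; psi_b = None (or 0) is the narrow-lobe
    (Dirac) limit in which the excess returns exactly retro-reflected.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    z, w = _saa_depth_nodes(props)
    s_eff = np.exp(_spread_exponent(q[:, None], z[None, :],
                                    2 * props.mu_a, 2 * props.mu_s,
                                    props.saa.p_b, props.saa.Theta))
    if props.psi_b:
        s_eff = s_eff * np.exp(-(q[:, None] * z[None, :] * props.psi_b / 2.0) ** 2)
    return s_eff @ w


def reflectance_saa_q(q, props: OpticalProperties, s_perp=None):
    """Reflectance of the SAA photons (one large-angle event), I_SAA(q).

    Sum of the single isotropic-turn return L1(q) (exact exit geometry) and
    the backscattering-excess term mu_b^x Int S_eff dz (retro-reflected
    glory excess blurred by the forward cascades of both legs).
    """
    _require_normal_incidence(s_perp)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = (np.atleast_1d(_single_turn_return(q, props.mu_iso, props.mu_a))
           + props.mu_b_excess * _glory_depth_integral(q, props))
    return out if out.size > 1 else float(out[0])


def ballistic_plateau(props: OpticalProperties) -> float:
    """mu_b^x / (2 mu_t): the quasi-ballistic glory plateau of I(q).

    Only the backscattering excess above the isotropic floor returns
    delta-like; the floor's return (L1) decays at large q.
    """
    return props.mu_b_excess / (2.0 * props.mu_t)


def reflectance_saa_highq(q, props: OpticalProperties):
    """High-spatial-frequency form of the SAA reflectance.

    L1(q) (already closed-form) plus the q l_Theta >> 1 limit of the glory
    term, (mu_b^x / 2 mu_t) e^A with A = 2 sqrt(pi)(1 - 2 p_b)/(q l_Theta);
    the plateau mu_b^x/(2 mu_t) is the ballistic contribution.  Invalid at
    q = 0.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("the high-q limit form is invalid at q = 0")
    pars = props.saa
    A = 2.0 * np.sqrt(np.pi) * (1.0 - 2.0 * pars.p_b) / (q * props.l_theta)
    out = (np.atleast_1d(_single_turn_return(q, props.mu_iso, props.mu_a))
           + props.mu_b_excess / (2.0 * props.mu_t) * np.exp(A))
    return out if out.size > 1 else float(out[0])


def reflectance_saa_rho_highq(rho, props: OpticalProperties,
                              q_max_factor: float = 400.0, n_q: int = 20000):
    """Real-space close-separation SAA reflectance.

    Returns ``(continuous, delta_weight)``: the continuous profile on the
    ``rho`` grid — the inverse zeroth-order Hankel transform of the SAA
    reflectance minus its quasi-ballistic plateau, using the closed
    high-frequency form above q = 20/l_Theta (where it is accurate to 1%)
    and the full expression below it (the limit form diverges as
    exp(A) for q l_Theta << 1) — and the Dirac-delta ballistic weight
    mu_b^x/(2 mu_t) at rho = 0, reported separately and never mixed into
    the grid.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    q_switch = 20.0 / props.l_theta
    q = np.geomspace(1e-3 / props.l_theta, q_max_factor / props.l_theta, n_q)
    f = np.empty(q.size)
    lo = q < q_switch
    f[lo] = reflectance_saa_q(q[lo], props)
    f[~lo] = reflectance_saa_highq(q[~lo], props)
    f -= ballistic_plateau(props)
    cont = hankel_transform(q, f, rho, direction="inverse")
    return cont, ballistic_plateau(props)


# ---------------------------------------------------------------------------
# Transport ladder (snake and diffuse photons)
# ---------------------------------------------------------------------------

def _escape_ballistic(q, z, mu_red):
    """Angle-integrated ballistic escape from depth z with transverse phase.

    (1/2) Int_0^1 exp(-mu z/u) J0(q z sqrt(1-u^2)/u) du: an isotropically
    emitted photon at depth z leaves without another scattering event, its
    oblique exit displacement carrying the transverse Fourier factor.
    """
    x, w = _GL64
    u = 0.5 * (x + 1.0)
    wu = 0.5 * w
    z = np.atleast_1d(np.asarray(z, dtype=float))
    with np.errstate(over="ignore", divide="ignore"):
        att = np.exp(-mu_red * z[:, None] / u[None, :])
    bes = j0(q * z[:, None] * np.sqrt(1.0 - u**2)[None, :] / u[None, :])
    return 0.5 * ((att * bes) @ wu)


def _ghat(kappa: float, w_abs: np.ndarray, n_tau: int = 400) -> np.ndarray:
    """Transverse-Fourier ballistic propagator between planes (reduced units).

    g(kappa, w) = (1/2) Int_{w}^inf J0(kappa sqrt(r^2 - w^2)) e^{-r} dr / r:
    the 2-D transverse Fourier transform of the infinite-medium propagator
    e^{-r}/(4 pi r^2) between planes at depth offset w, lengths in units of
    the attenuation length (between two interior points the straight
    segment never leaves the half-space, so the infinite-medium form is
    exact).  Logarithmically singular as w -> 0; vectorized over w with the
    substitution r = w + tau on a log-graded tau grid.
    """
    w = np.atleast_1d(np.asarray(w_abs, dtype=float))[:, None]
    tau = np.geomspace(1e-9, 80.0, n_tau)[None, :]
    r = w + tau
    u = np.sqrt(tau * (tau + 2.0 * w))
    integ = j0(kappa * u) * np.exp(-r) / r
    return 0.5 * np.trapezoid(integ, tau, axis=1)


# Shared dimensionless depth grid for the transport ladder: quadratically
# graded cells on [0, 40] attenuation lengths.
_NZ = 120
_Z_EDGES = 40.0 * np.linspace(0.0, 1.0, _NZ + 1) ** 2
_Z_MID = 0.5 * (_Z_EDGES[:-1] + _Z_EDGES[1:])
_Z_DW = np.diff(_Z_EDGES)

_KAPPA_GRID = np.concatenate([[0.0], np.geomspace(1e-3, 500.0, 72)])
_KERNEL_TABLE: list[np.ndarray] | None = None


def _kernel_matrix(kappa: float) -> np.ndarray:
    """Cell-averaged plane-to-plane kernel on the shared grid.

    K_ij dz_j = Int over cell j of g(kappa, |z_i - z'|) dz', evaluated
    exactly in z' through the cumulative kernel G(kappa, w) = Int_0^w g dt
    (tabulated densely in log w and interpolated), which integrates the
    w -> 0 log singularity without bias; midpoint sampling of the singular
    kernel would misplace ~10% of the multiply-scattered weight in
    conservative media.
    """
    wg = np.concatenate([[0.0], np.geomspace(1e-7, 2.05 * _Z_EDGES[-1], 900)])
    gvals = np.concatenate([[0.0], _ghat(kappa, wg[1:])])
    cum = np.concatenate([[0.0],
                          np.cumsum(0.5 * (gvals[1:] + gvals[:-1])
                                    * np.diff(wg))])

    def G(w):
        return np.interp(np.abs(w), wg, cum)

    n = _Z_MID.size
    zi = _Z_MID[:, None]
    lo = _Z_EDGES[:-1][None, :]
    hi = _Z_EDGES[1:][None, :]
    inside = (zi >= lo) & (zi < hi)
    cell_int = np.where(inside,
                        G(zi - lo) + G(hi - zi),
                        np.abs(G(np.abs(zi - hi)) - G(np.abs(zi - lo))))
    return cell_int / _Z_DW[None, :]


def _kernel_table() -> list[np.ndarray]:
    global _KERNEL_TABLE
    if _KERNEL_TABLE is None:
        _KERNEL_TABLE = [_kernel_matrix(k) for k in _KAPPA_GRID]
    return _KERNEL_TABLE


def _kernel_interp(kappa: float) -> np.ndarray:
    """K(kappa) by linear interpolation between tabulated kappa nodes."""
    tab = _kernel_table()
    kg = _KAPPA_GRID
    if kappa <= 0:
        return tab[0]
    if kappa >= kg[-1]:
        return None  # caller treats the kernel as negligible
    j = int(np.searchsorted(kg, kappa))
    k0, k1 = kg[j - 1], kg[j]
    t = (kappa - k0) / (k1 - k0)
    return (1.0 - t) * tab[j - 1] + t * tab[j]


class _TransportLadder:
    """Order-by-order scattering bookkeeping for an isotropically scattering
    half-space, on the shared dimensionless grid.

    Works in units of the attenuation ``mu_tilde`` with single-scattering
    albedo ``albedo``: successive scattering source densities
    Q_1 = a exp(-z), Q_{n+1} = a K Q_n, the resolvent sum over all orders,
    and angle-integrated ballistic escape scores.  The kernel depends only
    on kappa = q/mu_tilde and is shared across media via a module table.
    """

    def __init__(self, mu_tilde: float, albedo: float):
        self.mu_tilde = mu_tilde
        self.albedo = albedo
        self.z = _Z_MID
        self.dz = _Z_DW
        self.q1 = (albedo / self.dz
                   * (np.exp(-_Z_EDGES[:-1]) - np.exp(-_Z_EDGES[1:])))

    def escape(self, q: float) -> np.ndarray:
        return _escape_ballistic(float(q) / self.mu_tilde, self.z, 1.0)

    def order_escapes(self, q: float, n_orders: int = 3) -> list[float]:
        """Escaping reflectance of ladder orders 1..n_orders at frequency q."""
        kappa = float(q) / self.mu_tilde
        K = _kernel_interp(kappa)
        esc = self.escape(q)
        out = []
        src = self.q1
        for _ in range(n_orders):
            out.append(float(np.sum(src * self.dz * esc)))
            if K is None:
                src = np.zeros_like(src)
            else:
                src = self.albedo * (K @ (src * self.dz))
        return out

    def total_escape(self, q: float) -> float:
        """All-orders reflectance via the resolvent (I - a K)^{-1}."""
        kappa = float(q) / self.mu_tilde
        K = _kernel_interp(kappa)
        esc = self.escape(q)
        if K is None:
            return float(np.sum(self.q1 * self.dz * esc))
        A = self.albedo * K * self.dz[None, :]
        phi = np.linalg.solve(np.eye(self.dz.size) - A, self.q1)
        return float(np.sum(phi * self.dz * esc))

    def orders_and_total(self, q: float, n_orders: int = 2
                         ) -> tuple[list[float], float]:
        """Per-order escapes and the all-orders total with one kernel pass."""
        kappa = float(q) / self.mu_tilde
        K = _kernel_interp(kappa)
        esc = self.escape(q)
        orders = []
        src = self.q1
        if K is None:
            val = float(np.sum(src * self.dz * esc))
            return [val] + [0.0] * (n_orders - 1), val
        for _ in range(n_orders):
            orders.append(float(np.sum(src * self.dz * esc)))
            src = self.albedo * (K @ (src * self.dz))
        A = self.albedo * K * self.dz[None, :]
        phi = np.linalg.solve(np.eye(self.dz.size) - A, self.q1)
        total = float(np.sum(phi * self.dz * esc))
        return orders, total


def _iso_ladder(props: OpticalProperties) -> _TransportLadder:
    return _TransportLadder(props.beta, props.mu_iso / props.beta)


def _reduced_ladder(props: OpticalProperties) -> _TransportLadder:
    mu = props.mu_s_reduced + props.mu_a
    return _TransportLadder(mu, props.mu_s_reduced / mu)


def reflectance_snake_q(q, props: OpticalProperties,
                        boundary: BoundaryModel | None = None):
    """Reflectance of snake photons: exactly two large-angle events.

    Ladder order 2 of the isotropic channel: descent at mu_iso + mu_a, one
    isotropic scattering, a ballistic propagator flight, a second
    scattering, angle-integrated escape.  The boundary model does not enter
    (all flights are ballistic); absorption only ever reduces the value.
    """
    lad = _iso_ladder(props)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.array([lad.order_escapes(qv, 2)[1] for qv in q])
    return out if out.size > 1 else float(out[0])


def reflectance_diffuse_q(q, props: OpticalProperties,
                          boundary: BoundaryModel | None = None):
    """Reflectance of diffuse photons: three or more transport-scale events.

    Orders >= 3 of the similarity-reduced medium ((1-g) mu_s isotropic
    scattering), computed exactly as resolvent total minus orders 1 and 2.
    At q -> 0 and weak absorption this approaches the extrapolated-boundary
    diffusion-theory reflectance (see
    :func:`diffusion_theory_reflectance`), while remaining accurate at
    q l_t >~ 1 where the diffusion approximation fails.
    """
    lad = _reduced_ladder(props)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty(q.size)
    for i, qv in enumerate(q):
        orders, total = lad.orders_and_total(qv, 2)
        out[i] = max(total - orders[0] - orders[1], 0.0)
    return out if out.size > 1 else float(out[0])


def diffusion_theory_reflectance(q, props: OpticalProperties,
                                 boundary: BoundaryModel | None = None):
    """Extrapolated-boundary diffusion reflectance (oracle / q -> 0 limit).

    Fick flux at the surface for the first-scatter source
    mu_s' exp(-(mu_s' + mu_a) z) with the image-source Green's function:
    I(q) = (1 + e^{-2 kappa z_e}) mu_s' / (2 (mu_s' + mu_a + kappa)),
    kappa = sqrt(3 mu_s' mu_a + q^2).
    """
    boundary = boundary or BoundaryModel()
    z_e = boundary.z_e(props)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    mu_sr = props.mu_s_reduced
    kappa = np.sqrt(3.0 * mu_sr * props.mu_a + q * q)
    out = (1.0 + np.exp(-2.0 * kappa * z_e)) * mu_sr \
        / (2.0 * (mu_sr + props.mu_a + kappa))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Total reflectance
# ---------------------------------------------------------------------------

def reflectance_total_q(q, props: OpticalProperties,
                        boundary: BoundaryModel | None = None,
                        assembly: str = "sum",
                        locate_crossover: bool | None = None) -> ReflectanceProfile:
    """Total reflectance profile over a q grid spanning both regimes.

    ``assembly='sum'`` (default): I_SAA + I_snake + I_diffuse at every
    frequency — the three populations are disjoint photon classes, so their
    contributions add.  ``assembly='split'``: the classic two-branch form,
    low branch = snake + diffuse + ballistic plateau, high branch = I_SAA,
    switched at the crossover q_c.  q_c (intersection of the two branches,
    located by bisection in a bracket around 2 pi beta, with a logged
    fallback to 2 pi beta if they do not intersect there) is always
    computed for the split assembly; for the sum it is located only when
    ``locate_crossover`` is set (it is diagnostic there).
    """
    if assembly not in ("sum", "split"):
        raise ValueError("assembly must be 'sum' or 'split'")
    boundary = boundary or BoundaryModel()
    q = np.atleast_1d(np.asarray(q, dtype=float))

    saa = np.atleast_1d(reflectance_saa_q(q, props))
    snake = np.atleast_1d(reflectance_snake_q(q, props, boundary))
    diffuse = np.atleast_1d(reflectance_diffuse_q(q, props, boundary))
    bal = ballistic_plateau(props)

    if locate_crossover is None:
        locate_crossover = assembly == "split"
    q_c = _find_crossover(props, boundary) if locate_crossover else None
    branch = None if q_c is None else np.where(q <= q_c, "low", "high")
    if assembly == "sum":
        total = saa + snake + diffuse
    else:
        total = np.where(q <= q_c, bal + snake + diffuse, saa)
    return ReflectanceProfile(
        domain="q", abscissa=q,
        components={"saa": saa, "snake": snake, "diffuse": diffuse,
                    "ballistic": np.full(q.shape, bal), "total": total},
        branch=branch, q_c=q_c,
        meta={"mu_s": props.mu_s, "mu_a": props.mu_a, "mu_b": props.mu_b,
              "g": props.g, "p_b": props.saa.p_b, "Theta": props.saa.Theta,
              "assembly": assembly},
    )


def _find_crossover(props, boundary) -> float:
    from scipy.optimize import brentq

    def diff(qv: float) -> float:
        low = (reflectance_snake_q(qv, props, boundary)
               + reflectance_diffuse_q(qv, props, boundary)
               + max(ballistic_plateau(props), 1e-300))
        high = reflectance_saa_q(qv, props)
        return float(np.log(low) - np.log(high))

    q_guess = 2.0 * np.pi * props.beta
    lo, hi = q_guess / 16.0, q_guess * 16.0
    try:
        if diff(lo) * diff(hi) > 0:
            raise ValueError("no sign change")
        return float(brentq(diff, lo, hi, xtol=1e-10, rtol=1e-9))
    except ValueError:
        logger.warning(
            "total-reflectance branches do not intersect in [%g, %g]; "
            "falling back to q_c = 2 pi beta = %g", lo, hi, q_guess)
        return float(q_guess)


# ---------------------------------------------------------------------------
# Hankel transforms (q <-> rho)
# ---------------------------------------------------------------------------

def hankel_transform(x, f, y, direction: str = "inverse"):
    """Zeroth-order Hankel transform by high-resolution trapezoid quadrature.

    inverse: R(y) = (1/2 pi) Int f(x) J0(x y) x dx   (q -> rho)
    forward: I(y) = 2 pi Int f(x) J0(x y) x dx       (rho -> q)
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    kern = j0(np.outer(y, x)) * (f * x)[None, :]
    vals = np.trapezoid(kern, x, axis=1)
    if direction == "inverse":
        vals = vals / (2.0 * np.pi)
    elif direction == "forward":
        vals = vals * (2.0 * np.pi)
    else:
        raise ValueError("direction must be 'forward' or 'inverse'")
    return vals if vals.size > 1 else float(vals[0])


def to_real_space(profile: ReflectanceProfile, rho, tail_tol: float = 1e-2
                  ) -> ReflectanceProfile:
    """Inverse 2-D Fourier (zeroth-order Hankel) transform of an I(q) profile.

    The quasi-ballistic glory plateau transforms to a Dirac delta at
    rho = 0 and is carried in ``delta_weight``; the remainder is transformed
    numerically.  The q grid must extend far enough that the plateau-
    subtracted integrand has decayed: the estimated truncation error (the
    last octave's contribution relative to the peak) must stay below
    ``tail_tol``, else a ValueError reports it.
    """
    if profile.domain != "q":
        raise ValueError("to_real_space expects a spatial-frequency profile")
    q = profile.abscissa
    total = np.asarray(profile.components["total"], dtype=float)
    plateau = (float(np.asarray(profile.components["ballistic"])[-1])
               if "ballistic" in profile.components else 0.0)
    f = total - plateau
    rho = np.asarray(rho, dtype=float)
    # cosine taper over the last quarter of the grid suppresses the
    # truncation ringing of slowly decaying integrands; the difference
    # between the raw and tapered transforms estimates that ringing
    taper = np.ones(q.size)
    edge = q >= 0.75 * q[-1]
    taper[edge] = 0.5 * (1 + np.cos(np.pi * (q[edge] - 0.75 * q[-1])
                                    / (0.25 * q[-1])))
    raw = hankel_transform(q, f, rho, direction="inverse")
    vals = hankel_transform(q, f * taper, rho, direction="inverse")
    scale = float(np.max(np.abs(vals)))
    ring_rel = (float(np.max(np.abs(raw - vals))) / scale
                if scale > 0 else 0.0)
    if ring_rel > tail_tol:
        raise ValueError(
            f"q grid truncated too early for a faithful transform: "
            f"estimated truncation ringing {ring_rel:.2e} exceeds "
            f"{tail_tol:.0e}; extend q_max (>= 50 mu_t is a practical "
            "minimum)")
    return ReflectanceProfile(
        domain="rho", abscissa=rho,
        components={"total": np.atleast_1d(vals)},
        delta_weight=plateau,
        meta=dict(profile.meta, from_q=True),
    )
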