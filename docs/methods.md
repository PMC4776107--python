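# Methods

`subdiffuse` models the angle-integrated reflectance of a uniform
semi-infinite, forward-peaked scattering medium probed by a normally
incident pencil beam, in the spatial-frequency domain `I(q)` (the
modulation transfer of spatially modulated illumination) and in real space
`R(rho)`.  The medium is described by the scattering, absorption and
backscattering coefficients `mu_s`, `mu_a`, `mu_b` (1/cm), the anisotropy
factor `g`, and a two-parameter reduction of the single-scattering phase
function: the isotropic-background weight `p_b` and the angular width
`Theta`.  The refractive index at the interface is matched, photons are
scalar, and the geometry is strictly normal incidence and detection;
oblique geometries, layered media and polarization are out of scope and
rejected loudly by the API.

## The SAA phase-function mapping

An arbitrary azimuthally symmetric phase function `p(theta)` (normalized
so that `2 pi Int p sin dtheta = 1`) is reduced to

```
p_SAA(theta) = (1 - 2 p_b) p_Forward(theta) + p_b / (2 pi),
```

with the two parameters defined by integral functionals of `p`:

* `p_b = 2 pi Int_{pi/2}^pi p sin dtheta` — the backward-hemisphere
  scattering probability, reproduced exactly by the isotropic term;
* `Theta^2 = 2 pi Int_0^pi theta^2 p sin dtheta` — the full mean-square
  scattering angle.  This choice fixes the angular diffusion rate
  `mu_s Theta^2` of the reduced medium to that of the true medium, which
  is the quantity that governs multiple-small-angle beam spreading.  The
  spreading length is `l_Theta = Theta / mu_s`.

The model is then used through the planar Fourier-Bessel representation
`chi(v) = (1 - 2 p_b) exp(-v^2 Theta^2 / 4)`, whose integer-order values
give the closed-form moments `<P_n> = (1 - 2 p_b) exp(-n^2 Theta^2/4)`
(n >= 1); in particular the anisotropy of the mapped form is
`g_SAA = (1 - 2 p_b) exp(-Theta^2/4)`, which for the reference media
tracks the exact Mie `g` to about 1% but is deliberately not identical to
it — the mapping trades first-moment fidelity for angular-diffusion
fidelity.  Consequently:

* `synthesize_saa` tabulates a theta-domain Gaussian lobe whose width `w`
  is chosen so the synthesized function carries exactly the mapped second
  moment; the mapping is then an exact involution
  (`map(synthesize(p_b, Theta)) == (p_b, Theta)`), valid for pairs with
  `Theta^2 > 2 p_b (pi^2 - 4)/2` (below that the isotropic term alone
  exceeds the requested variance and no forward-peaked decomposition
  exists);
* the closed-form moments agree with spherical quadrature of the
  synthesized tabulation only in the small-angle limit (the isotropic
  term contributes to `Theta^2` but not to Legendre moments of order
  >= 1); the moment API is therefore tested against its defining planar
  quadrature.

Two auxiliary single-scattering quantities complete the parameter set:
`mu_b = mu_s p(pi)` evaluated from the analytic backscatter series, and
the backscattering-lobe width `psi_b` — the half-width at half-excess of
`p` above the isotropic floor `p_b/(2 pi)` around `theta = pi`, converted
to a Gaussian 1/e half-width.  For 1.50 um polystyrene spheres at
0.515 um the backward excess is a narrow glory (`psi_b ~ 0.03 rad`); for
0.49 um spheres it is a broad backward rise (`psi_b ~ 0.5 rad`).

## Mie inputs

Mie coefficients follow the standard downward-recursion logarithmic
derivative / upward Riccati-Bessel scheme; the phase function is the
unpolarized `(|S1|^2 + |S2|^2)/2` normalized by the series sum, tabulated
on a grid densified near both poles (2048 points by default), with the
`theta = pi` value taken from the analytic backscatter sum rather than
interpolation.  Absorption inside the spheres enters through `Im(n)`;
`tune_absorption` root-finds `Im(n)` for a requested `mu_a/mu_s` (the
ratio `Q_abs/Q_sca` at fixed number density).

The polystyrene and water refractive indices are the Sultanova (2003) and
Daimon–Masumura (2007) dispersion fits (1.6008 and 1.3361 at 0.515 um),
overridable per suspension.  Third-decimal quantities — `g`, the mapped
pair, and especially `p(pi)`, which rides the glory ripple — move within
literature uncertainty of these indices: across the plausible index box
`g(d=1.5)` spans ~0.910–0.925 and `p(pi)` spans ~0.0029–0.0037/cm, and a
0.7% diameter change moves `p(pi)` by +-40%.  The package reports what
the documented defaults give and does not tune indices per quantity.

## The reflectance model

Escaping photons are classified by their number of large-angle scattering
events, and each class is modelled separately (the classification was
verified directly by tagging >90-degree deflections in the Monte Carlo):

**SAA photons** — exactly one large-angle event.  In the mapped medium,
large-angle redirection happens through the isotropic channel at the rate
`mu_iso = 2 p_b mu_s`, while the forward cascade spreads the beam without
depleting it; the legs of a one-turn path are therefore attenuated by
`mu_tilde = mu_iso + mu_a` only.  The reflectance is

```
I_SAA(q) = L1(q) + mu_b^x Int_0^inf S_eff(q, z) exp[-(q z psi_b / 2)^2] dz
L1(q)    = (mu_iso / 2) Int_0^1 u du / sqrt[mu_tilde^2 (1+u)^2 + q^2 (1-u^2)]
```

`L1` is the single isotropic-turn return — descent `exp(-mu_tilde z)`,
one isotropic scattering, angle-integrated oblique ballistic escape, with
the exit displacement carrying the transverse Fourier factor; the depth
integral is analytic and the remaining `u`-integral is evaluated by
64-point Gauss–Legendre quadrature.  The second term is the
quasi-ballistic return of the backscattering *excess*
`mu_b^x = mu_b - mu_s p_b/(2 pi)` (the glory above the isotropic floor,
which `L1` already carries): `S_eff` is the spread function of the
doubled medium (twice the absorption and scattering) in the closed erf
form

```
S(q, z; mu_a, mu_s) = exp[-(mu_a + mu_s) z
    + mu_s (1 - 2 p_b) sqrt(pi) erf(q Theta z / 2) / (q Theta)],
```

and the Gaussian factor in `q z psi_b` is the Fourier transform of the
excess lobe's exit geometry (`psi_b -> 0` recovers a Dirac retro-return).
Using the excess rather than `mu_b` itself, and giving it a finite lobe
width, are both essential: with the full `mu_b` as a delta return the
model overshoots the Monte Carlo by a factor ~4 at `q ~ 40 mu_s`, because
no true delta-function return exists for a medium with a smooth backward
lobe.  The depth integral uses composite Gauss–Legendre quadrature on
geometrically graded segments out to 30 decay lengths of the slowest mode
`mu_a + 2 p_b mu_s` (which is also why `mu_a = 0` with `p_b = 0` is
rejected as divergent).  The high-frequency closed form replaces the
glory integral by its limit `(mu_b^x / 2 mu_t) exp[A]`,
`A = 2 sqrt(pi)(1 - 2 p_b)/(q l_Theta)`; it converges onto the full
expression within 1% for `q >= 20/l_Theta`.

**Snake photons** — exactly two large-angle events: ladder order 2 of the
same isotropic channel, with the inter-scattering flight described by the
transverse Fourier transform of the infinite-medium ballistic propagator
`exp(-mu_tilde r)/(4 pi r^2)` (exact between interior points of a
half-space).

**Diffuse photons** — three or more transport-scale events: orders >= 3
of the similarity-reduced medium (isotropic scattering at
`mu_s' = (1-g) mu_s`), computed *exactly* by the resolvent
`(I - a K)^{-1}` of the same ladder rather than by the diffusion
approximation.  The diffusion Green's function with an extrapolated
boundary (`z_e = (2/3) l_t`, matched-index convention) is kept as the
`q -> 0` oracle the term reduces to; as an approximation for the term
itself it fails for `q l_t >~ 1` (errors up to 2x were measured against
Monte Carlo during development).

The ladder discretizes depth on 120 quadratically graded cells spanning
40 attenuation lengths; the plane-to-plane kernel
`g(kappa, w) = (1/2) Int_w^inf J0(kappa sqrt(r^2-w^2)) e^{-r} dr/r`
(logarithmically singular at `w -> 0`, cell-averaged on the diagonal)
depends only on `kappa = q/mu_tilde` and is tabulated once per process on
a 73-node `kappa` grid and linearly interpolated, which makes the model
fully `mu_s`-scale invariant and fast enough for fitting (~80 ms per
65-point profile after the one-time ~15 s table build).  At `q = 0`,
`mu_a = 0` the three populations sum to unity within the grid resolution
(flux conservation, verified to 2%).

**Total.**  The default total is the plain sum of the three populations
(they are disjoint photon classes).  The classic two-branch piecewise
assembly — low-frequency branch `snake + diffuse + mu_b^x/(2 mu_t)`,
high-frequency branch `I_SAA`, joined where the branches intersect
(bisection bracketed around `q_c ~ 2 pi beta`, `beta = mu_iso + mu_a`,
with a logged fallback to `2 pi beta`) — is available as
`assembly='split'`, but it under-covers the one-turn population below the
crossover by ~30% and is not the default.  Known residual of the sum: the
similarity picture and the isotropic-channel picture double-cover part of
the intermediate regime, producing a localized +10–17% overshoot around
`q ~ (0.2-0.5) mu_s` for the reference media; elsewhere agreement with
Monte Carlo is within ~±5%.

**Real space.**  `to_real_space` applies a zeroth-order Hankel transform
by high-resolution trapezoid quadrature, carrying the quasi-ballistic
plateau separately as a Dirac-delta weight at `rho = 0`; the last-octave
contribution of the `q` grid serves as the truncation-error estimate and
transforms with an estimated error above 0.1% are refused (in practice
the grid should reach `q_max >= 50 mu_t`).

## Monte Carlo

The validation oracle is a scalar Monte Carlo in the half-space: implicit
capture (weight times `mu_s/mu_t` per event) with Russian roulette below
1e-4 (survival 0.1), scattering angles by inverse-CDF lookup (cumulative
trapezoid of `2 pi p sin theta`, PCHIP inverse resampled to a 65536-entry
uniform table), matched boundary, and per-photon splitmix64 streams keyed
by (seed, photon id) so tallies are bit-reproducible.  Reflectance is
scored radially (histogram density) and directly in the Fourier domain as
`weight * J0(q rho_exit)` per escape, which is exact for the azimuthally
symmetric geometry and free of binning bias.  Escaping photons also carry
their count of >90-degree deflections, which is what enabled the
class-by-class validation of the model above.

In a non-absorbing half-space the return-time distribution is heavy
tailed; photons diving beyond 100 transport mean free paths are
terminated and reported in `killed_fraction` (~1.7% for the g ~ 0.92
reference medium).  Since `mu_a = 0` implies no roulette losses, escaped
plus killed weight equals unity exactly; the killed weight would have
re-emerged at radii of order the kill depth and only depresses `I(q)`
for `q` below roughly the inverse kill depth, far under the comparison
window.

## The comparison window and merit

The model-vs-Monte-Carlo merit is
`R^2 = 1 - sum (ln I_model - ln I_MC)^2 / sum (ln I_MC - <ln I_MC>)^2`,
evaluated on the canonical window `0 < q <= 10 mu_s` (`merit_q_grid`: 20
points to `q = mu_s`, 45 above).  The upper edge is where the
reflectance sinks into the quasi-ballistic backscattering tail, whose
shape reflects the detailed backward lobe rather than the SAA parameter
set; beyond it the comparison would measure the lobe model, not the
transport model.

## Inversion

Stage 1 fits the sub-diffusive window (`q >= max(2 pi beta, mu_s/4)`) of
a `mu_s`-scaled profile for `(mu_b, mu_a, Theta)/mu_s` with `p_b` held
fixed and `g` tied to the pair by `g = (1 - 2 p_b) exp(-Theta^2/4)`; the
objective is least squares on log reflectance, optionally
inverse-variance weighted by the Monte Carlo standard errors, minimized
by bounded trust-region least squares from six starts spread across the
shallow `mu_a`–`Theta` valley.  Stage 2 frees `{mu_s, mu_a, p_b, Theta}`
against the full profile, holding `mu_b/mu_s` at its stage-1 value and
keeping the `g` tie (the constraint the paper-style two-stage procedure
relies on); `mu_s` is identified by the physical scaling of the `q`
axis.  Multi-start jitter is seedable; parameters pinned at bounds are
flagged.  On noise-free model-generated profiles both stages recover the
generating parameters to machine precision; with 1% log-normal noise the
median errors of `Theta` and `mu_s` stay below 5%.

### What the sub-diffusive reflectance does and does not encode

A controlled experiment (two synthesized SAA media differing only in
`Theta`, 0.45 vs 0.55 at fixed `p_b`) shows their `I(q)` are identical
within Monte Carlo noise over the whole sub-diffusive range: in scalar
transport the rise of `I(q)` from the quasi-ballistic level is governed
by the isotropic-channel geometry (`2 p_b mu_s`), not by the
forward-lobe width.  `Theta` is recovered from reflectance only through
the `g`–`Theta` tie acting on the diffusive tail near the crossover.  On
Monte Carlo profiles of the reference media the stage-1 `Theta` errors
are accordingly a few percent when absorption anchors the
`mu_a`–`Theta` valley (4–6%) but can reach ~20% for the non-absorbing
large-sphere case, where the valley is open and the intermediate-regime
model residual leaks into the estimate.  A forward-lobe width recovered
to a few percent from sub-diffusive intensity alone is, in our scalar
reconstruction, not achievable; coherent (field) transport effects or a
model that attributes the geometric rise to `Theta` would be needed to
claim it.

## Problem sizes

Default study conditions reproduce the reference experiments: `mu_s = 1`
/cm, 1e6 photons for headline validation runs (the acceptance script),
1e5–4e5 photons for the test suite, phase functions tabulated on 4096
angles for mapping work.  The merit and recovery statistics change by
less than the Monte Carlo scatter between these sizes.

## Known limitations

* The synthetic media are monodisperse spheres in a non-absorbing host;
  polydispersity, coated or non-spherical scatterers, index-mismatched
  boundaries, layered media, polarization and time gating are out of
  scope.
* The intermediate-regime double-coverage bump (+10–17% at
  `q ~ (0.2–0.5) mu_s`) is the dominant model systematic; it also biases
  stage-1 estimates for weakly absorbing media.
* `p(pi)` (hence `mu_b`) is hypersensitive to the sphere diameter and
  index choice (the glory ripple); absolute `mu_b` values are only as
  good as those inputs.
* The Monte Carlo kill depth trades a ~1–2% reflectance deficit
  (reported, not hidden) for bounded run time in conservative media.
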