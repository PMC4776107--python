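"""The analytical reflectance model in both domains.

Evaluates the SAA + snake + diffuse reflectance of the absorbing
d = 1.50 um reference medium on a spatial-frequency grid, locates the
two-regime crossover q_c, and transforms the profile to real space.  The
component columns show the handover: diffuse photons dominate at low q
(large separations), the single-large-turn SAA population everywhere above
the crossover.
"""

import numpy as np

import subdiffuse as sd

susp = sd.tune_absorption(sd.polystyrene_in_water(1.50), 0.0130)
phase = sd.mie_phase_function(susp, 4096)
bulk = sd.mie_bulk_properties(susp)
pars = sd.map_phase_function(phase)
props = sd.OpticalProperties(
    mu_s=1.0, mu_a=bulk["mu_a"], mu_b=bulk["mu_b"], saa=pars, g=bulk["g"],
    psi_b=sd.backward_lobe_width(phase, pars.p_b))

q = np.concatenate([np.geomspace(0.02, 1.0, 300),
                    np.linspace(1.025, 300.0, 9000)])
prof = sd.reflectance_total_q(q, props, locate_crossover=True)
print(f"crossover q_c = {prof.q_c:.3f} rad/cm "
      f"(2 pi beta = {2*np.pi*props.beta:.3f})")
print(f"\n{'q':>8}{'I_saa':>12}{'I_snake':>12}{'I_diffuse':>12}{'total':>12}")
for i in range(0, 9300, 1320):
    print(f"{q[i]:8.3f}{prof.components['saa'][i]:12.3e}"
          f"{prof.components['snake'][i]:12.3e}"
          f"{prof.components['diffuse'][i]:12.3e}{prof.total[i]:12.3e}")

# the q grid must extend well past 1/rho_min for a converged transform
rho = np.geomspace(1.5, 20.0, 8)
rprof = sd.to_real_space(prof, rho)
print(f"\nreal space (ballistic delta weight at rho = 0: "
      f"{rprof.delta_weight:.2e} carried separately)")
print(f"{'rho (cm)':>10}{'R(rho) (1/cm^2)':>18}")
for r, v in zip(rho, rprof.total):
    print(f"{r:10.3f}{v:18.4e}")
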