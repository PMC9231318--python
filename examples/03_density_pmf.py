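"""Axial density of channel water and the density-based PMF.

Samples 10^5 particles exactly from rho(z) ~ exp(-U(z)/RT) for a Gaussian
axial barrier of 2.5 kcal/mol centred in the membrane-spanning channel
(z = 2.32 to 6.55 nm), measures the axial density in a 1 nm sampling
cylinder, and inverts it: dG_PMF(z) = -RT ln(rho_z / rho_bulk).  The
recovered barrier should match the prescribed one.
"""

import poreform as pf

potential = pf.AxialPotential(kind="gaussian", height=2.5, center=4.435,
                              width=0.5, z_lo=0.0, z_hi=11.0)
traj = pf.generate_boltzmann_particles(potential, 100_000, temperature=310.0,
                                       lateral_radius=1.0, seed=5)
profile = pf.axial_density(traj, "water", z_lo=2.32, z_hi=6.55, n_bins=20,
                           cylinder_radius=1.0, bulk_cross_section="cylinder")
pmf = pf.density_pmf(profile, temperature=310.0)

print(pmf.to_frame().round(3).to_string(index=False))
print(f"\nrecovered PMF barrier: {pmf.barrier:.2f} kcal/mol "
      "(prescribed: 2.50)")
print("the density dip at the channel centre Boltzmann-inverts into the "
      "free-energy barrier a permeating molecule must cross")
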