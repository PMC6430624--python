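"""Apparent CO₂ diffusivity: micropores alone versus the full two-scale wall.

Solves ∇·(D∇c) = 0 through the pore space (solid is impermeable to CO₂)
with concentration fixed on two opposite faces.  The apparent diffusivity
D_app = QΔx/(AΔc) is referenced to the total cross-section, so porosity
and tortuosity both reduce it below the bulk coefficient D_c = 1.6e-5 m²/s.
"""

from nestpore import MediumSpec, co2_flux_scaled, solve_diffusion
from nestpore.media import generate_micropore_matrix, generate_pellet_pack

spec = MediumSpec(seed=4, domain_shape=(64, 64, 64), voxel_size=15.0,
                  pellet_radius_mean_mm=0.18, pellet_radius_sd_mm=0.09)

micro = generate_micropore_matrix(spec)   # small-pore-only subset analogue
full = generate_pellet_pack(spec)         # full two-scale wall analogue

r_micro = solve_diffusion(micro, axis="z")
r_full = solve_diffusion(full, axis="z")

print(f"micropores only : D_app = {r_micro.D_app:.3e} m^2/s")
print(f"full two-scale  : D_app = {r_full.D_app:.3e} m^2/s")
print(f"enhancement     : x{r_full.D_app / r_micro.D_app:.1f}")

_, flux = co2_flux_scaled(r_full)
print(f"CO2 flux through this sample at the physiological gradient "
      f"(5% of atmospheric per cm): {flux:.3e} mol/s")
print()
print("The connected macropore network multiplies CO2 exchange several-fold")
print("over what intra-pellet micropores alone would allow.")
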