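# Default material/fluid profile: micronised particles on an inhaler wall,
# dry van-der-Waals contact, air at 1013.25 hPa / 15 degC.
materials:
  Es: 4.1e9        # surface Young's modulus (Pa)
  Ep: 1.0e9        # particle Young's modulus (Pa)
  nu_s: 0.35       # surface Poisson ratio
  nu_p: 0.4        # particle Poisson ratio
  WA: 0.039        # work of adhesion (J/m^2), silicon-silicon dry contact
  ks: 0.5          # static friction coefficient
  f: 1.7           # near-wall Stokes drag correction
  Cu: 1.0          # Cunningham slip correction (spherical particles)
  rho_p: 1230.0    # particle density (kg/m^3)
fluid:
  rho: 1.225       # air density (kg/m^3)
  mu: 1.7894e-5    # dynamic viscosity (Pa s)
  rho_M: 1.225     # mixture density (dilute: equals rho)
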