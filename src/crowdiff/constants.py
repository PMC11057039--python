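"""Physical constants and unit conventions.

Internal units throughout the package: length in nm, time in µs,
temperature in K, viscosity in mPa·s.  Diffusivities are therefore in
nm²/µs; one nm²/µs equals 1e-12 m²/s.  This keeps Brownian-dynamics step
sizes of order 1e-3–1e-1 nm and avoids floating-point underflow in the
exponentials of the attenuation models.
"""

# CODATA 2018, exact by SI definition
BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹ (CODATA 2018)
GAMMA_1H = 2.6752218744e8

#: conversion factor: D [nm²/µs] * NM2_PER_US_TO_M2_PER_S = D [m²/s]
NM2_PER_US_TO_M2_PER_S = 1e-12
M2_PER_S_TO_NM2_PER_US = 1e12

#: random close packing of monodisperse hard spheres
PHI_RCP = 0.638
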