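"""Physical constants and unit conversions used across the package.

Interface units follow dMRI convention (b in s/mm², timings in ms, diffusivity
in m²/s); all signal computations are done in SI (s, m, T).
"""

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA = 2.6751525e8

#: Convert b from s/mm² (interface) to s/m² (SI).
B_SI_PER_B_MM2 = 1.0e6

#: Convert ms to s.
MS_TO_S = 1.0e-3

#: Free-water diffusivity at body temperature, m²/s.
FREE_WATER_DIFFUSIVITY = 3.0e-9
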