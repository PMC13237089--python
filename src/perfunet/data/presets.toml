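# Named parameter presets for perfunet.
#
# Units convention (used throughout the package): lengths in mm, time in s,
# concentration in mol m^-3, pressure in Pa.  All values here are already in
# this convention.
#
# "defaults" is a high-metabolic-rate, high-cell-density tissue (liver-like)
# in aqueous culture medium.  panelA..panelD are the metabolic variants used
# in the volume-ratio parameter sweeps; sphere_alt is the alternative
# metabolic parameter set for the spherical-compartment reference case.
schema_version = 1

[defaults.tissue]
rho_T = 2.0e5      # cells mm^-3
k_ocr = 1.0e-16    # mol cell^-1 s^-1
k_m = 0.028        # mol m^-3
c_H = 0.05         # mol m^-3

[defaults.transport]
D_t = 2.0e-3       # mm^2 s^-1, oxygen in tissue compartment
D_c = 3.0e-3       # mm^2 s^-1, oxygen in aqueous channel medium at 37 C
D_ws = 1.0e-5      # mm^2 s^-1, oxygen in solid wall material
K = 1.0            # partition coefficient, aqueous media on both sides

[defaults.medium]
mu = 6.9e-4        # Pa s, water at 37 C
nu = 0.696         # mm^2 s^-1, water at 37 C
c_in = 0.2         # mol m^-3, air-saturated medium at 37 C / 1 atm

[panelA.tissue]
rho_T = 2.0e5
k_ocr = 1.0e-16
k_m = 0.028
c_H = 0.05

[panelB.tissue]
rho_T = 2.0e4
k_ocr = 1.0e-16
k_m = 0.028
c_H = 0.05

[panelC.tissue]
rho_T = 2.0e5
k_ocr = 1.0e-16
k_m = 0.015
c_H = 0.05

[panelD.tissue]
rho_T = 1.4e4
k_ocr = 4.2e-17
k_m = 0.007
c_H = 0.05

[sphere_alt.tissue]
rho_T = 2.0e5
k_ocr = 7.0e-17
k_m = 0.015
c_H = 0.05
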