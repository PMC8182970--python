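"""Internal unit system.

All mechanics are computed in a self-consistent mm-g-ms system, in which the
derived force unit is the newton (1 g·mm/ms² = 1 N) and the derived stress
unit is the megapascal (1 N/mm² = 1 MPa).  Velocities in mm/ms coincide
numerically with m/s.  Public APIs speak the field's units (kPa for moduli and
pressures, kg/m³ for densities, Pa·s for viscosities, mm and ms for lengths
and times); the constants below convert at the boundary.
"""

# multiply a value in the public unit by the constant to get the internal unit
KPA = 1.0e-3         # kPa -> MPa
KG_M3 = 1.0e-6       # kg/m³ -> g/mm³
PA_S = 1.0e-3        # Pa·s -> MPa·ms  (Kelvin-Voigt viscosity)

# and back
MPA_TO_KPA = 1.0e3
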