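"""Physical constants (CODATA 2018), frozen so derived quantities are bit-reproducible."""

PLANCK_H = 6.62607015e-34  # J s (exact)
ELECTRON_MASS = 9.1093837015e-31  # kg
ELEMENTARY_CHARGE = 1.602176634e-19  # C (exact)
SPEED_OF_LIGHT = 299792458.0  # m/s (exact)

METERS_TO_ANGSTROM = 1e10
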