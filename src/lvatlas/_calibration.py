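"""Frozen calibration constants for the default population model.

Produced once by ``scripts/calibrate_population.py`` (root-finding on the
volume integral so that the default model reproduces the target global
statistics; see that script and docs/methods.md).  Do not edit by hand.
"""

FOCAL_LENGTH = 42.0
SEPTAL_AMPLITUDE = 0.04
PARAM_SD = 0.03
NOISE_SD = 0.004
SCALE_APEX = 0.06
SCALE_BASE = 0.025

BASE_LAMBDA = {
    "ED": {"endo": 0.6019689966602458, "epi": 0.7897598006634432},
    "ES": {"endo": 0.4189249073946394, "epi": 0.704053289427932},
}
BIAS_AMPLITUDES = {
    "ED": {'endo_apex': 0.07936871026014962, 'endo_base': 0.03968435513007481, 'epi': -0.02245565016706562},
    "ES": {'endo_apex': -0.1977952064087951, 'endo_base': 0.03791212910212508, 'epi': -0.07771163952033583},
}
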