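"""Physical constants (SI, CODATA values at the precision used throughout)."""

FARADAY = 96485.33212  # C/mol
R_GAS = 8.314462618  # J/(mol K)
EPS0 = 8.8541878128e-12  # F/m
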