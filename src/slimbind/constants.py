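"""Physical constants used across the package (SI-derived, kJ/mol energy scale)."""

#: Gas constant, J / (mol K)
R_GAS = 8.314462618

#: Boltzmann constant times Avogadro == R, exposed separately for readability
#: when converting per-molecule free energies to molar ones.
KB_KJ_PER_MOL_K = R_GAS / 1000.0  # kJ / (mol K)

#: gamma(15N)/gamma(1H).  Negative sign of gamma(15N) is irrelevant for |dw|;
#: the magnitude maps a 1H Larmor frequency in MHz to the 15N one.
GAMMA_RATIO_N15_H1 = 0.10136767

#: Default CSP weighting for the 15N dimension (dimensionless).
CSP_N15_WEIGHT = 0.2
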