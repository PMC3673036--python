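"""Physical constants shared across the fitting modules."""

#: Gas constant, J·mol⁻¹·K⁻¹
R_GAS = 8.314

#: Assay temperature for chemical denaturation, kelvin (25 °C bath)
T_CHEM = 298.15
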