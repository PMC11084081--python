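# Material cards for implant safety-factor assessment (MPa, magnitudes).
# Peak stresses are inputs from an external finite-element analysis of the
# nail-fixed femur; the worst case is the gap-fracture configuration, whose
# stress maxima sit on the fracture-adjacent fixation screws.
materials:
  Ti6Al4V:
    yield_compressive_MPa: 1074
    yield_tensile_MPa: 982
    ultimate_compressive_MPa: 1661
    ultimate_tensile_MPa: 1115
peak_stresses_MPa:
  gap_fracture_screws:
    compressive: 348
    tensile: 197
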