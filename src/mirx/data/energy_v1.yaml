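# Nearest-neighbour duplex parameters, version 1.
# stack key 'XY/ZW': pair X:Y (miRNA:target) followed 3'-ward on the miRNA by pair Z:W.
version: 1
allowed_pairs: [AU, UA, CG, GC, GU, UG]
helix_end_penalty: 0.45
bulge_penalty: {base: 3.8, slope: 0.5}
internal_loop_penalty: {base: 4.0, slope: 0.3}
stack_energies:
  AU/AU: -0.93
  AU/UA: -1.10
  AU/CG: -2.24
  AU/GC: -2.08
  AU/GU: -0.55
  AU/UG: -1.36
  UA/AU: -1.33
  UA/UA: -0.93
  UA/CG: -2.35
  UA/GC: -2.11
  UA/GU: -1.27
  UA/UG: -1.00
  CG/AU: -2.11
  CG/UA: -2.08
  CG/CG: -3.26
  CG/GC: -2.36
  CG/GU: -1.41
  CG/UG: -2.11
  GC/AU: -2.35
  GC/UA: -2.24
  GC/CG: -3.42
  GC/GC: -3.26
  GC/GU: -1.53
  GC/UG: -2.51
  GU/AU: -1.00
  GU/UA: -1.36
  GU/CG: -2.51
  GU/GC: -2.11
  GU/GU: -0.50
  GU/UG: -0.60
  UG/AU: -1.27
  UG/UA: -0.55
  UG/CG: -1.53
  UG/GC: -1.41
  UG/GU: -0.40
  UG/UG: -0.50
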