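# Montage derivation tables for the 19-electrode 10-20 system.
# Editable: the bipolar chain and Laplacian neighbourhoods are conventions,
# not physical constants.

# Canonical channel order used throughout the package.
channel_order:
  [Fp1, Fp2, F7, F3, Fz, F4, F8, T3, C3, Cz, C4, T4, T5, P3, Pz, P4, T6, O1, O2]

# Longitudinal bipolar ("double banana") derivations, anode-cathode.
bipolar:
  - [Fp1, F7]
  - [F7, T3]
  - [T3, T5]
  - [T5, O1]
  - [Fp2, F8]
  - [F8, T4]
  - [T4, T6]
  - [T6, O2]
  - [Fp1, F3]
  - [F3, C3]
  - [C3, P3]
  - [P3, O1]
  - [Fp2, F4]
  - [F4, C4]
  - [C4, P4]
  - [P4, O2]
  - [Fz, Cz]
  - [Cz, Pz]

# Nearest-neighbour table for the small Laplacian: each electrode minus the
# mean of its listed neighbours.
laplacian_neighbors:
  Fp1: [Fp2, F3, F7]
  Fp2: [Fp1, F4, F8]
  F7: [Fp1, F3, T3]
  F3: [Fp1, Fz, C3, F7]
  Fz: [F3, F4, Cz]
  F4: [Fp2, Fz, C4, F8]
  F8: [Fp2, F4, T4]
  T3: [F7, C3, T5]
  C3: [F3, Cz, P3, T3]
  Cz: [Fz, C3, C4, Pz]
  C4: [F4, Cz, P4, T4]
  T4: [F8, C4, T6]
  T5: [T3, P3, O1]
  P3: [C3, Pz, O1, T5]
  Pz: [Cz, P3, P4]
  P4: [C4, Pz, O2, T6]
  T6: [T4, P4, O2]
  O1: [T5, P3, O2]
  O2: [T6, P4, O1]
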