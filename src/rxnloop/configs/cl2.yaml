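# Second-loop space: reagent and base fixed to the CL1 incumbents (Bz2O,
# Et3N), eq-base ceiling raised 16.7 -> 30, and the solvent categorical
# replaced by a continuous MeCN:THF mixing ratio (0 = pure MeCN, 1 = pure THF).
metadata:
  loop: CL2
  objective: mono
  parent: cl1
parameters:
  - name: eq_bz
    kind: continuous
    lower: 1.0
    upper: 4.0
  - name: eq_base
    kind: continuous
    lower: 1.0
    upper: 30.0
  - name: conc
    kind: continuous
    lower: 0.04
    upper: 0.15
  - name: bz_reagent
    kind: ordinal
    levels: [1, 2]
    fixed_value: 2
  - name: base
    kind: ordinal
    levels: [1, 2, 3, 4, 5, 6, 7, 8, 9]
    fixed_value: 1
  - name: t1
    kind: ordinal
    levels: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  - name: solvent_ratio
    kind: continuous
    lower: 0.0
    upper: 1.0
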