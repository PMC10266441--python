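# Third loop: same space as CL2 but the objective switches to the
# 3,6-di-benzoylated product; warm-started from the CL1+CL2 histories.
metadata:
  loop: CL3
  objective: di
  parent: cl2
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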