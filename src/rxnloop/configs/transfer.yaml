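# Transfer-learning space: the full 7-parameter mixed space with expanded
# continuous ranges plus the eighth "sugar" task categorical.  Suggestions
# pin "sugar" to the substrate being optimized (set via space.pinned or the
# transfer module); historical records carry their own task label.
metadata:
  loop: transfer
  objective: mono
parameters:
  - name: eq_bz
    kind: continuous
    lower: 1.0
    upper: 10.0
  - name: eq_base
    kind: continuous
    lower: 1.0
    upper: 30.0
  - name: conc
    kind: continuous
    lower: 0.02
    upper: 0.2
  - name: bz_reagent
    kind: ordinal
    levels: [1, 2]
  - name: base
    kind: ordinal
    levels: [1, 2, 3, 4, 5, 6, 7, 8, 9]
  - name: t1
    kind: ordinal
    levels: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  - name: solvent
    kind: categorical
    levels: [MeCN, THF, dioxane, toluene, MeCN/THF, MeCN/dioxane, MeCN/toluene,
             THF/dioxane, THF/toluene, dioxane/toluene]
  - name: sugar
    kind: categorical
    levels: [beta-glucoside, alpha-thiomannoside, beta-galactoside]
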