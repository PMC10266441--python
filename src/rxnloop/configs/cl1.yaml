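# Initial closed-loop space: 7 parameters for regioselective benzoylation
# of an unprotected glycoside. Reaction time (1 h) and temperature (ambient)
# are fixed constants of the workflow, not parameters.
# Continuous ranges are package assumptions (see docs/methods.md); only the
# 16.7 eq-base maximum is anchored by the study design.
metadata:
  loop: CL1
  objective: mono
  constants:
    reaction_time_h: 1
    temperature: ambient
parameters:
  - name: eq_bz
    kind: continuous
    lower: 1.0
    upper: 4.0
  - name: eq_base
    kind: continuous
    lower: 1.0
    upper: 16.7
  - name: conc
    kind: continuous
    lower: 0.04
    upper: 0.15
  - name: bz_reagent          # 1 = BzCl, 2 = Bz2O
    kind: ordinal
    levels: [1, 2]
  - name: base                # PCA-ordered base integers, 1 = Et3N
    kind: ordinal
    levels: [1, 2, 3, 4, 5, 6, 7, 8, 9]
  - name: t1                  # minutes between base and Bz-reagent addition
    kind: ordinal
    levels: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  - name: solvent             # 4 pure solvents + all 1:1 binary mixtures
    kind: categorical
    levels: [MeCN, THF, dioxane, toluene, MeCN/THF, MeCN/dioxane, MeCN/toluene,
             THF/dioxane, THF/toluene, dioxane/toluene]
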