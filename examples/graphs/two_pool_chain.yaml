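nodes:
- X1
- X2
labeled_in:
- to: X1
  id: f1
unlabeled_in:
- to: X1
  id: f2
- to: X2
  id: f5
exits:
- from: X1
  id: f3
- from: X2
  id: f6
internal:
- from: X1
  to: X2
  id: f4
fluxes:
  f1: 0.15
  f2: 0.05
  f3: 0.08
  f4: 0.12
  f5: 0.08
  f6: 0.2
concentrations:
  X1: 0.5714285714285714
  X2: 0.6666666666666666
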