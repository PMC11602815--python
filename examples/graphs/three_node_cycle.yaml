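nodes:
- X1
- X2
- X3
labeled_in:
- to: X1
  id: f1
unlabeled_in:
- to: X1
  id: f2
- to: X2
  id: f5
- to: X3
  id: f8
exits:
- from: X1
  id: f3
- from: X2
  id: f6
- from: X3
  id: f9
internal:
- from: X1
  to: X2
  id: f4
- from: X2
  to: X3
  id: f7
- from: X3
  to: X1
  id: f10
fluxes:
  f1: 1.0
  f2: 2.0
  f3: 2.0
  f4: 4.0
  f5: 3.0
  f6: 2.0
  f7: 5.0
  f8: 1.0
  f9: 3.0
  f10: 3.0
concentrations:
  X1: 1.0
  X2: 1.0
  X3: 1.0
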