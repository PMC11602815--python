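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
- from: X2
  to: X1
  id: f-4
fluxes:
  f1: 0.21
  f2: 0.0875
  f3: 0.14
  f4: 0.21
  f-4: 0.0525
  f5: 0.09
  f6: 0.2475
concentrations:
  X1: 1.0
  X2: 1.0
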