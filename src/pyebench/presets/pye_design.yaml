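# Six-sample PYE benchmark design: human plasma background with yeast and
# E. coli spike-ins. Fractions are percent of total protein mass (w/w).
species: [human, yeast, ecoli]
background: human
base_samples:
  PYE1A: {human: 90, yeast: 2, ecoli: 8}
  PYE1B: {human: 90, yeast: 6, ecoli: 4}
dilutions:
  PYE3: {parts_base: 1, parts_diluent: 2}
  PYE9: {parts_base: 1, parts_diluent: 8}
pairs:
  PYE1: [PYE1A, PYE1B]
  PYE3: [PYE3A, PYE3B]
  PYE9: [PYE9A, PYE9B]
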