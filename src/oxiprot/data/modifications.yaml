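# Default modification registry: the six modifications used for
# radiation-oxidation TMT searches. Delta masses are monoisotopic (Da) at
# full precision; residues lists are one-letter codes, with "nterm"
# denoting the peptide/protein N-terminus. Compositions use optional
# isotope prefixes (13C, 15N); counts may be negative.
- name: carbamidomethyl
  delta_mass: 57.02146372
  residues: C
  role: dynamic
  composition: {C: 2, H: 3, N: 1, O: 1}
- name: oxidation
  delta_mass: 15.99491462
  residues: CDEFHILMNPQRSTVWY
  role: dynamic
  composition: {O: 1}
- name: carbonylation
  delta_mass: 13.97926456
  residues: AEILQRSV
  role: dynamic
  composition: {O: 1, H: -2}
- name: dioxidation
  delta_mass: 31.98982924
  residues: CEFILMPRVWY
  role: dynamic
  composition: {O: 2}
- name: trioxidation
  delta_mass: 47.98474386
  residues: CFWY
  role: dynamic
  composition: {O: 3}
- name: tmt
  delta_mass: 229.16293213
  residues: K,nterm
  role: static
  composition: {C: 8, 13C: 4, H: 20, N: 1, 15N: 1, O: 2}
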