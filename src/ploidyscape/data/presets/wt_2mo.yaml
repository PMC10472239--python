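# Wild-type 2-month cohort: mononuclear >=8n fraction 4.9 +/- 2.8 % between
# mice; binucleation moderate. 2n/4n split chosen as field-realistic for
# young mouse liver (see docs/methods.md).
name: wt_2mo
kind: imaging
n_mice: 6
n_cells: 950
binuclear_fraction: {mean: 0.225, sd: 0.030}
mononuclear_class_probs:
  p4: {mean: 0.26, sd: 0.04}
  p8_plus: {mean: 0.049, sd: 0.028}
  p16_given_8plus: 0.12
mitotic_fraction: 0.01
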