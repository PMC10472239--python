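# Mcl-1-deficient 2-month cohort: enriched highly polyploid nuclei
# (>=8n 15.9 +/- 5.7 % between mice), depleted diploid contingent, lower
# binucleation than wild type.
name: mcl1_2mo
kind: imaging
n_mice: 6
n_cells: 950
binuclear_fraction: {mean: 0.125, sd: 0.030}
mononuclear_class_probs:
  p4: {mean: 0.27, sd: 0.04}
  p8_plus: {mean: 0.159, sd: 0.057}
  p16_given_8plus: 0.25
mitotic_fraction: 0.02
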