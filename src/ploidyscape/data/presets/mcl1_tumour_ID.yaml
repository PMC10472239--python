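# Tumour indel-signature composition: the ID12-like signature dominates at
# ~45% relative contribution, with ID1-like and ID2-like clock-like
# signatures contributing in the 15-20% range each.
name: mcl1_tumour_ID
kind: catalog
signature_set: synthetic_id83_mini
n_mutations: 3000
exposures:
  ID1L: 0.20
  ID2L: 0.15
  ID5L: 0.20
  ID12L: 0.45
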