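# End-to-end demo: simulate a tissue field, profile its ploidy, simulate
# and score mitotic figures, simulate a catalog and refit exposures.
#   ploidyscape run --config examples/demo.yaml --seed 5
stages:
  - simulate_images
  - profile_ploidy
  - simulate_mitoses
  - score_mitoses
  - simulate_catalog
  - fit_signatures
params:
  simulate_images:
    n_cells: 200
    binuclear_fraction: 0.15
  profile_ploidy:
    dna: out/demo/simulate_images/dna.tif
    membrane: out/demo/simulate_images/membrane.tif
    mitotic_mask: out/demo/simulate_images/mitotic_truth.tif
  simulate_mitoses:
    n: 100
    aberration_probs: {multipolar: 0.1, asymmetric: 0.1, lagging: 0.2, bridge: 0.1}
  score_mitoses:
    figures: out/demo/simulate_mitoses/figures
  simulate_catalog:
    preset: mcl1_tumour_ID
  fit_signatures:
    catalog: out/demo/simulate_catalog/catalog.tsv
seed: 5
out_dir: out/demo
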