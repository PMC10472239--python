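# ploidyscape

Quantification toolkit for hepatocyte polyploidy and its genomic
consequences. Liver parenchyma is unusual: a large share of hepatocytes is
polyploid, either by carrying two nuclei (cellular ploidy) or by carrying
nuclei with doubled DNA content (nuclear ploidy — 2n, 4n, 8n, 16n).
Perturbations that derail mitosis shift this profile, produce visibly
aberrant mitotic figures (multipolar spindles, asymmetric metaphase plates,
lagging chromosomes, anaphase bridges) and, over time, leave genomic scars:
chromosomal instability and characteristic mutational signatures in the
tumours that eventually arise. `ploidyscape` implements the full
quantification chain for all three readouts, plus a ground-truthed
synthetic-data generator so that every stage is testable end-to-end without
any external dataset.

The package is aimed at quantitative biologists analysing two-channel
(DNA stain + membrane stain) tissue images, chromatin masks of mitotic
events, and VCF-derived mutation catalogs.

## What it computes

**Nuclear/cellular ploidy** (`ploidyscape.ploidy`). Nuclei are segmented
from the DNA channel (Otsu + distance-transform watershed), each nucleus's
background-corrected integrated intensity *I* is measured, and the diploid
reference *I*₂ₙ is located as the lowest mode of the log₂ *I* distribution
(KDE, bandwidth 0.12 log₂ units, ≥5% mode mass). Classes follow

    class(I) = 2 · 2^round(log₂(I / I₂ₙ))

with boundaries at geometric midpoints, so assignment is invariant to any
rescaling of the channel. The membrane channel groups nuclei into cells
(watershed with seeds merged where no membrane ridge separates them),
yielding the binucleated fraction (binucleated cells / total nuclei) and
the 2n/4n/≥8n fractions among mononucleated hepatocytes.

**Mitotic morphometry** (`ploidyscape.mitosis`). Chromatin masks are
classified by phase (prophase / metaphase / anaphase+telophase) from mass
count and elongation; pole count, metaphase-plate asymmetry
|m₁−m₂|/(m₁+m₂), lagging-chromatin count and anaphase-bridge presence are
scored, and a figure is aberrant when poles > 2, asymmetry > 0.25,
lagging > 0 or a bridge is present.

**Signatures and CIN** (`ploidyscape.signatures`). VCF + FASTA →
COSMIC-layout SBS96/ID83 catalogs; an FFPE C>T artifact component is
removed by NNLS over the signature matrix augmented with an artifact
column; exposures are refit by NNLS with <5% contributions pruned; and a
chromosomal-instability statistic is reported as the percentage of genomic
windows containing ≥1 variant.

**Statistics** (`ploidyscape.stats`). Mean ± SD/SEM summaries, classical
one-way ANOVA with Tukey HSD ("when significant"), two-sided t tests, R².

The analysis stages are sklearn-style estimators (`PloidyProfiler`,
`MitosisScorer`, `SignatureRefitter`, `FfpeCorrector`) with plain-function
wrappers; the generator lives in `ploidyscape.synth`.

## Worked example

```python
import numpy as np
from ploidyscape.synth import SceneConfig, sample_scene, render_scene, \
    sample_mitotic_figures
from ploidyscape import PloidyProfiler, MitosisScorer

cfg = SceneConfig(n_cells=400, binuclear_fraction=0.15,
                  ploidy_class_probs=(0.55, 0.27, 0.14, 0.04), seed=7)
scene = sample_scene(cfg)
image = render_scene(scene)           # (2, h, w) uint16: DNA, membrane

profiler = PloidyProfiler().fit(image.astype(float),
                                mitotic_mask=scene.mitotic_mask)
p = profiler.profile_
print(f"diploid reference intensity: {p.reference_intensity:.0f}")
print(f"mononuclear fractions: 2n={p.class_fractions['2n']:.3f} "
      f"4n={p.class_fractions['4n']:.3f} >=8n={p.class_fractions['8n_plus']:.3f}")
print(f"binucleated fraction: {p.binucleated_fraction:.3f} "
      f"(truth {scene.binucleated_nucleus_fraction():.3f})")

figs = sample_mitotic_figures(
    200, aberration_probs={"multipolar": 0.1, "asymmetric": 0.1,
                           "lagging": 0.2, "bridge": 0.1}, seed=7)
scorer = MitosisScorer().fit([m for m, _ in figs])
s = scorer.summary_
print(f"aberrant fraction: {s.aberrant_fraction:.3f}")
print(f"metaphase:telophase ratio: {s.metaphase_to_telophase_ratio:.2f}")
```

prints

```
diploid reference intensity: 39802
mononuclear fractions: 2n=0.556 4n=0.311 >=8n=0.133
binucleated fraction: 0.133 (truth 0.133)
aberrant fraction: 0.490
metaphase:telophase ratio: 0.76
```

The reference intensity sits at ~2 × 20 000 (the generator's
intensity-per-DNA-unit), the estimated fractions match the generative
mixture, and the aberrant fraction equals the generator's realized truth
(0.490 here).

Signature refitting on a simulated indel catalog (3 000 indels, dominant
signature at 45%):

```python
from ploidyscape.signatures import load_id_signatures, fit_exposures
from ploidyscape.synth import CatalogSimConfig, simulate_catalog

sig = load_id_signatures()
counts = simulate_catalog(CatalogSimConfig(
    signatures=sig, exposures=(0.20, 0.15, 0.20, 0.45, 0.0),
    n_mutations=3000, seed=7))
exp = fit_exposures(counts, sig)
```

recovers `ID1L 20.0%, ID2L 15.2%, ID5L 19.5%, ID12L 45.4%` with
reconstruction cosine 0.9976; a catalog half-contaminated with the FFPE
artifact profile is corrected from cosine 0.678 back to 0.999 against the
true biological catalog.

A command-line interface mirrors the library
(`ploidyscape simulate-images | profile-ploidy | simulate-mitoses |
score-mitoses | simulate-catalog | simulate-variants | build-catalog |
correct-ffpe | fit-signatures | cin | compare-groups | run`); see
`examples/demo.yaml` for a multi-stage pipeline config with a
reproducibility manifest.

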