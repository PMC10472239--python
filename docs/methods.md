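# Methods

`ploidyscape` quantifies three things about hepatocyte biology from
desk-scale inputs: (1) nuclear and cellular ploidy profiles from two-channel
fluorescence images, (2) the frequency and type of aberrant mitotic figures
from chromatin masks, and (3) FFPE-corrected COSMIC-style mutational
signature exposures plus a windowed chromosomal-instability (CIN) statistic
from variant tables. Every analysis stage is validated end-to-end against a
synthetic-data generator that produces inputs with known ground truth.

## Ploidy profiling

**Model.** Hepatocyte DNA content doubles per nuclear ploidy class (2n, 4n,
8n, 16n). The integrated DNA-stain intensity of a nucleus is therefore
proportional to its class, up to a biological coefficient of variation and
imaging noise. Cellular ploidy is the number of nuclei per cell (mono- vs
binucleated), read from a membrane stain that draws closed cell boundaries.

**Chain.**

1. *Nucleus segmentation* — Gaussian smoothing (σ = 1 px), Otsu foreground
   threshold, removal of objects < 30 px, then a distance-transform
   watershed (peak separation 6 px, plateau peaks merged by dilation) that
   splits touching nuclei.
2. *Densitometry* — per nucleus, the corrected integrated intensity is
   Σ(pixel − local background) over a 1-px dilation of the mask (the
   dilation recaptures edge intensity cut off by the global threshold,
   which otherwise biases dim nuclei low). Local background is the median
   of an annulus (width 4 px) around the nucleus excluding all labelled
   pixels. Nuclei touching the image border are flagged.
3. *Diploid calibration* — a Gaussian KDE (bandwidth 0.12 log2 units;
   Silverman fallback when unset) is formed on log2 corrected intensities
   of unflagged nuclei (≥ 50 required). The reference is the
   lowest-intensity local mode holding ≥ 5% of nuclei within ±0.5 log2
   units. The 5% mass floor keeps the 2n mode findable even in cohorts
   where diploid nuclei are depleted; the procedure is equivariant under
   rescaling all intensities.
4. *Class assignment* — class = 2·2^round(log2(I/reference)); boundaries
   fall at geometric midpoints 2^(m±0.5)·reference, symmetric in log
   space because DNA content doubles per class. Classes above 16n keep
   their computed power; profiles bucket everything ≥ 8n together.
5. *Cell grouping* — nucleus seeds are merged when the membrane intensity
   along the segment joining their centroids never exceeds a contrast
   threshold (default 25% of the robust membrane range above its median);
   a watershed over the membrane landscape restricted to the filled
   membrane foreground then draws cell territories. When the membrane
   channel has no usable contrast the function warns and results are
   low-confidence.
6. *Profile* — mononuclear class fractions are computed over unflagged
   mononuclear nuclei; the binucleated fraction is binucleated cells over
   total unflagged nuclei (bounded by 0.5). Border-touching and
   mitotic-flagged nuclei are excluded from calibration and all
   denominators: clipped nuclei carry partial intensity, and condensed
   mitotic chromatin (a G2/M population) would otherwise inflate the
   apparent polyploid contingent. The mitotic flag comes from input
   metadata or generator truth; it is not inferred from the DNA channel.

## Mitotic-figure morphometry

Figures are binary chromatin masks. After morphological opening (disk
radius 2), connected components ≥ 20% of total chromatin area are "major
masses":

* ≥ 2 major masses → anaphase/telophase (the telophase bucket includes
  anaphase); one elongated mass (moment aspect ratio ≥ 2.5) → metaphase;
  one compact mass → prophase.
* *Pole count* = number of major masses; > 2 flags multipolarity.
* *Plate asymmetry* = |m1 − m2| / (m1 + m2) over pixel counts on each side
  of the principal axis through the centroid; scores > τ = 0.25 flag an
  asymmetric plate. τ separates the generator's asymmetric class (70/30
  mass split, score ≈ 0.3 after the connecting isthmus is accounted for)
  from symmetric plates (score ≤ 0.02). A perfectly collinear mask is
  degenerate and scores 0 with a warning.
* *Lagging chromatin* = minor components inside the convex hull of the two
  largest masses. *Bridge* = the two largest masses are connected in the
  raw mask but separate after opening, i.e. only a strand thinner than
  ~4 px joins them.
* A figure is aberrant if pole count > 2, asymmetry > τ, lagging > 0, or a
  bridge is present. The summary reports phase counts, the aberrant
  fraction and the metaphase-to-telophase ratio (undefined, reported as
  null, when no anaphase/telophase events exist).

The thresholds (20% major-mass fraction, τ = 0.25, opening radius 2) are
recorded in the module constants and validated exclusively against
generator truth; the package scores chromatin geometry only, not spindle
immunostains.

## Mutation catalogs and signatures

* *SBS96* — substitution channels from the pyrimidine-strand trinucleotide
  context read from the reference FASTA; purine-reference variants are
  reverse-complemented. Contexts containing N are skipped with a log entry.
* *ID83* — indels are reduced to (kind, start, sequence) from anchored VCF
  records (left-aligned minimal representation is a precondition; complex
  records are skipped). 1-bp events are stratified by C/T base (pyrimidine
  representation) and homopolymer run length; longer events by
  tandem-repeat copy number; non-repeat deletions additionally by flanking
  microhomology length, with the COSMIC caps per size class.
* *FFPE correction* — formalin fixation adds spurious C>T counts. The
  observed catalog is decomposed by non-negative least squares over the
  reference signature matrix augmented with a packaged C>T-dominated
  artifact column; the rounded artifact expectation is subtracted per
  channel (clamped at 0), so biological + removed = observed exactly. The
  artifact profile is a synthetic stand-in with the defining features of
  formalin damage (C>T mass concentrated at non-CpG contexts), not a
  published profile.
* *Refitting* — NNLS of the catalog onto the signature matrix; signatures
  with relative contribution < 0.05 (configurable) are pruned and the fit
  repeated until all retained signatures pass, a standard sparsification
  for COSMIC refitting. Relative contributions are renormalized over the
  retained set; fit quality is the cosine between catalog and
  reconstruction.
* *CIN statistic* — 100 × (windows with ≥ 1 variant) / (total windows)
  over disjoint half-open windows, by default 50-kb tiles of the packaged
  genome. This window-fraction operationalization is a package decision:
  it rises monotonically with the dispersion of mutations across the
  genome and is exactly recoverable from the generator's construction.

The packaged signature matrices (6 SBS96 columns, 5 ID83 columns) are
synthetic miniatures in COSMIC layout: each column has the qualitative
shape of a familiar signature family (a CpG C>T clock-like column, a flat
background, a T>C column, homopolymer insertion/deletion columns, a
multi-bp deletion column, a microhomology-deletion column) but the exact
probabilities are constructed, which keeps tests self-contained and the
columns well-conditioned for NNLS.

## Synthetic-data generator

**Tissue fields.** Cells are laid on a jittered square grid whose pitch is
derived from the largest sampled cell, guaranteeing non-overlapping nucleus
masks (an explicit packing check raises otherwise). Each cell is
binucleated with the configured probability; both nuclei of a binucleated
cell share a ploidy class. Nuclear projected area scales as ploidy^(2/3)
(volume-proportional DNA projected to 2D), so area and intensity are
correlated but not redundant. True integrated intensity is ploidy ×
intensity-per-DNA-unit × a lognormal factor (default CV 8%), spread
uniformly over the mask pixels so noise-free integration is exact. The
membrane channel draws a Gaussian-profile ring along each cell ellipse.
Noise model: multiplicative linear illumination gradient (default ±10%),
Poisson shot noise, Gaussian read noise (default SD 8 counts), constant
background (default 300 counts), 16-bit quantization with clipping logged.
Defaults (2n radius 6 px, 20 000 photons per DNA unit giving a 2n nucleus
roughly the background level per pixel) give contrast typical of a
well-exposed DNA stain. A small fraction of cells (default 1–2%) is
flagged mitotic in the ground truth.

What the generator does **not** emulate: 3D optics and z-stacks, PSF blur,
stain spectral bleed-through, irregular (non-ellipsoidal) cell shapes,
tissue tears and lobule zonation. Passing tests therefore demonstrate
correctness of the quantification chain under the stated image-formation
model, not robustness to every histological artifact.

**Cohort presets.** The imaging presets encode cohort compositions as
between-mouse normal distributions for the ≥8n mononuclear fraction
(mcl1-deficient: 15.9 ± 5.7%; wild type: 4.9 ± 2.8%) and binucleated
fraction. Per-mouse ≥8n probabilities are placed at stratified normal
quantiles ((i+0.5)/m) of that distribution, shuffled across mice: the
cohort sample mean equals the preset mean by construction while preserving
the between-mouse spread, so a recovery experiment with 6 mice measures
pipeline bias rather than small-cohort sampling noise. The 2n/4n split is
not separately specified by the compositions the presets encode; the
presets use a 4n mean of 26–27% (typical for young mouse liver) with the
remainder diploid, and a fixed share of the ≥8n mass assigned to 16n.
All remaining per-mouse parameters are drawn from the seed.

**Mitotic figures.** Each aberration category forces a compatible phase
(asymmetric plates are metaphase; multipolarity, lagging and bridges are
anaphase/telophase), so generated labels are never contradictory.
Geometry realizes the label: k separated masses for k-polar figures,
distinct midzone stations for lagging fragments (they cannot merge), a
2–3 px strand for bridges, and a 70/30 two-band plate (joined by an
isthmus that survives opening) for asymmetric metaphases.

**Catalogs and variants.** Catalog counts are multinomial draws from
signature mixtures; the FFPE forward model adds round(f/(1−f) × total)
artifact counts so the artifact makes up fraction f of the output — the
exact process the correction stage must undo. Variant tables hit exactly
round(fraction × windows) windows. Catalog realization turns channel
counts into concrete VCF records by sampling genomic sites with the
required context from a site index built in one scan of the packaged
genome.

**Packaged genome.** Two chromosomes (1.2 Mb + 0.8 Mb) of fixed-seed
uniform random sequence with implanted homopolymer runs (4–12 bp) and
tandem arrays (2–6 bp units × 2–8 copies) at microsatellite-like density;
a purely iid sequence would lack realizable sites for the long-repeat
indel channels. The genome is generated deterministically at call time and
never shipped as a file.

## Statistics

Group summaries use the n−1 sample SD and SEM = SD/√n. Group comparisons
use classical one-way ANOVA with Tukey's HSD computed only when the
omnibus p < α (a `force_tukey` switch overrides), and plain two-sided
pooled-variance t tests; Welch correction is deliberately not applied,
matching the convention the rest of the pipeline assumes — a documented
limitation for strongly heteroscedastic groups. Correlation strength is
the squared Pearson coefficient.

## Problem sizes and determinism

Validation experiments use 6 simulated mice × ~950 cells (~1100 nuclei)
per imaging cohort, 200–300 mitotic figures, catalogs of 3000–5000
mutations and 40 CIN windows — sizes at which recovery tolerances (±2
percentage points for cohort means, ±0.05 for fractions, ±5 points for
exposure contributions) are comfortably above residual estimator noise.
Every sampler is a pure function of (config, seed); pipeline stages derive
per-stage seeds from the global seed, and `scripts/acceptance.py` derives
all of its seeds from its `--seed` argument.

## Known limitations

* Calibration requires the 2n mode to hold ≥ 5% of nuclei; cohorts with
  near-total diploid depletion need a manual reference.
* Sub-2n debris is bucketed into 2n (minimum-area filtering removes most
  of it); apoptotic-body discrimination is out of scope.
* The mitosis module operationalizes categories that were defined on
  spindle/chromatin co-stains using chromatin masks alone.
* The CIN window statistic is an operationalization, not a reimplementation
  of any exome-specific instability score.
* `cin_fraction` scans windows linearly per variant; it is intended for
  desk-scale window sets (10²–10⁴ windows), not genome-wide tiling at
  kilobase resolution.
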