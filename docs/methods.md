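# Methods

## The assay and its statistical model

`hibafish` analyzes three-color break-apart FISH experiments in interphase
nuclei. Two differentially labeled probes (Green, Red) flank a putative
breakpoint of gene A; a third probe (FarRed) marks a candidate
translocation partner, gene B. At an intact allele the Red and Green
signals virtually co-localize. Chromosome breakage of the intervening
region separates them; a reciprocal translocation additionally brings the
separated Red signal next to a FarRed signal.

Event calling is purely geometric. For every Red signal in a nucleus the
minimum 2D center-to-center distance to any Green signal (`rg_min`) and to
any FarRed signal (`rfr_min`) is computed on maximum-intensity
projections, in pixel units. With proximity threshold `t` (default 4 px =
1.28 µm at 320 nm/px):

* breakage: `rg_min > t`;
* translocation: `rg_min > t` and `rfr_min <= t`;
* intact otherwise (distances exactly at `t` count as proximal).

A translocation therefore always satisfies the breakage condition and is
counted in breakage tallies. A nucleus is positive for an event class if
it carries at least one such event among its Red signals.

Before any distance is reported, a nucleus must pass the signal-count QC
filter: at least two signals in each FISH channel and equal Green and Red
counts. This guards against missed or spurious detections; the full filter
is applied before all distance reporting, including threshold calibration.

## Image analysis

Each channel's z-stack is maximum-projected; nuclei are segmented from the
DAPI projection by Gaussian smoothing (σ = 2 px), Otsu thresholding and
hole filling, with optional watershed splitting of touching nuclei (off by
default — the simulator places nuclei apart, and on real data splitting
merged objects trades one artifact for another). Objects outside the area
range [500, 15 000] px², below roundness 0.5 (roundness = 4πA/P², computed
on the digital perimeter and clipped at 1), or touching the field border
are flagged excluded with a reason and retained in outputs for audit. The
filter defaults are declared package choices; high-content systems keep
such cutoffs in per-session parameter files and no canonical values exist.

Spot detection within each nucleus ROI is a difference-of-Gaussians
band-pass at the spot scale (σ = 1 px, ratio 1.6), local-maxima extraction
with a minimum peak separation of 3 px (brighter peak wins), a robust
intensity threshold (median + 10·MAD of the band-passed signal inside the
nucleus), and intensity-weighted sub-pixel centroiding in a 5×5 window.
Peaks whose centroid leaves the nucleus mask are dropped. The algorithm is
deliberately standard; its parameters are all exposed in `SpotParams`.

Distances are measured on 2D projections even though acquisition is 3D.
This mirrors the assay's analysis convention and is a known conflation
risk: two signals separated mainly in z can merge in projection. The QC
filter absorbs most such cases by rejecting nuclei with unequal Red/Green
counts.

## Population statistics

Event-positive proportions are reported with modified Wald
(Agresti–Coull) confidence intervals: p̃ = (x+2)/(n+4), half-width
z·sqrt(p̃(1−p̃)/(n+4)), z = 1.96 at 95%, clipped to [0, 1]. The add-2/add-4
variant is used (not the z²/2 generalization) because it is the canonical
"modified Wald" recommendation for exactly this rare-event regime; it is
implemented directly rather than delegated, since the common library
implementations add z²/2 = 1.92 successes and differ in the third decimal.
Pairwise condition comparisons use the two-sided Fisher exact test for
count data (probability-mass convention), delegated to
`scipy.stats.fisher_exact` and cross-checked in tests against full
hypergeometric enumeration. No multiple-testing correction is applied;
comparisons are reported unadjusted, matching standard practice for a
small number of planned contrasts. Percentages print with two significant
figures below 1% and three above; raw fractions are always emitted
alongside.

The proximity threshold is calibrated empirically, not assumed: on a
negative-control (unbroken) condition, the calibrated threshold is the
smallest integer pixel radius covering 99.8% of per-Red minimum Red/Green
distances. On data in this assay's geometry that procedure yields 4 px or
less.

## The synthetic-imaging generator

The simulator is first-class, tested code; it defines the conditions every
downstream validation runs under.

Geometry: nuclei are 2D ellipses (semi-axes uniform in 14–22 px,
i.e. 9–14 µm diameters at 320 nm/px) extruded in z with a Gaussian axial
intensity profile, placed without overlap and away from the field border.
Allele anchor points are placed inside the nucleus with a minimum mutual
separation of 8 px per channel, a coarse stand-in for chromosome
territories; chromosome-territory spatial statistics are deliberately not
modeled. Unbroken FarRed loci are otherwise uniform in the nucleus, which
reproduces the background Red/FarRed proximity rate of negative cells
without territory modeling.

Offsets: the Red–Green separation is Rayleigh-distributed with mean
0.32 µm (1 px) at intact alleles and 3.2 µm at broken alleles, isotropic
in direction and resampled to stay inside the nucleus; a translocated
allele relocates (never duplicates) one FarRed partner signal to a
Rayleigh mean 0.32 µm from the separated Red signal. The Rayleigh form is
a modeling convenience — the true intact-distance distribution's
parametric form is not established — chosen as the simplest isotropic 2D
displacement law; its mean is configurable.

Optics and noise: spots render as 3D Gaussians (σ = 1 px lateral, 0.75
planes axial, peak 500 counts); the default acquisition is 512×512 px
fields, seven z-planes 1.5 µm apart, four channels. Default noise is a
100-count background with Poisson shot noise and 2-count Gaussian read
noise. These are documented defaults, not a fit to any instrument.

Determinism: one master seed; each field uses
`SeedSequence(seed, spawn_key=(field_index,))`, so any field is
independently reproducible and identical seeds give bit-identical stacks
and tables.

### Latent state versus detectable geometry

Each gene-A allele carries a latent state (intact / broken /
translocated), drawn per allele with probability `p_break` and, given a
break, `p_transloc_given_break` (translocations capped by the number of
gene-B partners). `CellModel.from_cell_rates` converts per-cell target
rates into per-allele probabilities.

With a broken-offset mean of 3.2 µm (10 px), about 12% of Rayleigh draws
fall below the 4 px threshold: those alleles are broken in state but
geometrically indistinguishable from intact ones, which is precisely the
false-negative regime break-apart assays report (a 5–10% per-cell false
negative rate for uniformly positive populations). The ground-truth tables
therefore record, per allele, both the latent state and the realized
geometry (`rg_sep_px`, `rfr_min_px`); parameter-recovery validation scores
the pipeline against the realized thresholded geometry of the nuclei it
actually analyzed (matched by centroid, QC-passing), with latent-state
rates reported alongside. Scoring latent states directly would build the
assay's intrinsic false-negative rate into every comparison.

What passing simulations do not show about real data: no chromatin
texture, no illumination gradients, no probe-efficiency variation, no
replication-induced doublet signals, no optical aberrations, and no
z-resolved analysis. Detection accuracy on the simulator (≥99%,
typically 100%) is therefore an upper bound for real images; the assay's
published accuracy regime (>99%) is the benchmark the simulated
conditions were designed to be in, not evidence about any particular
microscope.

## Validation problem sizes

The shipped validation suite uses these sizes, chosen to exercise each
claim at desk scale:

* oracle equivalence: 1000 random nuclei (exhaustive pair scan), 400
  random 2×2 tables with margins ≤ 30 (full enumeration);
* parameter recovery: 5000 cells at 2% per-cell breakage / 0.4%
  translocation through the full image pipeline; exact binomial 95%
  interval of each estimate must cover the realized rate;
* titration: six dilution points (0, 0.1%, 0.5%, 1%, 10%, 100%) of
  translocation-positive into negative cells, 2000 cells each; detected
  fractions must be monotone and proportional (weighted through-origin
  slope in [0.55, 1.05], reflecting geometric misses plus QC losses);
* detection accuracy: 1000 nuclei (8000 spots), default noise, ≥99% per
  channel at a 2 px match radius;
* threshold calibration: five seeds × 10,200 Red signals from unbroken
  populations with 0.3 px localization jitter; the calibrated threshold
  must be ≤ 4 px and seed-invariant.

## Numerical choices and degenerate inputs

* Distances and thresholds are always in pixel units internally;
  micrometer-coordinate tables are converted on entry via the declared
  pixel size.
* Ties in minima need no tie-break — only the minimum value is stored.
* A blank DAPI image segments to an empty list (not an error); zero
  detected spots is a valid result; an empty condition list simulates an
  empty dataset without error.
* Roundness is clipped at 1.0 because the digital perimeter estimate can
  push 4πA/P² slightly above 1 for small smooth disks.
* `peak_local_max` enforces the minimum spot separation; two true signals
  closer than 3 px merge into one detection, which downstream QC converts
  into a nucleus-level rejection rather than a silent miscount.
* Fold changes against a zero baseline proportion are reported as absent,
  not infinite.
* Placement failure after bounded retries raises a "field too dense"
  error rather than degrading silently.

## Known limitations

* No 3D spot localization; z-overlap merging is only mitigated by QC.
* The QC filter preferentially removes nuclei with crowded or merged
  signals, which in heavily rearranged populations are enriched for true
  positives; rates are therefore per analyzed nucleus, as in the assay
  itself, and the validation comparator is computed over the same
  analyzed population.
* The proprietary `.flex` acquisition format is not read; input is
  OME-TIFF/TIFF (both one multi-channel file per field and one file per
  channel), or spot tables entering the pipeline mid-way.
* Dual-fusion probe logic, metaphase spreads, well/field mixed models and
  multiple-testing correction are out of scope.
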