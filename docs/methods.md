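# Methods

`sgquant` quantifies stress granules (SGs) in multi-channel fluorescence
fields of adherent cells and scores high-content drug screens for granule
retention. This note documents the models and procedures, the parameters
that matter, what the synthetic data emulate (and do not), and the numerical
choices made where the design was open.

## Pipeline overview

For each field (channels: DAPI/nuclei, WGA/membrane, two SG markers such as
TIAR and G3BP2):

1. **Nuclei (primary objects).** Gaussian smoothing (`smoothing_sigma`,
   default 2 px) then automatic global Otsu thresholding of the DAPI image,
   hole filling, area filtering (`[min, max]_nucleus_area`, defaults
   40–5000 px²), and optional declumping by watershed on the distance
   transform with h-maxima seed suppression (`declump_h`, default 1).
   Adding a constant to the image leaves the result unchanged — the
   threshold shifts with the data.
2. **Cells (secondary objects).** Each nucleus seed grows over a foreground
   mask (Otsu threshold of the smoothed membrane image, hole-filled) by
   competitive multi-source Dijkstra propagation on the 8-connected grid.
   Step cost onto pixel q is `len * (lambda + (1-lambda) * g(q))` with `len`
   the Euclidean step, `g` the local gradient magnitude normalized by its
   99th percentile, and `lambda = propagation_lambda` (default 0.05).
   Competing fronts therefore meet along membrane ridges, where crossing is
   expensive. Cells touching the field edge are dropped by default
   (`exclude_border_cells`), since partial cells bias per-cell counts.
3. **Cytoplasm.** Per-cell set difference, cell minus nucleus, labels
   preserved.
4. **Puncta per marker channel.** White top-hat enhancement
   (`tophat_radius`, default 3 px ≈ the expected punctum diameter), then one
   global threshold per field and channel computed on the cytoplasmic pixels
   of the enhanced image by the robust background rule: sort, discard the
   lowest and highest `trim_fraction` (default 5%) of pixels, threshold =
   trimmed mean + `robust_k` (default 2) trimmed SDs. 8-connected
   components are kept if they contain at least one pixel above the trimmed
   mean + `hysteresis_k` (default 6) trimmed SDs and have area in
   `[min, max]_punctum_area` (defaults 6–400 px²). Each punctum is assigned
   the cell under its centroid and cropped to that cell's cytoplasm;
   intensities (mean, integrated, peak) are measured on the *original*
   image so reported brightness does not depend on enhancement settings.
5. **Dual-marker SG calling.** Puncta from the two marker channels are
   paired one-to-one within each cell by footprint overlap (greedy on
   largest intersection; ties by centroid distance, then punctum ids); a
   centroid-distance rule is available for offset channels. A pair is
   called an SG iff (a) the Pearson correlation of the two channels' pixel
   intensities over the pair's footprint exceeds `correlation_threshold`
   (default 0.5, strict inequality) and (b) each punctum's mean intensity is
   at least the channel background mean + `intensity_sufficiency_k`
   (default 2) background SDs, with background measured on cytoplasmic
   pixels outside all detected puncta. Single-channel puncta are never
   called.
6. **Statistics.** Per condition: percent SG-positive cells, mean SGs per
   positive cell (undefined and flagged when no cell is positive), mean SG
   integrated intensity (a size proxy), each with SEM over replicates.
   Per-cell counts are modelled by negative-binomial (NB2) regression with
   log link, condition as covariate and one shared dispersion k (variance
   mu + mu²/k); Wald z-tests on the contrasts. Replicate-level comparisons
   use Welch t-tests with Benjamini–Hochberg FDR control (flagged at
   q ≤ 0.01 by default; classical Student t available by config).
7. **Screen scoring.** Per arm, every drug well's mean granules/cell is
   z-scored against the arm's non-drug control wells (sample SD, n−1;
   configurable ddof). Hits are wells with z ≥ 2 control SDs (one-sided by
   default — the screen seeks *retained* granules; two-sided available).
   Drugs whose normoxia-arm z also meets the threshold are excluded as
   stress-independent inducers; final candidates = hypoxia hits minus
   exclusions.

## Design choices where the procedure was open

- **Correlation domain.** The dual-marker rule requires ">50% correlation"
  between markers without fixing the pixel set. We default to the
  *intersection* of the two matched footprints. Rationale: at realistic
  spot densities a detected footprint frequently fuses with a neighbouring
  single-channel punctum; a union domain then mixes one-channel-only signal
  into the correlation and rejects a large fraction of genuinely coincident
  pairs (measured on synthetic fields: the called fraction at planted
  coincidence 0.5 drops from ~0.5 to ~0.35). The intersection isolates the
  pixels both objects claim. `correlation_domain="union"` restores the
  alternative. Correlation over fewer than 4 pixels (or an intensity-flat
  patch) is undefined; such pairs are rejected and logged.
- **Hysteresis peak test and no pre-smoothing.** The robust background rule
  with trim 5%/k=2 places the threshold near the 94th percentile of any
  approximately normal enhanced background, so a few percent of cytoplasmic
  noise pixels always exceed it; false spots must be removed by spatial
  criteria. Pre-smoothing correlates the noise and makes spurious
  above-threshold clusters *more* likely, so the default `smoothing_sigma`
  is 0; instead every component must contain a high-significance pixel
  (trimmed mean + 6 trimmed SDs) — a standard hysteresis design. Planted
  diffraction-limited spots at SNR 8 exceed this peak test by a wide margin
  (peak ≈ 8 background SDs), giving recall ≥ 0.95 with essentially zero
  false puncta on noise-only fields.
- **One global threshold** per field and channel (not per cell), matching
  the global-thresholding design of the original assay.
- **Punctum adjacency.** Two spots merging into one 8-connected component
  count as one punctum (no punctum-scale declumping); occurrences are
  logged.

## Synthetic data

`simulate.generate_field` renders fields that emulate the statistical
structure the pipeline assumes; all objects are recorded as ground truth.

- **Geometry.** Nucleus centers by rejection sampling with minimum
  separation 0.9×(sum of the two cells' radii), so neighbouring territories
  touch but nuclei stay apart; cell territories are a radius-weighted
  nearest-nucleus partition clipped to each cell's (jittered) radius.
  Defaults: 512×512 px, 60 cells, nucleus radius 6–9 px, cell radius
  16–24 px — a confluent monolayer at roughly 10× magnification scale.
- **Channels.** Nuclei: soft-edged bright disks. Membrane: a 2-px elevated
  ridge along every cell boundary over a dim (35% amplitude) cytoplasmic
  haze — the gradient the propagation segmenter follows. Markers: Gaussian
  puncta (sigma 1.2 px, near diffraction-limited).
- **Counts and coincidence.** Per cell, one NB(mu, k) draw N of punctum
  sites per channel (defaults mu=5, k=2, chosen as a realistic granule load
  under overdispersion; the assay's own count statistics assume unequal
  variance). Each site is dual-channel with probability rho
  (`coincidence_fraction`); otherwise it yields one marker1-only and one
  marker2-only punctum at independent locations. Hence the expected
  coincident fraction of either channel's puncta is exactly rho, per-channel
  counts remain NB(mu, k) and a cell's true SG count (its "both" sites) is
  NB(rho·mu, k). Coincident sites share a location but draw independent
  ±10% amplitude jitter per channel, so their profiles correlate highly
  without being degenerate.
- **Placement.** Punctum centers are uniform over the cell's cytoplasm
  eroded by `punctum_margin` (default 2 px): a granule is an extended
  object about two pixels wide, so its center cannot sit on the compartment
  boundary. Fixture helpers: `fixed_puncta_per_cell` (exact counts) and
  `min_punctum_separation` (rejection-sampled spacing) for planted-spot
  benchmarks.
- **Noise.** Poisson shot noise on background + signal flux plus Gaussian
  read noise (`noise_sigma`, default 5 at background 100). `snr` is the
  peak amplitude over the total background noise SD
  (sqrt(noise_sigma² + background)).
- **Determinism.** All randomness flows from one seed through counter-based
  substreams (per stage, per well), so identical specs are bit-identical
  and adding wells never perturbs earlier ones.
- **Screen plates.** Control and drug wells drawn from
  N(control_mean, control_sd) (defaults 1.0 ± 0.25 granules/cell after
  recovery); hit wells shifted by `hit_effect` (default 4) control SDs in
  the hypoxia-recovery arm; normoxia inducers shifted in both arms.

What the simulator does **not** model: realistic point-spread functions, 3D
structure, illumination gradients, autofluorescence, cell-shape diversity,
marker bleed-through and chromatic offsets between channels. Passing tests
demonstrate the pipeline's correctness and calibration under its own
statistical assumptions, not performance on any particular microscope's
images.

## Numerical notes and degenerate inputs

- Constant images yield zero objects with a warning, not an exception; a
  background sample with fewer than 10 pixels after trimming is an error.
- A nucleus outside the propagation foreground keeps its own footprint as
  its cell (logged). Cells at the field edge are dropped with their nuclei.
- NB fits: when counts show no overdispersion (variance ≤ mean) or the
  fitted dispersion collapses, a Poisson GLM is reported with k at an upper
  bound (1e8) and a Poisson-limit note. BFGS with a Nelder–Mead fallback.
- Welch t-test on two identical groups returns t=0, p=1; zero-variance
  groups with n=2 trigger a degeneracy warning.
- z-scores require ≥2 control wells and nonzero control SD (error names the
  arm). Control z-scores self-normalize to mean 0, SD 1 under the same
  ddof convention.
- Validation sample sizes (chosen to keep the full validation run within a
  few minutes on one core): 10 fields for segmentation recovery, 4
  planted-spot fields and 20 noise-only fields for puncta detection, 10
  seeds per coincidence level, 200 simulations for null calibration of the
  NB Wald test, 100 null plates and 20 hit plates for screen calibration.

## Known limitations

- Sub-pixel registration between marker channels is not modelled or
  corrected; the footprint-overlap matcher tolerates ~1–2 px offsets only.
- The propagation cost uses the gradient at the target pixel; very thin
  (1 px) membrane ridges can be stepped over diagonally.
- Punctum-dense cells can fuse spots into single components, which slightly
  deflates counts and is the main reason the called-SG fraction tracks the
  planted coincidence fraction to ±0.1 rather than exactly.
- The NB model assumes a shared dispersion across conditions (per-condition
  k is a config option but not used by the default reports).
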