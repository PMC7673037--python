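# sgquant

Stress-granule (SG) quantification and drug-screen scoring for multi-channel
fluorescence microscopy of adherent cells.

Stress granules are cytoplasmic condensates of stalled mRNAs and RNA-binding
proteins (marked by TIAR, G3BP1/2, FMRP) that form under stresses such as
hypoxia and normally dissolve within minutes of stress removal. Delayed
dissolution ("granulostasis") is a drug-targetable phenotype: in a
high-content screen, a compound that keeps granules assembled after
reoxygenation shows an elevated mean granule count per cell relative to
untreated controls. `sgquant` implements the full measurement chain needed
for such experiments, for imaging scientists and screeners who want a
tested, scriptable alternative to point-and-click pipelines:

- **Segmentation** — nuclei as primary objects (automatic Otsu thresholding
  of DAPI), cells as secondary objects grown from nucleus seeds by
  minimum-cost propagation over the membrane (WGA) channel, with step cost
  `λ·distance + (1−λ)·∇I` so fronts meet on membrane ridges.
- **Puncta detection** — white top-hat enhancement and one global
  robust-background threshold per field and channel (trimmed mean + k·SD of
  cytoplasmic pixels, trim 5%, k = 2) with a hysteresis peak test and area
  bounds; intensities measured on the raw image.
- **Dual-marker SG calling** — one-to-one matching of the two marker
  channels' puncta within each cell; a pair is an SG iff the channels'
  pixelwise Pearson r exceeds 0.5 over the pair's footprint and both puncta
  are ≥ 2 background SDs above the cytoplasmic background.
- **Statistics** — % SG-positive cells, SGs per positive cell and SG
  intensity with SEM over replicates; negative-binomial regression of
  per-cell counts (variance μ + μ²/k); Welch t-tests with
  Benjamini–Hochberg FDR.
- **Screen scoring** — per-well z = (x − m_c)/s_c against non-drug
  controls, hits at z ≥ 2, ranking, and a normoxia counter-screen that
  excludes stress-independent granule inducers.
- **Synthetic data** — a generator for fields (nuclei, membrane ridges, two
  marker channels with a controllable coincidence fraction ρ, NB-distributed
  counts, Poisson + Gaussian noise) and screen plates with planted hits, so
  every stage is validated against known ground truth.

## Worked example

The `analysis/` scripts run a complete in-silico experiment. Script 01
simulates a 30-min recovery timepoint in two groups (vehicle: most granules
dissolved, planted dual-marker coincidence ρ = 0.3, ~1 punctum/cell; drug:
granules retained, ρ = 0.7, ~5 puncta/cell), 02 quantifies the images, 03
runs the statistics:

```text
$ python analysis/02_quantify_fields.py
                    recovered_pct  planted_pct
drug_recovery30              83.2         86.7
vehicle_recovery30           21.3         21.1

$ python analysis/03_condition_statistics.py
         condition  n_cells  pct_cells_with_sgs  sem_pct  mean_sgs_per_positive_cell
   drug_recovery30      333               83.18    1.258                       2.874
vehicle_recovery30      329               21.28    2.464                       1.157
NB dispersion k = 4.01; condition means drug_recovery30: 2.39, vehicle_recovery30: 0.25
contrast vehicle_vs_drug: beta = -2.27 (Wald p = 2.4e-76)
t-test drug_vs_vehicle: t = 22.4, p = 2.1e-4, BH q = 2.1e-4, significant at 1% FDR
```

The recovered percentage of SG-positive cells tracks the planted truth to a
few points; the NB contrast (log ratio of mean counts) and the
replicate-level t-test both flag the planted group difference.

Scripts 04–05 simulate and score a 1120-compound screen (96 controls, 50
planted 4-SD hits, 9 normoxia inducers):

```text
$ python analysis/05_score_screen.py
control mean granules/cell: 0.9778 (SD 0.2452)
hits before counter-screen: 86
excluded by normoxia counter-screen: 12
final candidates: 74
sensitivity vs planted truth: 0.940 (47/50)
```

86 wells exceed the 2-SD threshold (50 true hits, the 9 inducers, and ~27
expected false positives from the 2.3% one-sided tail of 1120 nulls); the
counter-screen removes the inducers plus a few chance overlaps.

The same operations are available as a CLI (`sgquant simulate-fields`,
`simulate-plate`, `quantify`, `screen`, `report`) for running on your own
TIFF fields and plate CSVs.

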