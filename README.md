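# maldiclust

Species discrimination from MALDI-ToF protein mass spectra, as a tested,
reusable pipeline: raw two-column ASCII spectra are preprocessed
(range trim, square-root transform, Savitzky–Golay smoothing, SNIP baseline
removal, TIC normalisation), peaks are picked at SNR 6 with a half-window of
7 points, binned across spectra at a relative tolerance of 0.001, filtered at
a minimum occupancy of 0.05, and Hellinger-transformed. On that feature
matrix the package computes:

- Ward-2D / Euclidean cluster dendrograms with multiscale-bootstrap
  **AU/BP** edge support (10,000 replicates per scale by default),
- diagonal-discriminant **t-score feature ranking**,
- **NMDS** (Kruskal stress-1, Bray–Curtis, k = 2) with restarts,
- **betadisper-style dispersion homogeneity** and one-way **PERMANOVA**
  (999 permutations),
- per-species **peak-pattern tables** (minimum frequency 0.8).

A synthetic-spectrum generator (species fingerprints, occurrence
probabilities, intensity variation, mass jitter, decaying baseline,
truncated noise) makes every stage testable offline, and a small genetics
module provides **Kimura 2-parameter distances with complete deletion**
from aligned FASTA.

## Command line

```sh
# simulate a labeled dataset (ASCII spectra + manifest.csv)
maldiclust simulate --species 10 --per-species 10 --seed 1 --out data/

# full analysis bundle: feature matrices, Newick dendrogram with AU|BP
# labels, ranking, NMDS coordinates, test statistics, peak patterns
maldiclust run --in data/ --out results/ --seed 1

# individual stages
maldiclust preprocess data/ --out processed/
maldiclust peaks data/ --out peaks.csv
maldiclust discriminate data/ --out results/

# K2P distance matrix (complete deletion) from an aligned FASTA
maldiclust k2p aligned.fasta --out k2p.csv
```

All parameters live in a flat YAML config (`--config`); the defaults
reproduce the published parameter set (1.5–20 kDa, SNR 6, half-window 7,
tolerance 0.001, minimum frequency 0.05, Ward-2D/Euclidean, 10,000
bootstrap replications, Bray–Curtis k = 2, 999 permutations, pattern
frequency 0.8). A single pipeline seed deterministically derives per-stage
seeds; reruns are byte-identical.

## Layout

```
src/maldiclust/
  spectrum.py     ASCII spectrum dialect, RawSpectrum / PeakList
  simulate.py     synthetic fingerprints, spectra, datasets
  preprocess.py   trim / sqrt / SG smoothing / SNIP / TIC / peak picking
  features.py     peak binning, feature matrix, Hellinger, peak patterns
  distance.py     Euclidean and Bray–Curtis distance matrices
  cluster.py      Ward-2D dendrograms, multiscale-bootstrap AU/BP, Newick
  ranking.py      diagonal-discriminant t-score feature ranking
  ordination.py   NMDS (isotonic disparities + Guttman descent)
  permtests.py    PERMANOVA and dispersion-homogeneity tests
  genetics.py     K2P distances with complete deletion
  config.py       flat YAML pipeline configuration
  pipeline.py     end-to-end orchestration and output bundle
  cli.py          click command line
```
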