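# Methods

## The screen model

A tiled peptide-matrix interaction screen immobilizes fixed-length windows
of a parent protein (here 14-mers, offset 4, so neighbouring spots share 10
residues) plus variants of those windows carrying single post-translational
modifications. After incubation with cell extract, label-free MS yields one
protein × spot intensity table per replicate, with 0 meaning "not detected".
The analytical problem is to separate sequence-specific, motif-mediated
binding from two pervasive artifacts: promiscuous low-level binding spread
across many distant spots, and irreproducible single-spot hits.

The pipeline exploits the tiling geometry: a short linear motif of ≤ 10
residues is fully contained in at least two consecutive windows, so a
genuine interaction produces near-maximal signal on those windows and
attenuated signal on flanking windows where the motif is truncated. The two
filters implement exactly this expectation.

## Pipeline stages and their parameters

1. **Identifier normalization** — UniProt isoform suffixes are stripped;
   rows sharing a normalized id merge by **per-spot maximum** (summing would
   double-count peptides shared between isoforms). MaxQuant contaminant
   (`CON__`) and reverse-decoy (`REV__`, `Reverse`/`Potential contaminant`
   flags) rows are dropped on read.
2. **Replicate integration** — per (protein, spot), the value is the mean of
   the *detected* (nonzero) replicate values; reproducibility is encoded in
   the confidence label (`double`/`single`/`absent`) rather than by shrinking
   the value toward zero. Replicate set membership (SET1/SET2) is raw
   detection before any filtering.
3. **Normalization** — each protein's profile is divided by its own maximum,
   so profiles are comparable in [0, 1] regardless of abundance; all-zero
   profiles are flagged undetected and pass through unchanged.
4. **Outlier filter** — per protein, the threshold is the **nearest-rank
   90th percentile of its detected (nonzero) values** (`outlier_quantile`,
   default 0.90); values **≥ threshold are kept**, the rest zeroed. Detected
   values only: including the structural zeros of a sparse binder would make
   its own threshold trivially 0. The ≥ keep-rule means a constant profile
   survives intact, and ties at the threshold all survive — deliberate, since
   a motif plateau produces near-equal maxima on adjacent spots. The filter
   records its state on the profile; re-applying it is a no-op (a literal
   re-application of the rank rule to its own output would keep shrinking
   the survivor set, so stage idempotence is by state, not by fixed point).
5. **Consecutive-binding criterion** — surviving spots collapse to the
   unmodified tile they coordinate-share with (a surviving PTM-variant marks
   its parent tile); the protein passes if some run of ≥ `min_run` (default
   2) consecutive tiles carries signal. Core interactors = detected in both
   replicates ∧ passing this criterion.

Stage order is fixed (integrate → normalize → outlier → consecutive);
filters only ever remove signal, so per-spot values decrease monotonically
through the cascade and core ⊆ both ⊆ SET1, SET2 on any input.

## Footprints

Maximal runs of surviving tiles map to residue intervals from the first
residue of the run's first tile to the last residue of its last tile;
intervals that overlap in residue space (possible even for runs separated in
tile space, because tiles overlap by 10 residues) are merged. PTM-variant
spots contribute to per-spot accumulated intensities (they are matrix
peptides) but not to footprint intervals, which are defined on the
unmodified tiling. Heatmap row order comes from average-linkage hierarchical
clustering on Euclidean distances between normalized profiles, with rows
pre-sorted by id so the leaf order is permutation-invariant.

## PTM-response classification

Ratios are computed on integrated **raw** intensities (0–1 normalization
within a peptide group would distort them): ratio = I_variant / I_parent.
A variant detected where the parent is not gets ratio = `cap_value`
(default 64, flagged) — capping rather than ∞ keeps downstream clustering
well-defined. A parent detected with an undetected variant gives ratio 0
(binding abolished by the modification); only parent-and-variant-both-zero
is "not detected". With fold threshold δ (default 2; the choice of a
visual-gradient boundary is inherently conventional, so δ is configurable
and echoed in the output): repressed ⇔ all detected ratios ≤ 1/δ, enhanced
⇔ all ≥ δ, independent ⇔ all strictly inside, regulated otherwise. The four
categories partition all evaluable pairs and are invariant to rescaling the
whole group.

## Validation statistics

* **Capture–recapture FDR.** Assume true interactions replicate between
  independent screens while false positives do not. The sensitivity of
  screen B estimated on a high-precision reference R is s_B = |B∩R|/|R|;
  true positives in A ≈ |A∩B|/s_B; hence
  FDR_A = 1 − |A∩B|·|R| / (|A|·|B∩R|), clipped to [0, 1] and undefined when
  B∩R = ∅. The estimator is unbiased when R is drawn independently of the
  screens and false positives land outside R.
* **Hypergeometric enrichment** uses exact integer binomials
  (`math.comb`), avoiding floating-point tail summation; it is checked in
  the tests against both exhaustive subset enumeration (all N ≤ 12) and
  SciPy's survival function.
* **Benjamini–Hochberg** is the standard step-up with a running minimum
  from the largest p downward; cross-checked against statsmodels in tests.
* **Complex ranking.** Screen and IP sets are intersected with the catalog
  background first. Retention: ≥ 1 screen member and ≥ 3 members in the
  union of screen and IP sets (a per-set "each" mode is available; "union"
  is the default reading of a combined-overlap requirement). The two
  criteria — screen coverage % (descending) and Fisher-combined
  hypergeometric p (ascending) — are combined by the **mean of ranks**, a
  deliberately scale-free combination since the two quantities live on
  different scales; ties break by larger complex first, then id. Upper
  quartile = ranks 1..⌊n/4⌋.

## Synthetic screens

The generator plants what the pipeline is designed to find, at the default
study conditions used throughout the tests: a 203-spot design (72 tiles of a
297-residue synthetic parent protein plus 131 single-PTM variant spots),
500 true binders, 1,500 isolated background binders, per-replicate dropout
0.1, multiplicative log-normal noise with CV 0.3.

* A true binder gets a **plateau of 2–4 consecutive tiles at its peak
  intensity** with flanks at 0.5× and 0.2× — the signature of a motif fully
  contained in several windows and truncated in the neighbours. The plateau
  (not a single-peak triangle) is what makes the noise-free pipeline oracle
  exact: the nearest-rank threshold lands on the shared plateau value and
  the ≥ keep-rule retains all its tiles.
* Peak intensities are 10^N(7, 1), spanning ~6 orders of magnitude across
  binders; background binders sit at 10^N(4, 0.5) on one random tile.
* Replicates observe truth × exp(N(0, σ)) with σ = √ln(1 + CV²),
  independently per spot, then lose detected entries with the dropout
  probability.
* When PTM effects are planted, each (binder, covered group) pair draws a
  category; variant spots carry the parent-tile value × 0.1 (repressed),
  1.0 (independent), 8.0 (enhanced), or 8.0 on one variant and 1.0 on the
  rest (regulated; drawn only for groups with ≥ 2 variants, else demoted to
  independent and recorded as such in the truth report).

What the generator does **not** emulate: correlated noise across
neighbouring spots, membrane-position effects, protein-complex
co-enrichment (a complex member dragging its partners onto a spot),
compositional interference between co-binding proteins, and intensity-
dependent missingness (dropout here is intensity-independent). Passing the
synthetic oracles therefore demonstrates the correctness of the filter
logic and the estimators under the stated generative model, not performance
on real MS data.

## Numerical and edge-case choices

* Nearest-rank quantile (⌈q·k⌉-th smallest of k detected values): exact,
  discrete, no interpolation — matches the "remove everything below the
  90 % point of the signal distribution" reading and keeps the filter
  decision reproducible across numeric libraries.
* Isoelectric point: composition-based Henderson–Hasselbalch net charge
  (free termini + K/R/H positive, D/E/C/Y negative), root by bisection on
  pH ∈ [0, 14] to |charge| < 1e−6. The charge is strictly decreasing in pH
  and has opposite signs at the interval ends, so the root exists and is
  unique. The pKa set is named ("EMBOSS" default, "Lehninger" available)
  and recorded in the bias report. GRAVY is the plain mean of
  Kyte–Doolittle hydropathies.
* Bias report: Spearman correlations of per-spot accumulated intensity vs
  GRAVY and vs pI over unmodified spots; a constant covariate (or constant
  accumulation) is reported as not-applicable rather than ρ = 0.
* All-zero profiles flow through every stage unchanged and never enter any
  interactor set. Ranking ties break deterministically (size, then id);
  written tables are sorted, so equal inputs give byte-identical outputs.

## Problem sizes

Tests and the acceptance script run on the 203-spot design with
500 + 1,500 proteins per screen (the default conditions above), 20-seed
Monte-Carlo batches for the FDR estimator (1,000 true interactors,
sensitivity 0.8, 5,000-protein background, |R| = 200), and 10-seed batches
for noisy PTM recovery — sizes at which every check completes in seconds
while exercising the full pipeline.

## Known limitations

* The consecutive-binding criterion with the strict 90 %-outlier filter is
  conservative under replicate noise: when noise breaks the plateau tie,
  only the single maximal spot survives the outlier filter and the protein
  fails the run criterion. Noise-free recall 1.0 degrades to ~0.45 at
  CV 0.3 with 10 % dropout (precision stays at 1.0 in the synthetic
  regression). This mirrors the intended stringency of a "core" set.
* PTM-variant spots share the outlier filter with unmodified spots; a
  strongly enhanced variant can dominate a protein's intensity distribution
  and suppress its unmodified plateau from the core-set decision.
* The capture–recapture FDR assumes R is independent of both screens;
  shared systematic biases between screens and reference inflate apparent
  replication and understate the FDR.
* The bundled default design uses a synthetic 297-residue parent sequence
  (the spot layout of any particular published screen is not
  redistributable); analyses of real screens should supply their own design
  table and FASTA.
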