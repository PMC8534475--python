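# Methods

## The model

The package analyses a two-condition contrast between RNA profiles of the
same microbial community stabilized *in situ* (on site, before retrieval)
and *onboard* (after retrieval). Its working model of retrieval bias is a
**transcriptome-wide multiplicative shift**: for taxon *t* with onboard
multiplier *m_t* ∈ (0, 1], every transcript of *t* has onboard expectation
*m_t* times its in-situ expectation, while individual genes may carry
additional condition-specific multipliers. This is an operational model of
degradation, not a mechanistic RNA-decay model: nothing about decay
kinetics, fragment-length bias, or sequence composition is represented.

On this model the analysis decomposes observed shifts into:

* the **taxon-wide fold change** FC_t = (mean in-situ taxon total) /
  (mean onboard taxon total) = 1/*m_t* on an absolute scale;
* the **per-gene deviation** dev_g = log₂ FC_g − log₂ FC_t, which is zero
  for genes that only follow their taxon's global trend and ±log₂ k for a
  k-fold gene-specific effect. Method-wide scale factors cancel in dev_g,
  which is why flagging is robust to TPM's per-sample renormalization.

### Compositional caveat

TPM sums to 10⁶ per sample, so between-condition TPM ratios mix each
taxon's absolute change with the renormalization constant
Σ_t w_t·m_t. With multipliers (1, 1/1.5, 1/2) this turns absolute folds
(1.0, 1.5, 2.0) into relative folds of roughly (0.72, 1.08, 1.44) — the
stable taxon *appears* to increase, exactly as a stable taxon's relative
abundance rises when others degrade. The package therefore reports both:
absolute fold changes and regression slopes are computed on
length-normalized counts without per-sample rescaling
(`quant.rpk`), and the TPM-scale (relative) fold changes are reported
alongside as the directly observable quantity.

## Synthetic data generator (`synthio`)

The generator emulates the data shapes the pipeline consumes, with ground
truth sufficient to compute every downstream expectation without
re-simulation.

* **Reference database.** One 16S-like sequence per species, evolved along
  a birth-process tree under a Jukes-Cantor-style model (single rate, no
  indels, fixed length — pairwise identity is then positionwise-exact,
  which keeps the clustering oracle exact). Taxa hang off the root on
  0.08-substitutions/site stems; within a taxon, node heights shrink
  geometrically from 0.06 with a floor of 0.045, so between-species
  identity stays safely below the 95 % OTU threshold (~88–93 %) and
  between-taxon identity lower still (~74–79 %). Defaults: 3 taxa × 10
  species × 1500 bp.
* **rRNA arm.** Per-sample expected compositions are Dirichlet-jittered
  (concentration 400) around a base composition (taxon weights 0.45 / 0.30
  / 0.25; geometric 0.75 rank-abundance within taxa); onboard compositions
  are multiplied by the taxon factors and renormalized (degradation acts on
  expectations *before* multinomial sampling). Defaults: 6 in-situ + 7
  onboard samples × 10⁴ reads, matching the study design. Each read yields
  hit rows whose top hit points at the source identifier; with probability
  0.2 the top hit ties across 2–3 same-taxon identifiers (conserved
  region), with probability 0.05 all hits fail exactly one assignment
  criterion, and ~3 % extra junk reads (short, low quality) exercise QC.
  FASTQ is emitted for the rRNA arm only.
* **mRNA arm.** 500 genes per taxon; lengths U(300, 3000) bp; baseline
  expression lognormal(meanlog 3, sdlog 1) fixed per gene across
  conditions; counts Poisson with expectation ∝ baseline × (length/1000) ×
  *m_t* (onboard) × gene multiplier, scaled to ~10⁶ in-situ reads per
  sample, 2 samples per method. No per-sample renormalization is applied to
  the emitted counts — onboard totals genuinely shrink. By default five
  genes per taxon carry a 4-fold onboard-specific multiplier. 86 % of
  features are taxon-annotatable and 50 % KO-annotatable through the
  simulated hit tables (the remainder emulate unannotatable sequences).
  ~5 % of features are CDS-less contigs annotated at contig level.
* **Determinism.** One root seed; each stage derives a child generator at a
  fixed spawn key. Fixed seed ⇒ byte-identical outputs.

**What the generator does not emulate:** sequencing errors, chimeras,
length-heterogeneous references, incomplete reference databases (every
identifier is in the database), correlated gene expression, and real
rank-abundance shapes. Passing tests therefore demonstrate correctness of
the *computations* under the stated model, not robustness to the noise
sources of real libraries.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| assignment thresholds | E ≤ 1e−20, length ≥ 180 bp, identity ≥ 97 % | inclusive at the boundary; the standard operating point of the analysis |
| OTU clustering threshold | 0.95 identity | species-like units; greedy centroid, input ordered by decreasing length then id |
| annotation cutoff | E ≤ 1e−5 | protein-level search cutoff for both taxonomic and functional annotation |
| QC | Q20/Q20, min 200 bp (total RNA); Q26/Q26, min 50 bp (rRNA-depleted) | single-base end-trim windows (see below) |
| Shannon base | 2 | common ecology-toolchain default; natural log by flag |
| UniFrac variant | unnormalized | normalized variant by flag (denominator: depth-weighted tip proportions) |
| PERMANOVA permutations | 999 | p = (#{F* ≥ F}+1)/(n+1) |
| pathway display floor | TPM > 1000 (strict) in ≥ 1 sample | |
| pseudocount | 0.01 TPM | keeps log-ratios finite; zeros are otherwise unaddressed |
| deviation flag threshold | \|log₂\| > 2 | reporting default in `FoldChangeReport` |
| detection operating point | \|log₂\| > 1 | used by the power/FPR study (see below) |
| panel floor | TPM > 50 in all samples | "expressed" call for panel genes |

## Numerical and design choices

* **QC trimming semantics.** External trimmers leave the window semantics
  underspecified; this package uses the simplest rule consistent with the
  flags: drop bases from each end while the single base's quality is below
  the threshold (strict `<`), then length-filter. The rule is idempotent
  and never touches interior bases.
* **Top-hit tie key** is (min E-value, max bitscore) everywhere, with a
  final lexicographic subject-id tie-break (flagged) in annotation so
  results are independent of hit-table row order.
* **Disambiguation** is two-pass with *unambiguous-only* frequencies:
  resolved reads never feed back, making the result order-independent.
  Zero-frequency ties fall back to the lexicographically smallest
  identifier and are flagged, preferring determinism over silent dropping.
* **Faith's PD** is root-inclusive (branches from observed tips up to the
  root), matching the common toolchain convention.
* **PCoA** reports negative eigenvalues but excludes them from the
  proportion-explained denominator and gives their axes zero coordinates;
  no Lingoes/Cailliez correction is applied (transparency over silent
  correction).
* **Mann-Whitney U** uses exact enumeration (count-recursion over rank
  splits) when n₁+n₂ ≤ 20 without ties, else a normal approximation with
  tie and continuity corrections; two-sided by default.
* **PERMANOVA tie tolerance.** Permuted pseudo-F values are compared to
  the observed one with a 1e−9 relative tolerance so permutations that
  reproduce the observed partition count as ties despite summation-order
  rounding; samples are canonically sorted by id before permuting, making
  the result invariant to input order for a fixed seed.
* **PERMANOVA calibration design.** The null study uses groups of 6 and 7
  samples (the study design). With very small equal groups (e.g. 4 + 4)
  the permutation distribution collapses onto ~35 distinct partitions and
  the achievable significance levels become so coarse that the exact
  type-I rate at α = 0.05 sits near 0.03; at 6/7 the 1716 partitions make
  the null p effectively uniform.
* **Effective length = feature length in bp.** The upstream EM
  quantifier's effective-length model is out of scope; the generator uses
  the same definition, keeping recovery exact.
* **Regression through the origin** (slope = Σxy/Σx²) is the default
  because a transcriptome-wide multiplicative shift predicts a
  proportional line; a free-intercept mode exists for diagnostics.
* **Deviation detection operating point.** A 4-fold gene-specific effect
  has expected |log₂ deviation| exactly 2. Flagging at a threshold equal
  to the expected signal would, by symmetry of the sampling noise, detect
  only ~half of such genes, so the power/false-positive study flags at
  |log₂| > 1 — twice the sampling noise scale (~0.1 at these depths) and
  half the signal. The report-level default threshold of 2 is retained for
  conservative flagging of larger-than-4-fold deviations.
* **Heatmap normalization** ("per taxon and sample") is read as one
  z-score per (taxon × sample) vector across pathways; a per-taxon (one
  mean/sd over all that taxon's samples) mode is also implemented.
  Vectors with sd below 1e−9 (constants, single pathways) map to zeros.
* **KEGG panel fixture.** The packaged panel file carries the nine
  stress-response genes (recA K03553, dnaK K04043, hsp90 K04079, clpB
  K03695, clpA K03694, clpX K03544, groEL K04077, rpsA K02945, atpD
  K02112), the markers pmoA K10944 and hupL K06281, sulfur-globule genes
  (tusA K04085, dsrA K11180, dsrB K11181), and the module lists per
  functional category in standard five-digit M-number form.

## Problem sizes

The test suite and acceptance script run everything at the generator's
study conditions: 13 rRNA samples × 10⁴ reads for assignment recovery
(~1.3×10⁵ reads), 3 × 500 genes at ~10⁶-read depth for fold-change
recovery, 100 replicates for detection power/FPR, 500 null simulations ×
999 permutations for PERMANOVA calibration, and a reduced demo community
(4–5 species per taxon, ~10³ reads per sample) for the end-to-end
determinism runs. These sizes were chosen so each study completes in tens
of seconds on one CPU while keeping Monte-Carlo error well inside the
asserted bands.

## Known limitations

* The degradation model is a single per-taxon multiplier; graded decay
  within a taxon, length- or GC-dependent decay, and partial-degradation
  artifacts are not representable.
* Assignment accuracy statements assume the true source is always in the
  reference database; novel-taxon behaviour (best hit to a wrong
  identifier above threshold) is not simulated.
* The toy aligner is adequate for fixed-length, indel-free references; it
  is not a general-purpose aligner, and the greedy clustering inherits the
  usual input-order dependence of centroid methods (the order is fixed and
  documented).
* Mann-Whitney sidedness and the UniFrac normalization variant are
  configurable because the conventional choices vary between toolchains;
  defaults are stated above.
* Gene-level differential-expression significance testing is deliberately
  absent: the decomposition flags deviations descriptively, mirroring the
  analysis this package implements.
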