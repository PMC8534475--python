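# stabilimeta

Comparative metatranscriptomics of host-attached (episymbiotic) microbial
communities under two RNA stabilization regimes: **in situ** (preservative
injected on the seafloor, before retrieval) versus **onboard** (preservation
after the ~3 h trip to the surface). During retrieval, each taxon's RNA pool
can decay at its own rate, so the onboard profile confounds real biology
with taxon-specific, transcriptome-wide degradation. This package
implements the full analysis as a tested pipeline and — because the
deposited raw data and external databases are not required to validate the
computations — ships a synthetic-community generator with known ground
truth that every stage is exercised against.

## What it computes

**rRNA arm.** Reads are quality-trimmed (end trimming at a Phred floor,
minimum-length filter) and assigned to reference 16S identifiers by the
best alignment hit passing inclusive criteria (E ≤ 1e−20, alignment length
≥ 180 bp, identity ≥ 97 %). When the top hit ties across several
identifiers (a conserved region was sequenced), the read is resolved to the
identifier most frequent among unambiguous assignments *of the same
stabilization method* — a parsimony rule. Detected references are clustered
into OTUs by greedy centroid clustering at 95 % identity; OTU abundance is
the sum over member identifiers.

**Diversity.** OTU richness, Shannon diversity (H = −Σ pᵢ log₂ pᵢ),
root-inclusive Faith's PD, weighted UniFrac

d(A,B) = Σ_b ℓ_b · |p_A(b) − p_B(b)|

over branches b, PCoA by double-centering −½D², an exact/approximate
Mann-Whitney U test, and PERMANOVA (pseudo-F, permutation p with 999
permutations) — all written from first principles and verified against
brute-force oracles and scikit-bio.

**mRNA arm.** CDSs (and CDS-less contigs) are taxonomically annotated by
the top hit (min E-value, ties by bitscore) restricted to an allowed taxon
set, and functionally annotated by the top hit's KO (E ≤ 1e−5, no fallback
past a KO-less top hit). Counts become TPM (TPMᵢ = 10⁶·(cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ)),
summed to KOs (with an unannotated remainder, conserving 10⁶ per sample),
then to KEGG modules and pathways (overlapping sets double-count by
design).

**Decomposition.** For each taxon the transcriptome-wide fold change
FC_taxon = (mean in-situ total)/(mean onboard total); per gene the
deviation log-ratio

dev_g = log₂(FC_g) − log₂(FC_taxon)

flags genes that moved against their taxon's global trend. A through-origin
regression of onboard on in-situ means estimates the onboard multiplier
(slope ≈ 1/FC_taxon). TPM is compositional, so absolute fold changes are
recovered on length-normalized, non-rescaled counts; the TPM-scale
(relative) fold changes are reported alongside.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_rrna_assignment.py
python analysis/03_diversity.py
python analysis/04_mrna_quant.py
python analysis/05_compare.py
```

The simulated study has three taxa whose onboard RNA is degraded 1.0×,
1.5× and 2.0×, six in-situ and seven onboard rRNA samples of 10⁴ reads,
and 500 genes per taxon with fifteen injected 4-fold onboard-specific
perturbations. The drivers print, among other things:

```
alpha diversity (mean in_situ vs onboard):
   richness:    30.00 vs    30.00  (Mann-Whitney p = 1.000)
    shannon:     4.33 vs     4.16  (Mann-Whitney p = 0.001)
   faith_pd:     1.69 vs     1.69  (Mann-Whitney p = 1.000)
PERMANOVA on weighted UniFrac: pseudo-F = 21.98, p = 0.001 (999 permutations)

taxon-wide fold changes (in_situ / onboard):
   Methylococcales: recovered 1.469 (truth 1.482); slope 0.675 (truth 0.669)
        Sulfurovum: recovered 1.958 (truth 1.968); slope 0.506 (truth 0.501)
     Thiotrichales: recovered 0.962 (truth 0.964); slope 1.012 (truth 1.010)

flagged genes (|log2 deviation| > 1): 12; 12 of 12 taxon-annotated injected
perturbations (15 injected in total)
```

Read: the same OTUs are present under both regimes (richness and
phylogenetic diversity unchanged) but onboard retrieval skews their
abundances (lower Shannon diversity, clear separation in UniFrac space);
the taxon-wide degradation factors and the per-taxon regression slopes are
recovered within a few percent of ground truth; and the injected
gene-specific effects are the genes flagged against the global trends.

## Layout

```
src/stabilimeta/   synthio (generator + ground truth), qc, align, taxassign,
                   diversity, mrna_annot, quant, compare, experiments,
                   io, pipeline
analysis/          numbered narrative drivers (simulate → … → compare)
tests/             unit + property tests, brute-force oracles, acceptance suite
docs/methods.md    model, parameters, numerical choices, limitations
```
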