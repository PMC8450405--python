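# Methods

## The model

`gagmap` estimates the activity of glycosaminoglycan (GAG) biosynthesis
pathways from bulk gene expression. The premise is the standard
gene–protein–reaction (GPR) reading of a metabolic map: a reaction is
feasible when some enzyme that catalyzes it is expressed, so the transcript
abundance of the catalyzing genes is a proxy for the reaction's capacity.

The curated knowledge base enumerates 29 reactions in five categories —
assembly of the common linker tetrasaccharide and the CS/HS backbones
(12 steps), HS sulfation (5), CS/DS sulfation (5), KS synthesis (4) and HA
synthesis/catabolism (3) — plus auxiliary gene sets (nucleotide-sugar and
PAPS transporters, PAPS synthases, nucleotide catabolism, regulators),
66 distinct genes in total. Each reaction carries a gene group with one of
two aggregation semantics:

* **ALTERNATIVES** (isozymes): reaction activity in a sample is the
  **maximum** TPM over the member genes. Any expressed isozyme suffices.
* **COMPLEX** (obligate subunits): activity is the **minimum** member TPM.
  The only complex in the packaged KB is the EXT1/EXT2 HS polymerase, an
  obligate heteromer; it serves backbone steps 8 and 9 (its two alternating
  transfer activities), so those steps share one gene group.

The chondroitin synthase family (CHSY1/CHSY3/CHPF/CHPF2) polymerizes as
heterocomplexes, but any pairing of the five family proteins is active;
modeling the group as ALTERNATIVES (max approximates "some functional pair
exists") is a documented approximation — a strict pairwise-complex model
would need the second-largest member TPM and abundance assumptions the data
cannot support.

Ties inside a group break to the first-listed gene in KB order, making the
aggregation and its provenance (the contributing gene per reaction and
sample) fully deterministic.

### Knowledge-base provenance and its reconstructed part

The backbone (12 numbered steps) and CS/DS-sulfation (5 steps) memberships
follow the published step legends exactly. The partition of the remaining
12 reactions is not printed anywhere, so the packaged `paper-v1` file
reconstructs it: HS sulfation as 5 steps (NDST1–4; GLCE; HS2ST1; HS6ST1–3;
the seven HS3ST genes), KS as 4 (B3GNT7; CHST5/CHST6; B4GALT4; CHST1) and
HA as 3 (HAS1–3 synthesis; TMEM2 cell-surface depolymerization;
HYAL1/HYAL2/SPAM1 hydrolysis). This is flagged in the KB file header. The
KB is a versioned data file, not code, so membership corrections do not
require a release; the fixed inventory (66/29/5, 12 backbone + 5 CS/DS
steps) is enforced by validation for the packaged version only. Alias pairs
recognized: BPNT2→IMPAD1, CEMIP2→TMEM2, HYAL5→SPAM1.

## Expression input

Values are plain TPM; the package never renormalizes columns. Orientation
(genes in rows vs columns) must be stated by the caller — auto-detection is
refused because silent transposition is a classic corruption bug. Symbol
harmonization upper-cases, resolves KB aliases and collapses duplicate rows
by the per-sample maximum (the isozyme rule applied to redundant annotation
rows); it is idempotent. Xena-style inputs encoded as log2(TPM + 0.001) are
decoded by `2^x − 0.001` with a clamp at 0 for the zero-TPM encoding.
Display tables for boxplots use log2(TPM + 1).

## Tissue profiling

Reaction activities are z-scored per reaction across tissues using the
sample standard deviation (ddof = 1; a population-sd flag exists);
zero-variance rows map to zeros and are flagged rather than producing NaN.
Tissues are clustered agglomeratively on the z-scored activity matrix with
Euclidean distance and complete linkage — the common default of R heatmap
tooling, since the original analysis did not state its linkage — and both
are configurable. Items are label-sorted before linkage so distance ties
resolve identically across runs. Gene co-expression across tissues uses the
Pearson correlation matrix; genes with fewer than 3 samples or zero variance
are dropped and flagged. The published correlation figure used a 56-gene
subset that is never itemized, so the profiling API takes an explicit gene
list rather than guessing.

## Tumor–normal comparison

For each target (gene, or reaction after per-sample aggregation) the fold
change is

    fc = (median(tumor TPM) + 1) / (median(normal TPM) + 1)

with UP called when fc > 1.5 and DOWN when fc < 1/1.5, both strict. The
lower threshold is the exact reciprocal internally (0.667 is a display
rounding), which makes classification antisymmetric under cohort swap. The
pseudocount (default 1, configurable) stabilizes ratios of near-zero
medians at the cost of shrinking the fc of low-expressed genes toward 1;
the raw median ratio is therefore reported alongside as the unbiased
estimator of a multiplicative shift, and parameter-recovery checks assert
on it while direction calls use the pseudocounted classifier.

Reaction-level records aggregate per-sample gene TPM into per-sample
reaction activities first and take medians second. The reverse order
(aggregate the per-cohort gene medians) is available behind a flag for
sensitivity analysis; the two agree when signal is clean but differ under
heavy noise because median and max do not commute.

Significance is the two-sided Wilcoxon rank-sum (Mann–Whitney) test. The
matched-pairs signed-rank test the original description names is impossible
for the cohorts actually compared (unpaired, unequal sizes such as 662
tumors vs 1146 normals), so the unpaired test is the default and the paired
variant is exposed separately for genuinely paired designs. The exact null
is enumerated for tie-free samples up to 25 per arm; larger or tied samples
use the tie-corrected normal approximation. No multiple-testing correction
is applied by default (reports highlight raw p < 1e-4); a
Benjamini–Hochberg flag adds q-values.

Degenerate inputs: empty arms are errors; fewer than 3 observations per arm
is an error for the test; identical cohorts yield fc = 1 and UNCHANGED
everywhere. Genes present in the matrices but absent from the KB (e.g.
proteoglycan core genes such as VCAN and DCN) pass through the gene-level
report with their KB membership flagged.

## Pathway rendering

Diagrams are layered drawings of the KB reaction graph: substrate/product
labels are nodes placed left-to-right by longest-path depth, one arrow per
reaction, labeled with its step number and gene group, colored pink
(#e8a0bf) for UP, green (#7fbf7f) for DOWN, gray otherwise. Colors are
configurable; the semantic mapping, not the hue, is the contract. The
geometry is algorithmic, not a replica of any hand-drawn map, and the SVG
output is byte-identical across runs for identical inputs (no timestamps,
sorted iteration everywhere).

## Synthetic data

The simulators generate the two study designs with planted, recoverable
structure; they exist so every downstream stage is testable without
downloads, and their defaults are the study conditions used throughout the
tests and the acceptance script.

* **Tissue atlas** (`simulate_tissues`): 37 tissues, 20 assigned to a
  HIGH_GAG archetype that adds Δ = 3 (log2) to the 54 biosynthesis-reaction
  genes and 17 to a LOW_GAG archetype; auxiliary genes are
  archetype-neutral. Noise sd 0.3 on the log2 scale.
* **Cohorts** (`simulate_cohorts`): n = 100 per arm, log-normal noise
  sd 0.5; tumor samples multiply the TPM scale of each planted gene by its
  fold change (a log2(fc) mean shift before the noise draw). The planted
  panel used in the analyses — CHST3 4.0, CHST15 3.5, VCAN 4.8, DCN 1.5,
  DSE 0.4 — mirrors the fold-change magnitudes reported for pancreatic
  (up) and breast/prostate (DSE down) tumors, with DCN sitting exactly at
  the UP threshold.

Per-gene baseline log2-TPM means were drawn once from Uniform(0, 8) and
frozen in a packaged fixture (`synthetic_baseline_log2_tpm.json`, covering
the 66 KB genes and a small proteoglycan panel) so that tests are stable
across machines; genes outside the fixture get a seeded per-run draw.
Because the noise is log-normal with median 1 and columns are never
renormalized, a planted fold change is exactly recoverable in expectation
from the raw median ratio.

What the simulators deliberately do not model: count-level noise
(library-size variation, overdispersion, gene length and GC bias),
correlated co-regulation between genes, tumor purity and subtype mixtures,
and batch effects. Passing recovery tests therefore demonstrates the
correctness of the pipeline's arithmetic and decision rules under its own
statistical assumptions — not robustness to the full messiness of real
RNA-seq, which is why the comparison module keeps the real-data entry path
(Xena-encoded matrices) first-class.

## Problem sizes in the checks

The recovery analyses use 200 replicates of 100-vs-100 cohorts over the
~70-gene panel, 20 seeds for the null false-positive control, and 20 seeds
of the 37-tissue atlas for archetype recovery (adjusted Rand index at k=2);
the aggregation oracle runs 100 random 66×10 matrices. These sizes give
stable estimates (the Monte-Carlo error of a median over 200 replicates is
well under the ±15% recovery band) while keeping the whole suite fast.

## Known limitations

* Transcript abundance is a proxy: no post-transcriptional regulation,
  enzyme kinetics, substrate availability or Golgi organization enters the
  score. Reaction activity is a capacity estimate, not a flux.
* The max/min rules ignore isozyme substrate preferences (e.g. the HS3ST
  family members are not interchangeable in vivo).
* The reconstructed HS/KS/HA step partition is one consistent reading of an
  unpublished inventory; the KB file format exists precisely so users can
  ship a corrected version.
* Fold-change classification is threshold-based and unadjusted by default;
  with ~100 targets, raw p-values near the display threshold should be read
  with the optional BH correction in mind.
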