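# Methods

`bacevol` quantifies how per-gene features relate to the rate of protein
evolution in bacterial genomes. This note records the models implemented,
the numerical choices made where the design was open, and what the
synthetic-data experiments do and do not demonstrate.

## Features

One row per gene, one column per feature (Table-1-style abbreviations):

| column | meaning | source in this package |
|---|---|---|
| ER | evolutionary rate, ln(Ka + 0.001) | `evorate` |
| CAI | codon adaptation index, (0, 1] | `codonstats` |
| EL | log-scaled expression level | external table via `io_core` |
| ESS | essentiality flag {0, 1} | external table |
| PPA | number of protein–protein associations | external links table, score ≥ 0.4 |
| MFS | mRNA folding strength, [0, 1] | `mfs` |
| HS | hydropathicity (GRAVY) | `seqprops` |
| AS | aromaticity (frequency of F/Y/W) | `seqprops` |
| LEN | protein length (aa) | `seqprops` |
| RSB | leading-strand flag {0, 1} | `seqprops` + ori/ter |
| TMH | transmembrane helix count | external table |
| SLC/SLM/SLP/SLO/SLE/SLW | localization scores (score if predicted type, else 0) | external table |

Missing cells are empty strings on disk and NaN in memory, never zero. A
species may lack a column entirely (e.g. no expression data); downstream
statistics treat such columns as blank.

## Codon statistics

RSCU is a codon's count divided by its synonymous family's mean count.
Vectors are kept 64-dimensional: stop codons form a 3-member family and
the single-member families (ATG, TGG) are retained, so ordination always
sees the complete codon table; constant columns are tolerated downstream.

CAI follows Sharp & Li. Weights are relative adaptiveness values
`w_c = count_c / max_family_count` on counts pooled over the ribosomal
reference genes (supplied explicitly as an ID list, never auto-detected).
Codons unobserved in the reference get `w = 0.01`, the customary guard
against a zero geometric mean; ATG, TGG and stops are excluded from the
geometric mean because they encode no synonymous choice. Both choices are
configurable.

## Correspondence analysis and CUS

CA is computed by SVD of the standardized residual matrix under the
chi-square metric; genes are the primary cloud in principal coordinates.
Total inertia times the grand total equals the table's Pearson chi-square
statistic (tested against an independent chi-square computation). Axis
signs are fixed by orienting each axis so its largest-magnitude column
coordinate is positive, making outputs deterministic across linear-algebra
backends. All-zero rows (genes with no countable codons) are dropped with
a warning; CA defaults to the per-gene RSCU table, with raw-count mode
available through the same entry point.

CUS (codon usage separation) is the fraction of ribosomal genes falling
outside the reference box of the non-ribosomal cloud on (PC1, PC2):
mean ± 1.64 SD per axis, the two-sided 90% normal range. Per-axis sample
standard deviations (n−1 denominator) are used — the statistic's defining
equation writes a single S, but per-axis spread is what "standard
deviation of the principal component value" measures; a pooled-S variant
is one flag away. A point exactly on the boundary counts as inside;
"outside" means outside on either axis (a rectangular, not elliptical,
criterion). CUS is invariant to translation, uniform scaling and gene
order, and monotone in the separation of the two clouds.

## mRNA folding strength

Windows of 150 nt slide in 10-nt steps over the coding sequence; when the
last regular window stops short of the 3′ end one terminal window is
anchored at `length − window` so every nucleotide is covered, and
sequences shorter than one window get a single whole-sequence window (the
terminal-anchor rule is this package's choice). Each nucleotide's pairing
probability is the number of covering windows in which it pairs divided by
the number of covering windows; MFS is the mean over the mRNA. Only the
CDS is folded — UTRs are not available from a CDS FASTA.

The built-in engine is Nussinov base-pair maximization: AU/GC/GU pairs
(T read as U), minimum hairpin loop of 3 unpaired nucleotides, and a
deterministic traceback (prefer pairing the right end; smallest partner
index on ties). It is exact for the maximum pair count (verified against
exhaustive enumeration up to 18 nt) and fast (numba-compiled fill). A
folding temperature parameter is carried for interface parity but has no
effect — the engine has no thermodynamics. Externally computed structures
(e.g. RNAfold dot-bracket strings per window) plug in via
`DotBracketEngine`.

**Limitation.** A pair-count engine is nearly insensitive to GC content on
random sequences: AU and GU pairs are as countable as GC, so the empirical
association between GC-richness and thermodynamic folding strength is not
reproduced. What the engine does respond to is complementary-partner
availability (tested: balanced G/C folds far more than G-skewed content).
Conclusions about MFS from synthetic runs therefore transfer to
thermodynamic MFS only qualitatively.

## Evolutionary rates

Orthologs between two proteomes are reciprocal best hits under global
protein alignment (BLOSUM62, gap open 11 / extend 1, deterministic
tie-breaking); ties for best hit drop the query. Pairs are retained when
identity ≥ 0.30, coverage ≥ 0.80 (aligned columns over the shorter
sequence — the denominator is configurable), both proteins are strictly
longer than 30 aa, and neither gene is on the horizontal-transfer
exclusion list; an E-value ≤ 1e−5 filter applies only to imported tabular
hits, which carry E-values. Protein alignments are back-translated onto
the original codons (gap residues become `---` codons).

Ka and Ks come from the Nei–Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions (each possible point mutation
contributes 1/3 site; mutations creating a stop codon are excluded from
both classes, reducing that codon's site total below 3), observed
differences averaged over all equally weighted minimal substitution paths
(paths through stop codons are discarded; if all are blocked, all paths
are used), and the Jukes–Cantor correction `d = −(3/4) ln(1 − (4/3) p)`
applied separately to pN and pS. Proportions ≥ 3/4 are flagged saturated
and the rate left missing. ER is `ln(Ka + 0.001)`; the small constant
keeps zero-divergence genes finite and the log base is configurable. When
a gene has several retained partners its ER is the mean across pairs. An
import path accepts externally computed per-pair Ka tables (e.g. from
codeml) in place of the built-in estimator.

## Spearman screen and PCR partitioning

The screen computes Spearman's rho (average ranks for ties; large-sample
t approximation, n−2 df) of each feature against ER on pairwise-complete
observations, flags the species' largest |rho| and marks p > 0.05 as
non-significant; no multiple-testing correction is applied.

PCR (principal component regression) partitions ER variance into
independent per-feature contributions: z-score the complete-case feature
matrix, eigendecompose its correlation matrix, regress ER on all sample
PCs (their R² values add exactly, by orthogonality), and attribute each
component's R² to features by its squared unit-norm eigenvector loadings:

    contribution_j = Σ_k v_jk² · R²_k

Contributions sum to the OLS R² of ER on all features jointly (tested
against a least-squares oracle); proportions normalize them to 1. All PCs
are retained — the goal is orthogonal decomposition, not dimension
reduction. Components with eigenvalue below 1e−10 are null directions and
receive no R². ER is used on its natural-log scale and left unstandardized
(R² is scale-invariant).

**Properties of the attribution worth knowing.** (i) For a correlated
pair whose correlation structure is exchange-symmetric, the attribution
splits the pair's variance exactly 50/50 regardless of which member drives
ER — the 2-block eigenvectors are ±(1/√2, 1/√2) by symmetry. (ii) When
several eigenvalues are nearly equal, the eigenvectors within the
near-degenerate subspace are determined by sampling noise, and some R²
smears onto uninvolved features. Both effects are inherent to the scheme,
not implementation artifacts; the recovery experiments below are designed
around them.

## Synthetic species generator

`simulate_species` produces an ancestral CDS FASTA, a derived FASTA, an
external-feature table and a ground-truth table, byte-identical per seed.
Structure and defaults:

- expression latent `e_g` lognormal(0, 1); measured EL = log e + N(0, 0.5)
  noise (microarray-scale measurement error);
- codon-bias strength `b_g = logistic(α·z(log e) + N(0, 1) + 1.5·ribo)`,
  α = 1 by default. The idiosyncratic term reflects that expression
  explains only part of codon-bias variation in real genomes (empirical
  CAI–expression correlations are ~0.5–0.7); the ribosomal subset is the
  top-expression 5% of genes with an extra bias boost;
- codons drawn per synonymous family with the optimal codon's probability
  `1/k + b_g(1 − 1/k)` (optimal = highest-GC family member, fixed);
- ESS Bernoulli with rate 0.3 tilted by expression (essential genes are
  enriched among highly expressed ones); PPA negative binomial with mean
  5 + 15·ESS (overdispersed); membrane genes (15%, never ribosomal) get
  hydrophobic-tilted residue composition, 1 + Poisson(3) transmembrane
  helices and the SLM score, others SLC (or occasionally SLE);
- genes laid along a circular genome with ori at 0 and ter at the
  midpoint; each gene's strand is chosen so its leading/lagging status
  equals the drawn RSB flag (70% leading);
- divergence `d_g = exp(β₀ + Σ β_j z(feature_j) + ε)`, ε ~ N(0, 0.3),
  β₀ = ln 0.05, clipped to ≤ 0.3 so the counting estimator's
  multiple-hit correction stays adequate. The derived genome receives
  Poisson(d_g · N_sites) nonsynonymous and Poisson(κ·d_g · S_sites)
  synonymous point substitutions (κ = 4), placed uniformly without
  enforcing reversibility; stop codons are never introduced.

What the generator does **not** emulate: real codon tables' species-level
GC bias, operon structure, within-gene rate variation, indels, genuine
HGT, and any particular real species' parameter values. Passing recovery
tests show the pipeline's estimators and statistics behave correctly under
the assumed generative structure — not that the biological conclusions
drawn from real genomes are reproduced.

## Recovery experiments

Two standing experiments (used by the acceptance checks and
`scripts/acceptance.py`):

- **Single driver.** 500 genes, divergence driven only by the codon-bias
  latent (β_CAI = −0.8). The pipeline must recover a negative,
  significant CAI–ER Spearman correlation and rank CAI's PCR proportion
  first. The simulated species carries no expression measurements:
  with a collinear EL column present the 50/50 pair-splitting property
  above makes "CAI first" ill-posed (blank EL columns are a normal
  condition for this analysis).
- **Mixed drivers.** β = {CAI: −1.5, ESS: −0.5, PPA: −0.25, SLM: 0.1},
  500 genes × ~150 codons, proportions averaged over 5 replicate seeds to
  damp eigenvector rotation noise. Tolerance: Spearman rank correlation
  ≥ 0.8 between recovered proportions and |β| over the four targeted
  features — one adjacent swap is allowed because ESS and PPA are
  correlated by construction and the attribution splits their shared
  variance.

Problem sizes (500 genes, 150–300 codons, 5 replicates) keep a full
recovery run around three minutes on one CPU while leaving the Monte-Carlo
tolerances comfortable.

## Numerical and edge-case conventions

- Coordinates 0-based half-open throughout; gene located by its midpoint
  for strand assignment (start-codon mode available); positions exactly at
  ori/ter resolve by the half-open [ori, ter) convention.
- Expression zeros are replaced by half the smallest positive value before
  logging (with a warning); negative values are errors.
- The PPA score cutoff is inclusive (≥ 0.4).
- CA requires ≥ 3 non-empty rows; CUS requires ≥ 1 ribosomal and ≥ 2
  non-ribosomal genes and errors if the non-ribosomal cloud has zero
  variance on both axes.
- Codon columns with gaps, ambiguous bases or stops are excluded from
  NG86; an alignment with no usable columns is an error.
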