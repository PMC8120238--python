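# Methods

This note documents the statistical models behind `smirnet`, the design
choices made where several defensible options existed, what the
synthetic data emulate, and the package's known limits.

## Study design assumed

The pipeline targets a multi-tissue bulk RNA-seq design: `T` tissues
(default TP, HE, TE) × `A` animals (default 4), one library per sample,
mRNAs and small RNAs quantified together in one counts matrix. All
defaults assume the resulting 12-sample layout; every stage accepts
other designs as long as each tissue has at least 2 samples (DE) or 3
samples (within-condition correlations).

## Normalization

**RPKM.** `count / (mapped reads in millions × exon length in kb)`.
Mapped-read totals default to the column sums of the counts matrix
(exon-assigned reads), because true mapped totals are not recoverable
from a counts table; they can be supplied per sample (the synthetic
sample sheets carry a `mapped_reads` column, and the pipeline uses it
when present). Note that with column-sum depths, any purely
multiplicative per-library bias cancels in RPKM by construction; the
mixed model can only recover library effects when an external depth is
given.

**log2.** `log2(RPKM + 1)`; the offset (configurable) keeps zeros finite
and maps 0 → 0.

**Mixed model.** Per observation (gene g, sample s):

    y_gs = μ + L_l(s) + G_g + (GT)_g,t(s) + (GA)_g,a(s) + e_gs

with the library L fixed and gene, gene×tissue and gene×animal random.
Two structural facts make this model cheap at any scale: the only fixed
effect is a sample-level factor, and every random effect is
gene-indexed, so the marginal covariance of the stacked data is
block-diagonal by gene with a single common (samples × samples) block.
The restricted likelihood therefore reduces exactly to algebra on that
block. Variance components are estimated by direct REML — a quasi-Newton
search on log-variances of the block-reduced restricted likelihood
(ftol 1e-6, iteration cap 200); components driven to the boundary are
reported as 0. An EM fixed-point iteration was evaluated first and
rejected: its convergence is sub-linear precisely when a component is
truly zero (the gene×animal term in data without animal effects),
needing thousands of iterations for the same answer. `solve_mme`
provides a dense Henderson mixed-model-equation solver for small
problems and cross-checks.

Only the estimated library effects (constrained to sum to zero) are
subtracted from the data. Gene, tissue and animal structure is left in
place deliberately: the downstream contrasts are between tissues, and
removing tissue effects would erase the signal of interest. The
gene×animal term can be dropped via `drop_animal_interaction`. The model
is fitted jointly across genes with shared library solutions; a
per-gene variant was considered and rejected as it cannot separate
library from noise at 12 samples.

**PCA QC.** Centered (not scaled) SVD of samples × transcripts; signs
fixed by making each component's largest-magnitude loading positive.

## Differential expression

Transcripts are kept when they reach ≥ 2 RPKM in ≥ 3 samples (the
keep-if-expressed reading; both thresholds configurable). Per pairwise
comparison "A/B", log2FC = mean(A) − mean(B) (positive = up in the
first-named tissue). The pooled two-group variance s²_g (df = n₁+n₂−2)
is shrunk toward an empirical-Bayes prior (d₀, s₀²) estimated by the
closed-form method of moments on log s²_g (inverse-trigamma for d₀;
d₀ = ∞ when the observed spread of log s² is at or below its
theoretical minimum). The moderated t uses d₀+d_g degrees of freedom;
d₀ = 0 reduces exactly to the ordinary pooled t. Benjamini–Hochberg
within comparison; DE ⇔ p_adj ≤ 0.05 ∧ |log2FC| ≥ 1 (i.e. fold change
≥ 2; both knobs configurable — the fold-change wording in such studies
is ambiguous between FC ≥ 2 and log2FC > 2, and FC ≥ 2 is taken as the
analysis definition). Tests are two-sided and unpaired; animal blocking
was left out because the standard contrast in this design is unpaired
(the tissues come from the same animals, but the gene×animal term of
the normalization model already absorbs animal-level shifts).

## Regulatory Impact Factor

Regulators are the DE small RNAs of a comparison and targets its DE
mRNAs (same-comparison pairing; a cross-comparison run is possible by
passing an explicit DE table). With e₁ⱼ, e₂ⱼ the mean normalized
expression of target j per condition and r₁ᵢⱼ, r₂ᵢⱼ the within-condition
Pearson correlations (n = 4 each; constant vectors give r = 0):

    PIF_j = ½ (e1_j + e2_j)(e1_j − e2_j)
    DW_ij = r1_ij − r2_ij
    RIF1_i = (1/n_de) Σ_j PIF_j · DW_ij²
    RIF2_i = (1/n_de) Σ_j [(e1_j·r1_ij)² − (e2_j·r2_ij)²]

Raw scores are z-standardized across the regulators of a comparison;
significance at |z| ≥ 1.96 (configurable) in either score, in at least
one comparison. A single regulator (or zero spread) leaves z undefined:
NaN with significant = False.

Statistical floor worth knowing: with 4 samples per condition the null
distribution of a within-condition correlation is uniform on [−1, 1]
(sd ≈ 0.58). A regulator whose targets are a small fraction of the DE
mRNA list cannot beat this noise, whatever its true wiring — the
planted-regulator benchmarks therefore use panels where the module's
targets dominate the DE mRNA list (see below).

## PCIT and the network

For every ordered trio (x, y, z) the three first-order partial
correlations

    r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²))

and the tolerance ε_xyz = mean of the three |partial/direct| ratios are
computed; edge (x, y) is discarded if some z has |r_xy| ≤ |ε·r_xz| and
|r_xy| ≤ |ε·r_yz|. Guards: a denominator factor 1−r² < 1e-12 sets that
partial to 0; a zero direct correlation contributes 0 to ε. The scan is
O(n³) time, O(n²) memory (vectorized over the conditioning node), and
agrees flag-for-flag with a brute-force per-trio oracle. The network
uses edges that are PCIT-significant **and** |r| > 0.95 (the
threshold-only variant is a flag), over the union of DE transcripts
across comparisons using all samples.

Hubs: degree > mean + 2·sd (sample sd, strict inequality); hub
centrality: same rule on exact unnormalized betweenness. Clusters are
connected components, reported largest-first with lexicographic
tie-break.

## Seed sites and duplex energy

Position 1 is the miRNA 5′ nucleotide; the seed is nt 2–7. On the
target read 5′→3′: 6mer = exact reverse complement of the seed;
7mer-m8 adds the match to nt 8 (5′ of the core on the target);
7mer-A1 adds an A opposite position 1 (an A in the target regardless of
the miRNA base); 8mer has both. Every occurrence is reported once under
its most specific type; coordinates are 0-based.

The duplex minimum free energy is a dynamic program over (miRNA
position, target position) pairs, antiparallel, Watson–Crick and G:U
pairs only, no intramolecular structure: consecutive pairs are scored
by a nearest-neighbor stack table, gaps by affine bulge and
internal-loop penalties (≤ 15 nt per side), plus one duplex-initiation
term (+4.1 kcal/mol). The embedded parameter set uses the standard
Watson–Crick nearest-neighbor free energies with a single
representative stack value (−1.25) for any stack touching a G:U pair —
a deliberate simplification that reproduces hybridization energies at
the right scale; the full table can be replaced via a TSV
(`EnergyParameters.from_tsv`). If no structure is stabilizing the
result is 0 with an empty trace. A pair is a confirmed target when it
has ≥ 1 seed site and mfe < −20 kcal/mol. Full cDNA sequences are
scanned (3′UTR-only scanning is a matter of what FASTA is supplied).

## Enrichment

Hypergeometric upper tail P[X ≥ k] per gene set (sets intersected with
the universe; default universe = transcripts passing the expression
filter, the standard over-representation practice), Holm step-down
("Bonferroni step-down") family-wise correction, enrichment-only
(one-sided). Significant terms are clustered by pairwise Cohen's kappa
over query-gene membership indicators; κ ≥ 0.4 links terms and clusters
are connected components; identical vectors get κ = 1 even when chance
agreement saturates.

## Synthetic data

`datagen.simulate_dataset` draws NB counts (variance = μ + μ²·φ,
default φ = 0.02) around a log2-scale mean combining: log-normal
baseline abundance (mean 5, sd 1.5 log2 units); planted DE transcripts
per tissue pair (± half the effect on each tissue of the pair; default
|log2FC| = 2); a regulator module; multiplicative library offsets
(2^offset; default {L1: 0, L2: 0.5}, libraries split across animals);
biological replicate noise (sd 0.15 log2); library sizes 0.8–1.2 M. The
sample sheet records the pre-offset depths as `mapped_reads`, mimicking
a quantifier's mapped-read report: the library bias multiplies the
counts but not that denominator, which is what makes the offset
recoverable.

The regulator module emulates a repressive miRNA like the hub small
RNAs such studies report: one miRNA (default) with 20 mRNA targets, all
repressed (`repressed_target_fraction` re-introduces co-activated
targets), a strong tissue contrast (default 3.5 log2 units, in line
with the ~7-fold changes reported for the strongest hub miRNAs) so the
module enters every TP-contrasting DE list, and a shared per-sample
latent factor confined to the active tissue (default: the first tissue)
creating the differential wiring RIF detects. The factor is
standardized over the active samples so the realized coupling variance
is fixed even at n = 4, and its amplitude is calibrated against the
total log2 noise (biological + NB mixing, φ/ln²2) so the
regulator–target correlation comes out at the configured value
(default 0.95). Mean expression of module members is pinned at
baseline + 1.5 so counting noise does not erode the correlation.

The default biotype mix is a small-RNA-focused panel (10% mRNA, 60%
miRNA, 15% snRNA, 15% snoRNA): as derived above, regulator recovery at
n = 4 is only statistically possible when the planted targets dominate
the DE mRNA list, and z-standardization needs ~30 decoy DE small RNAs
for a stable scale. The mRNA-dominated composition of a real bulk
library (85% mRNA, ~11% small RNAs) is available as
`BULK_BIOTYPE_PROPORTIONS` for composition-focused runs.

Sequences: mature miRNAs are random 22-mers; each planted target embeds
the reverse complement of miRNA nt 2..end plus the t1 base, with the
m8/t1 positions adjusted to realize the requested canonical site type —
so planted pairs carry both an exact seed site and a long helix whose
duplex energy clears −20 kcal/mol by a wide margin. All other target
windows, and the insertion boundaries, are rejection-sampled to contain
no seed match for any planted miRNA. Everything is deterministic given
the seed.

**What passing tests do and do not show.** The generator's noise is
exchangeable across samples within tissue (no batch structure beyond
the library offset, no animal effects, no compositional outliers, no
count-length bias), its DE effects are symmetric two-group shifts, and
its regulator wiring is a single clean latent factor. Recovery results
on these data demonstrate internal consistency of the chain — each
stage finds exactly the structure the generator planted — not
performance on real tissue RNA-seq, where correlated confounders,
unmodeled covariance and annotation error all bite.

## Problem sizes

Defaults were chosen so a full synthetic run (400 transcripts, 12
samples) takes well under a second and the complete test suite plus the
acceptance script run in about a minute: large enough for every
statistical property to be measurable across 20-seed replications,
small enough to iterate on. The implementation itself scales to
thousands of transcripts (the REML step is size-independent; PCIT is
the O(n³) bottleneck over the DE union).

## Known limitations

- Variance components come from one common within-gene covariance
  block; per-gene heteroscedasticity of the random effects is not
  modeled (only the residual prior in the DE stage adapts per gene).
- The duplex model has no dangling-end, terminal-AU or
  loop-sequence-specific terms and one flat G:U stack value; energies
  are on the right scale but not tool-exact.
- RIF significance with few candidate regulators is structurally
  unstable (a z-score over < ~15 values rarely clears 1.96); the
  pipeline emits the raw scores so users can rank instead.
- Enrichment treats gene sets as flat lists: no ontology hierarchy,
  no two-list mode, no term-level trees.
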