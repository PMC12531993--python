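# Methods

## Problem and model

Tumor copy-number variants (CNVs) leave two complementary traces in
single-cell sequencing data: a dosage trace (more or fewer molecules from
the affected region) and an allelic trace (heterozygous SNPs lose their
50/50 balance between the two parental haplotypes when one haplotype gains
or loses copies).  `multiomecnv` infers clonal and subclonal CNVs from
scRNA-seq, scATAC-seq, or both together, by projecting every modality onto
one shared set of genomic bins and decoding both traces jointly.

The genome (per pseudobulk) is modelled as a hidden Markov chain over 15
copy-number states.  Each state carries total copies `c`, paternal copies
`m` and an effective aberrant-cell fraction `f`, which imply

- total dosage `phi = ((1-f)*2 + f*c) / 2` (1 = diploid), and
- paternal haplotype fraction
  `theta = ((1-f)*1 + f*m) / ((1-f)*2 + f*c)` (0.5 = balanced);

the "paternal" haplotype is whichever the phased VCF arbitrarily labels
first.  The state list is: neutral, plus {deletion, copy-neutral LOH (CNLoH),
amplification} x {haplotype up, haplotype down} x {strong `f = 1`, weak
`f = 0.5`}, plus balanced amplification (c = 4, m = 2) and balanced
(homozygous) deletion (c = 0).  Weak states keep diluted events decodable
when normal cells contaminate the pseudobulk; the balanced-deletion state
uses a dosage floor of `phi = 0.05` so its emission stays proper.

### Emissions

Coverage: the count `X_b` of a bin `b` (per modality) is
Poisson-log-normal, `X_b ~ Poisson(N * lambda_b * phi * e^z)` with
`z ~ Normal(-sigma^2/2, sigma^2)`; `lambda_b` is the bin's normalized rate
from a matched cell-type reference profile and `N` the pseudobulk's library
size.  The mean-preserving `-sigma^2/2` offset makes `sigma` a pure
overdispersion knob.  The marginal pmf has no closed form; it is evaluated
with 32-node Gauss-Hermite quadrature **centered at the Laplace mode** of
the integrand.  Fixed (prior-centered) quadrature fails badly for large
counts — the Poisson factor is then far narrower than the prior grid — and
pseudobulk bins routinely hold thousands of counts, so the adaptive
centering is load-bearing, and is pinned by Monte-Carlo and normalization
tests at both small and large rates.

Alleles: the pooled paternal count `a_j` out of depth `d_j` at SNP `j` is
beta-binomial, `a_j ~ BetaBinom(d_j, alpha = theta*gamma, beta =
(1-theta)*gamma)`; `gamma` controls cell-to-cell allelic variability.
State `theta` values at the boundary are clamped to `[1e-6, 1 - 1e-6]`.

### Transitions and phase switches

Between adjacent observations (bins and SNPs interleaved in genome order;
in combined mode the RNA and ATAC counts of one bin are two observations of
the same hidden state), the chain switches copy-number state with total
probability `t` spread uniformly over the other 14 states.  Population
phasing carries switch errors whose rate grows with inter-SNP distance, so
within the retained `1 - t` mass, mirrored (haplotype up/down) state pairs
exchange probability `p(dist) = 0.5 * (1 - exp(-dist/nu))`.  This keeps a
single CNV segment decodable across phase switches: the path flips between
mirror states while the segment's category is unchanged.  Chromosomes are
decoded independently (no inter-chromosome transitions); each chromosome
starts in the neutral state with probability `1 - t`.

### Segments, estimates, classification

The Viterbi path is collapsed into maximal runs of constant category.  Per
segment, `phi_hat` is the 1-D PLN maximum-likelihood dosage and `theta_hat`
the beta-binomial MLE of the major-haplotype fraction (counts oriented by
the decoded phase; balanced segments use a symmetric two-component mixture
so the estimate is phase-free), reported in [0.5, 1].  Segments without
SNPs report `theta_hat = 0.5` flagged low-confidence.

Final event typing does **not** reuse the discrete state labels.  Each
category defines a one-parameter family of `(phi(f), theta(f))` profiles
over the aberrant-cell fraction `f in [0.1, 1]`; the category whose family
passes closest to `(phi_hat, theta_hat)` (squared deviations scaled by
0.10 in `phi` and 0.05 in `theta`) wins, with a deterministic tie-break
(neutral > del > amp > cnloh > bamp > bdel).  Rationale: with a strong
allele track, a 70%-pure deletion (`phi = 0.65`, `theta = 0.77`) sits
between the strong (f=1) and weak (f=0.5) deletion states and the discrete
grid can prefer a CNLoH state on allelic grounds alone; the continuous-f
match types it correctly at any purity.  This replaces aggregated state
posteriors as the classification rule; the posterior route remains
available.

## Pipeline

Per mode (`rna_gene`, `rna_bin`, `atac_bin`, `combined_bin`):

1. features -> bins: genes/peaks go whole to their maximal-overlap bin
   (ties to the lower coordinate) so no molecule is double counted;
   fragments go to the bin containing their midpoint; dropped features are
   ledgered, never silent.  `rna_gene` skips binning and uses gene
   intervals as the coordinate axis.
2. reference: per cell type, up to 1500 annotated normal cells (seeded
   subsample, default seed 123) are summed and normalized per bin; the
   pseudobulk is matched to the reference column (per modality in combined
   mode) maximizing PLN likelihood at `phi = 1` over all bins — a
   non-circular variant of "deviance on presumed-diploid regions".
   Zero-rate bins are excluded per modality and logged.
3. alleles: RNA and ATAC per-cell SNP counts are merged under
   modality-tagged barcodes, phase is attached from the phased VCF
   (haplotype 1 = "paternal"; unphased/homozygous/unknown sites ledgered),
   and counts are pooled into the pseudobulk track.
4. HMM segmentation of the whole-sample pseudobulk, then per-cell event
   log-likelihood ratios (the cell's own counts under the event's
   `(phi_hat, theta_hat)` vs diploid; a cell with no reads in the region
   scores exactly 0), then clone assignment.

### Clone model and refinement

Clones are a flat mixture of binary event genotypes (no phylogeny): cell
log-likelihood under clone `k` is `sum_e [g_ke * log sigmoid(LLR_ce) +
(1-g_ke) * log sigmoid(-LLR_ce)]`.  EM alternates responsibilities with
the closed-form genotype update `g_ke = [sum_c r_ck * LLR_ce > 0]`; clone
0 is pinned all-neutral; `K` is chosen by BIC up to `max_clones` (default
6), with K-means-on-`tanh(LLR/4)` initialization, all seeded.

Refinement re-segments each sizeable clone's own pseudobulk (purer, so
weak events sharpen) and scans for subclonal events invisible in any
existing pseudobulk: per event-free chromosome arm, cells with >= 5 allele
reads on the arm contribute phase-block residuals (`a - d/2` summed over
50-SNP blocks) to a cells x blocks matrix whose first principal component
learns the per-block haplotype orientation — this is what makes the scan
robust to population phase switches, which flip the sign of the raw
residual mid-arm.  A 2- vs 1-component Gaussian mixture on the PC scores
(BIC margin 10, minority >= 10 cells) nominates a candidate subset, which
is confirmed only if its own pseudobulk re-segments into a non-neutral
event spanning >= 30% of the arm with >= 10 SNPs.  Overlapping duplicate
events from different pseudobulks are collapsed, keeping the one with the
strongest allelic imbalance (a subclonal CNLoH diluted into its parent's
pseudobulk masquerades as a weak amplification; the imbalance signal
identifies the real type).  Iteration stops at `max_iter` (default 2), on
unchanged assignments, or when the likelihood would drop on an identical
event set.  Known limitation: two clones carrying *different* true events
on the same locus are collapsed to one event by this rule.

### Annotation and evaluation

Non-neutral segments are merged within chromosome arms when adjacent and
same-status; candidates spanning > 80% of the telomere-trimmed arm (last
10 kb excluded; centromeres excluded by the arm table) are arm-level,
10% < fraction <= 80% focal (cytoband range label), and <= 10% or < 200 kb
dropped.  Boundary reading: exactly 80% is focal, exactly 10% is dropped;
the 200-kb floor applies to the merged span.

Evaluation thresholds WGS-style truth (total CN < 1.3 deletion, > 2.5
amplification; optionally minor CN < 0.3 at neutral total = CNLoH) and
computes length-weighted precision (overlap / predicted CNV length),
recall (overlap / truth CNV length) and F1, overall and stratified by
status or scope.  Balanced-amplification predictions count toward
amplification truth because total-CN truth cannot separate them; a strict
mode disables this.  Empty predictions give precision NaN (recall 0); an
event is "detected" by a mode when its recall is >= 0.8.

## Default parameters

| parameter | default | meaning / why |
|---|---|---|
| bin size | 220 kb (hg38 default bin set), 500 kb (synthetic genome) | ~one expression unit per bin; synthetic genome is desk-scale |
| `t` | 1e-5 | state-switch probability; segments are megabase-scale |
| `gamma` | 20 | beta-binomial concentration of the pooled allele track |
| `sigma` | 0.3 per modality | PLN overdispersion; conservative for deep pseudobulks |
| `nu` | 1e7 bp | phase-switch length scale (matches the simulator's switch process) |
| telomere trim | 10 kb | telomeric scraps excluded from arm fractions |
| reference cap | 1500 cells/type, seed 123 | reference subsampling |
| `max_clones` | 6 | BIC search range |
| `min_cells` | 20 | clone size floor |

`t`, `gamma`, `sigma` and `nu` are tuning constants of this
implementation, not literature-printed values; they are logged with every
run and overridable via config.

## Synthetic data: what it emulates, and what it does not

The generator draws per-cell bin counts from the same PLN family the HMM
assumes (library sizes log-normal; baselines heavy-tailed log-normal with
a zero-inflated dead-bin fraction, higher for ATAC), and per-cell SNP
depths thinned from the cell's own bin coverage (so CNVs dose the allele
depth too), with beta-binomial paternal counts, a 0.5% symmetric
read-level allele error, and a phased VCF whose per-gap switch probability
follows the same exponential law the HMM models.  Everything derives from
one seed; identical configs are byte-identical.

Default study conditions: a six-chromosome 360-Mb genome (60 Mb each, 3-Mb
centromere), 500-kb bins, SNPs every ~40 kb, 250 cells per modality, 30%
normal contamination, one tumor clone with 8 events per sample spanning
amp/bAmp/del/CNLoH at arm and focal scale, allele capture 0.05 (RNA) /
0.12 (ATAC) of bin counts.  The minor-subclone scenario plants a
subclone-private arm-level CNLoH in 15% of tumor cells and sets allele
capture to 0.004 (RNA) / 0.08 (ATAC): scATAC covers heterozygous SNPs
genome-wide while scRNA concentrates in expressed exons, and this order-of
-magnitude gap is the mechanism the scenario isolates.

Because generator and model share distributional families, passing
benchmarks demonstrate correct inference *given the model*, not robustness
to model misspecification.  Real data add, and these fixtures omit:
ambient contamination, doublets, expression covariance between neighboring
genes, mappability and GC artifacts, allele-specific expression unrelated
to CNVs, and reference cell types mismatched to the tumor's lineage.  The
desk-scale genome also makes arm fractions coarser than hg38's.

## Numerical choices

- PLN quadrature: 32 Laplace-mode-centered Gauss-Hermite nodes; Newton
  mode search (30 iterations, step clamp 2.0).
- Forward-backward uses scaled probability-space recursions; Viterbi works
  in log space.  Brute-force path enumeration over 15^5 states is the
  decoding oracle in tests.
- MLEs by bounded scalar minimization: `phi` in [0.05, 4], `theta` in
  [0.5, 1 - 1e-6].
- Ties: feature-to-bin ties go to the lower-coordinate bin; arm-assignment
  ties to p; category ties follow the fixed order above.  Degenerate
  inputs (all-zero LLR matrix, empty cell subsets, empty tracks) raise or
  return the single normal clone explicitly rather than propagating NaNs.

## Scale of the shipped experiments

The test-suite and acceptance benchmarks run the six-sample cohort at 250
cells/modality on the 360-Mb genome and the subclone comparison over ten
seed families — sizes chosen so a complete from-scratch reproduction runs
in minutes on a laptop core while keeping every per-sample decision
(segmentation, typing, clone recovery) at realistic signal-to-noise.
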