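# Methods

## Model and procedure

The pipeline treats extended homozygosity as a region-level genomic variant.
For each subject, a **tract of homozygosity (TOH)** is a maximal run of
consecutive SNP calls on one chromosome whose first and last calls are
homozygous and non-missing, containing at most `max_het` heterozygous and
`max_missing` missing calls, and meeting a size criterion: at least
`min_snps` SNPs (L), or — when `min_kb` is set — a bp span of at least
`min_kb` together with at least `min_snps_if_kb` SNPs. *Maximal* means no
qualifying run of the same subject strictly contains it. Maximal runs are
reported instead of every qualifying sub-window because the downstream
accumulation step only consumes per-SNP coverage, and maximal runs induce
exactly the same coverage; overlapping sub-runs would be redundant.

**cTOH accumulation.** Per-SNP TOH coverage is summed over subjects; a cTOH
is a maximal run of at least `min_snps` consecutive same-chromosome SNPs
each covered by at least `min_subjects` TOH calls. The source text for this
rule mixes "more than n" with "n or more"; the count ≥ n reading is used
because it matches the operational genome-wide SNP count reported alongside
it. A subject is *present* for a cTOH when any of its TOHs overlaps it by
at least one SNP (no minimum overlap fraction at this level).

**Cluster tree (gTOH/aTOH).** Within one cTOH, member TOHs are grouped by
repeated binary spectral clustering. The similarity matrix S is built from
one of two kernels:

* positional (gTOH): s_ij = min(o_ij/l_i, o_ij/l_j), with o_ij the overlap
  length and l_i, l_j the member lengths. This is exactly the pairwise gTOH
  criterion that the overlap cover at least a fraction γ of each member's
  length. An
  alternative kernel o²/(l_i·l_j) is available by configuration. Lengths
  are SNP counts by default; bp mode by flag. Both choices are exposed as
  configuration rather than constants because the kernel definition is the
  one genuinely open design point of the method.
* allelic (aTOH): 0 if min(o/l_i, o/l_j) < γ (default 0.5), else the
  fraction of overlap SNPs at which both subjects are homozygous,
  non-missing, and carry the same allele.

Each split is Ng–Jordan–Weiss normalized spectral clustering with k = 2:
D = diag(row sums of S), L_sym = I − D^{−1/2} S D^{−1/2}; the eigenvectors
of the two smallest eigenvalues form the embedding, rows are normalized to
unit Euclidean norm, and k-means (k = 2, 10 restarts, best inertia, seeded)
assigns sides. The symmetric-normalized variant is used because the
row-normalization step is the NJW signature. Members with all-zero
off-diagonal similarity are split off as one side before the
eigendecomposition (a node of mutually disjoint tracts degenerates to
singleton peels, which the reporting gate then drops).

A node becomes a leaf when: depth = `max_depth` (default 100), or it holds
fewer than `min_node_size` members (default 5), or the summary statistic of
its pairwise similarities — `minimum`, `lower_quartile` (default) or `mean`
— strictly exceeds `threshold` (default 0.75). Leaves with at least
`min_report_size` members (default 2) **and** statistic ≥ threshold are
reported (strict ">" at stopping, "≥" at reporting, both on the same
statistic; a node can become a leaf via the size rule while loose, and the
reporting gate is what keeps such leaves out of the output).

**Region boundaries.** A reported region's bounds are quantiles of its
members' start and end positions, to avoid extreme boundaries contributed
by outlier members. The shipped default is the *interior* pair — quantile
0.75 of starts and 0.25 of ends — with the *literal* lower-quartile pair
(0.25, 0.25) available as `boundary_mode="literal"`; the interior pair is
the default because only it pulls both bounds inward. Quantiles use linear
interpolation between order statistics everywhere (similarity lower
quartile included), and interpolated bounds are snapped inward to actual
member SNP positions (start: next member start at or above the quantile;
end: previous member end at or below it), so reported boundaries are real
SNPs. If the two interior quantiles cross on a tiny leaf, the bounds fall
back to member medians.

**Association.** Presence of each surrogate region is a binary predictor of
case-control status. When every observed 2×2 cell is ≥ 5, a logistic model
adjusting for covariates (age; sex; smoking as indicator contrasts against
the never-smoker reference) is fitted and the Wald test on the presence
coefficient reported, with OR = exp(β) and CI = exp(β ± 1.96·SE). Any cell
< 5 dispatches to Fisher's exact test: the two-sided p is the
point-probability rule (sum of fixed-margin tables no more probable than
the observed one — this, not doubling the one-sided tail, reproduces the
reference values for zero-cell tables), the OR is the conditional MLE of
the noncentral hypergeometric odds parameter, and the 95% CI inverts the
exact conditional tails at 0.025 per side; zero-cell tables report OR 0 or
+∞ with the corresponding one-sided exact bound. The "< 5" rule is applied
to *observed* cells for determinism. Separation or non-convergence of the
logistic fit falls back to Fisher with a warning. A Benjamini–Hochberg
column is available but off by default; the primary output is raw p-values
against a significance cut.

**Calibration.** The chance-run length is the smallest integer L with
n_subjects × n_snps × p_hom^L < α (default α = 0.05): an expected-count
bound on runs of L consecutive chance homozygotes across all subjects and
SNP positions, assuming independent SNPs with a genome-wide homozygosity
rate p_hom. This product form uniquely reproduces the reference value
L = 58 at p = 0.665, 1618 subjects and 514,355 SNPs (a per-genome-only
version gives 40). LD is handled separately by deflating L by the
tag-group fraction (round-half-up: 58/0.63 → 92); haplotype-block and
tag-SNP estimation are *not* reimplemented — their summary numbers are
inputs. `toh_length_quantiles` supports the empirical route: rescan with a
permissive L, then take linear-interpolation quantiles of observed tract
lengths.

## Coordinates and conventions

Map bp positions are 1-based; all regions are closed intervals
[first member SNP bp, last member SNP bp], so a region's bp length is
end − start + 1. Internal SNP indices are 0-based per chromosome. Allele
tokens are any single non-whitespace string except "0" (missing), so ACGT
and 1/2/3/4 dialects both pass; a call is missing iff either allele is "0",
and missing calls are never counted as homozygous. Per-call allele order
carries no meaning.

## Synthetic generator

`tohkit.synthetic` emulates the data structure the method assumes:
independent per-SNP Hardy–Weinberg genotypes (fixed or uniform-range MAF;
a target homozygosity rate r ≥ 0.5 maps to the fixed MAF
q = (1 − √(2r − 1))/2, e.g. r = 0.665 → q = 0.2128), planted homozygous
tracts shared by chosen carriers with independent Gaussian boundary jitter
per carrier and per end, three allele-match patterns (`matched`,
`two_groups` with complementary patterns, `random`), optional het/missing
noise inside tracts, and a logistic disease model on tract carriage and
covariates. Default conditions in tests: 200 subjects × 5,000 SNPs,
background homozygosity 0.665, planted 150-SNP tracts with 12 carriers and
jitter SD 3 SNPs — tract length, carrier fraction (6%) and background rate
chosen to mirror a realistic SNP-array homozygosity study at fixture scale.

What it does **not** emulate: linkage disequilibrium (no haplotype copying
or recombination maps), allele-frequency ascertainment, genotyping batch
effects, or population structure. Passing recovery tests therefore shows
the pipeline is correct under its own model — independent SNPs with planted
signal — not that real-data LD cannot produce short spurious tracts; the
calibration utilities exist precisely because real data need a larger L
than the independence bound suggests.

## Numerical choices

* Scanner: two-pointer sweep over budget-feasible windows (allowance and
  gap constraints are hereditary), each maximal window trimmed to
  homozygous endpoints, then nested runs dropped. Verified against
  exhaustive O(n²) enumeration.
* Spectral: eigendecomposition via symmetric `eigh`; k-means seeded per
  node through a SeedSequence derived from the run seed and the node's
  path, so trees are reproducible and independent of sibling order. The
  first member's side is listed first (tie-break by first index). A
  degenerate single-cluster k-means outcome falls back to a deterministic
  first-vs-rest peel.
* Exact test: scipy's point-probability two-sided p and conditional-MLE OR
  back the implementation; both are cross-checked in the test suite against
  independent oracles (exact rational hypergeometric enumeration; dense
  log-grid + golden-section refinement of the conditional likelihood).
* Chance-run length: closed form via logs, then verified and adjusted at
  the integer boundary against float roundoff so the returned L is exactly
  the crossing point.
* Determinism: identical inputs, parameters and seed give byte-identical
  outputs across the CLI pipeline (asserted in tests).

## Problem sizes in the test suite

Unit oracles run on chromosomes of ≤ 500 SNPs (200 random replicates for
the scanner), exhaustive exact-test enumeration on all 2×2 tables of total
≤ 26 plus 400 random larger tables, exhaustive normalized-cut comparison on
instances of ≤ 12 members, end-to-end recovery on 200 × 5,000 fixtures, and
2,000 permutation replicates (1000 cases/1000 controls, 60 carriers) for
the type-I error check — sizes at which every oracle is exact and the whole
suite completes in a few minutes on one core.

## Known limitations

* No LD-aware TOH calling (no genotype-likelihood/HMM model as in some ROH
  callers); density is only guarded by the optional `max_gap_kb` rule.
* cTOH calling is not case/control-stratified or frequency-weighted.
* The association stage offers no genome-wide permutation FWER control or
  population-structure correction.
* Binary PLINK (.bed/.bim/.fam) and VCF inputs are not supported; the text
  .ped/.map dialect only.
* k > 2 splits and alternative clustering backends are out of scope; the
  binary tree with k = 2 is the method.
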