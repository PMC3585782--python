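# tohkit

Detection of tracts of homozygosity (TOH) from SNP-array genotypes, their
aggregation into *surrogate-TOH* regions, and case-control association
testing of those regions — for homozygosity-mapping studies where the signal
of interest is a chromosomal segment shared in the homozygous state by many
subjects, rather than a single SNP.

A TOH is a maximal run of consecutive homozygous SNP calls in one subject on
one chromosome, subject to a minimum length *L* (SNPs or kb) and small
allowances for interior heterozygous/missing calls. Because individual
tracts have noisy, subject-specific boundaries, downstream analysis works on
three surrogate regions:

* **cTOH** — a maximal stretch of ≥ *L* consecutive SNPs, each covered by TOH
  calls in at least *n* subjects (default *n* = 10);
* **gTOH** — within a cTOH, a group of tracts whose pairwise overlap is a
  high fraction of each member's length (proximal boundaries), found by a
  repeated binary spectral-clustering tree with the positional kernel
  s<sub>ij</sub> = min(o<sub>ij</sub>/l<sub>i</sub>, o<sub>ij</sub>/l<sub>j</sub>);
* **aTOH** — the same construction with an allelic kernel (fraction of
  overlap SNPs at which both subjects carry the same homozygote), isolating
  allele-matched subgroups.

The cluster tree applies Ng–Jordan–Weiss normalized spectral clustering with
k = 2 recursively: D = diag(Σ<sub>j</sub> s<sub>ij</sub>),
L<sub>sym</sub> = I − D<sup>−1/2</sup> S D<sup>−1/2</sup>, the eigenvectors
of the two smallest eigenvalues are row-normalized and split by k-means. A
node stops splitting when the lower quartile (configurable) of its pairwise
similarities exceeds a threshold (default 0.75), when it holds fewer than 5
tracts, or at the maximum depth. Each region's presence/absence per subject
is then tested against case-control status: a covariate-adjusted logistic
model with a Wald test when every 2×2 cell is ≥ 5, otherwise Fisher's exact
test (point-probability two-sided p, conditional-MLE odds ratio, exact CI).

Inputs are PLINK-style text `.ped`/`.map` files plus a tab-separated
phenotype table (`fid iid status age sex smoking`). A synthetic generator
produces fixtures with planted tracts and known ground truth for every
stage.

## Worked example

```python
from tohkit import (
    SimSpec, PlantedTract, simulate, ScanParams, scan_all, homozygosity_rate,
    CtohParams, call_ctoh, toh_call_counts, ClusterParams, cluster_all, test_regions,
)

# 200 subjects x 5,000 SNPs at background homozygosity 0.665, with two
# planted 150-SNP tract groups (12 carriers each, boundary jitter sd 3 SNPs);
# the first locus raises its carriers' disease log-odds by 2.
spec = SimSpec(
    n_subjects=200, n_snps=5000, seed=11,
    tracts=(
        PlantedTract(1000, 1149, tuple(range(12)), jitter_sd=3.0, effect=2.0),
        PlantedTract(3000, 3149, tuple(range(50, 62)), jitter_sd=3.0),
    ),
)
sim = simulate(spec)
print(f"homozygosity rate: {homozygosity_rate(sim.genotypes):.3f}")

tohs = scan_all(sim.genotypes, sim.snp_map, ScanParams(min_snps=100))
print(f"TOHs detected: {len(tohs)}")

ctohs = call_ctoh(toh_call_counts(tohs, sim.snp_map), sim.snp_map, CtohParams(), tohs)
print(f"cTOH regions: {len(ctohs)}")

gtohs = cluster_all(ctohs, tohs, "gtoh", ClusterParams(), sim.snp_map,
                    seed=17, genotypes=sim.genotypes)
for res in test_regions(gtohs, sim.phenotypes):
    reg = gtohs[res.region_id]
    print(f"gTOH {reg.start_snp}-{reg.end_snp} ({reg.n_snps} SNPs): "
          f"{res.n_cases_present}/{res.n_controls_present} carriers, "
          f"p={res.p_value:.4f}, OR={res.odds_ratio:.2f} ({res.test})")
```

prints

```
homozygosity rate: 0.666
TOHs detected: 24
cTOH regions: 2
gTOH rs1002-rs1148 (147 SNPs): 10/2 carriers, p=0.0160, OR=5.76 (fisher_exact)
gTOH rs3000-rs3146 (147 SNPs): 8/4 carriers, p=0.2406, OR=2.22 (fisher_exact)
```

Both planted loci are recovered as gTOHs with all 12 carriers present
(10 cases/2 controls at the risk locus, whose carriers were simulated with
elevated disease odds; 8/4 at the neutral one). Small carrier counts
dispatch to Fisher's exact test; the risk locus reaches p = 0.016 with an
odds ratio of 5.8.

The same pipeline runs from the shell:

```bash
tohkit simulate --spec spec.json --out-prefix sim
tohkit run-all --ped sim.ped --map sim.map --pheno sim.pheno.tsv \
    --seed 17 --out-dir results/
tohkit calibrate chance --p-hom 0.665 --subjects 1618 --snps 514355 \
    --tag-fraction 0.63
```

`run-all` writes `tohs.tsv`, `ctohs.tsv`, `gtoh.tsv`, `atoh.tsv` and the
per-kind association tables; `calibrate chance` prints the minimum run
length whose genome-wide chance-homozygosity likelihood falls below 5%
(58 at the conditions above) and its LD-adjusted version (92 at tag-group
fraction 0.63).

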