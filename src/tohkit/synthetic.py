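"""Synthetic diploid genotype fixtures with planted homozygous tracts.

Emulates the data the pipeline consumes: PLINK-style diploid genotypes with
per-SNP allele frequencies under Hardy-Weinberg, planted homozygous tracts
shared by chosen carriers (with controllable boundary jitter, allele-match
pattern, and het/missing noise), a case-control phenotype table whose status
is generated by a logistic model on tract presence and covariates, and a
ground-truth record for end-to-end recovery checks.

The background homozygosity rate is controlled through the minor-allele
frequency: a fixed MAF q gives rate (1-q)^2 + q^2, so a target rate r >= 0.5
is hit by q = (1 - sqrt(2 r - 1)) / 2 (r = 0.665 -> q = 0.2128).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .io_plink import (
    GenotypeMatrix,
    PED_SAMPLE_COLUMNS,
    PhenotypeTable,
    SnpMap,
    write_ped_map,
)

ALLELES = ("A", "C")


def maf_for_hom_rate(rate: float) -> float:
    """Fixed MAF whose Hardy-Weinberg homozygosity rate equals ``rate``."""
    if not 0.5 <= rate < 1:
        raise ValueError("achievable homozygosity rates are in [0.5, 1)")
    return (1.0 - np.sqrt(2.0 * rate - 1.0)) / 2.0


@dataclass(frozen=True)
class PlantedTract:
    """One planted locus: a homozygous span shared by the listed carriers.

    pattern: "matched" (all carriers share one allele pattern), "two_groups"
    (carriers split in half with complementary allele patterns — invisible to
    the positional kernel, split by the allelic one), or "random" (each
    carrier its own pattern). ``jitter_sd`` is the SD (in SNPs) of the
    independent Gaussian jitter applied to each carrier's start and end.
    ``effect`` is the per-carrier log-odds added to the disease model.
    """

    start_idx: int
    end_idx: int
    carriers: tuple[int, ...]
    pattern: str = "matched"
    jitter_sd: float = 0.0
    het_noise: float = 0.0
    missing_noise: float = 0.0
    effect: float = 0.0

    def __post_init__(self) -> None:
        if self.start_idx > self.end_idx or self.start_idx < 0:
            raise ValueError("invalid planted span")
        if self.pattern not in ("matched", "two_groups", "random"):
            raise ValueError("pattern must be matched|two_groups|random")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated chromosome."""

    n_subjects: int = 200
    n_snps: int = 5000
    chrom: str = "1"
    maf: Union[float, tuple[float, float], None] = None
    target_hom_rate: float = 0.665
    spacing_bp: int = 6000
    tracts: tuple[PlantedTract, ...] = ()
    baseline_logit: float = 0.0
    age_beta: float = 0.0
    sex_beta: float = 0.0
    smoking_betas: tuple[float, float] = (0.0, 0.0)  # former, current vs never
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.tracts:
            if t.end_idx >= self.n_snps:
                raise ValueError("planted span outside chromosome")
            if any(c < 0 or c >= self.n_subjects for c in t.carriers):
                raise ValueError("carrier index outside subject range")
        # overlapping loci sharing a carrier would need contradictory alleles
        for i, a in enumerate(self.tracts):
            for b in self.tracts[i + 1 :]:
                if a.start_idx <= b.end_idx and b.start_idx <= a.end_idx:
                    shared = set(a.carriers) & set(b.carriers)
                    if shared:
                        raise ValueError(
                            f"overlapping planted loci share carriers {sorted(shared)}"
                        )


@dataclass
class TruthCluster:
    """Ground truth for one intended output cluster."""

    cluster_id: str
    tract_index: int
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    carriers: list[int]
    subjects: list[str]
    realized_spans: dict[int, tuple[int, int]]


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    snp_map: SnpMap
    phenotypes: PhenotypeTable
    truth: list[TruthCluster]


def _draw_background(rng, n_subjects, n_snps, maf, target_hom_rate) -> tuple[np.ndarray, np.ndarray]:
    if maf is None:
        q = np.full(n_snps, maf_for_hom_rate(target_hom_rate))
    elif isinstance(maf, tuple):
        q = rng.uniform(maf[0], maf[1], size=n_snps)
    else:
        q = np.full(n_snps, float(maf))
    draws = rng.random((n_subjects, n_snps, 2)) < q[None, :, None]
    alleles = np.where(draws, ALLELES[1], ALLELES[0]).astype("U8")
    return alleles, q


def simulate(spec: SimSpec) -> SimResult:
    """Generate genotypes, map, phenotypes and ground truth for one spec.

    Fully reproducible: the same spec (including seed) yields identical
    output, file for file.
    """
    rng = np.random.default_rng(spec.seed)
    alleles, _ = _draw_background(
        rng, spec.n_subjects, spec.n_snps, spec.maf, spec.target_hom_rate
    )
    positions = (np.arange(spec.n_snps) + 1) * spec.spacing_bp
    snp_map = SnpMap(
        pd.DataFrame(
            {
                "chrom": spec.chrom,
                "snp_id": [f"rs{j + 1}" for j in range(spec.n_snps)],
                "cm": 0.0,
                "bp": positions.astype(np.int64),
            }
        )
    )

    truth: list[TruthCluster] = []
    tract_effect = np.zeros(spec.n_subjects)
    for k, tract in enumerate(spec.tracts):
        span_len = tract.end_idx - tract.start_idx + 1
        base_pattern = np.array(
            [ALLELES[i] for i in rng.integers(0, 2, size=span_len)], dtype="U8"
        )
        groups: dict[str, list[int]] = {}
        realized: dict[int, tuple[int, int]] = {}
        half = len(tract.carriers) // 2
        for ci, carrier in enumerate(tract.carriers):
            if tract.pattern == "matched":
                pattern = base_pattern
                gid = f"t{k}"
            elif tract.pattern == "two_groups":
                if ci < half:
                    pattern, gid = base_pattern, f"t{k}.0"
                else:
                    flipped = np.where(base_pattern == ALLELES[0], ALLELES[1], ALLELES[0])
                    pattern, gid = flipped.astype("U8"), f"t{k}.1"
            else:  # random
                pattern = np.array(
                    [ALLELES[i] for i in rng.integers(0, 2, size=span_len)], dtype="U8"
                )
                gid = f"t{k}"
            s = tract.start_idx + int(round(rng.normal(0, tract.jitter_sd)))
            e = tract.end_idx + int(round(rng.normal(0, tract.jitter_sd)))
            s = min(max(s, 0), spec.n_snps - 1)
            e = min(max(e, s), spec.n_snps - 1)
            # the pattern is anchored to the planted span; jittered extensions
            # reuse the edge allele so carriers stay allele-consistent inside
            idx = np.arange(s, e + 1)
            rel = np.clip(idx - tract.start_idx, 0, span_len - 1)
            alleles[carrier, s : e + 1, 0] = pattern[rel]
            alleles[carrier, s : e + 1, 1] = pattern[rel]
            for j in idx:
                r = rng.random()
                if r < tract.missing_noise:
                    alleles[carrier, j] = ("0", "0")
                elif r < tract.missing_noise + tract.het_noise:
                    alleles[carrier, j] = ALLELES
            realized[carrier] = (s, e)
            groups.setdefault(gid, []).append(carrier)
            tract_effect[carrier] += tract.effect
        for gid, members in sorted(groups.items()):
            truth.append(
                TruthCluster(
                    cluster_id=gid,
                    tract_index=k,
                    start_idx=tract.start_idx,
                    end_idx=tract.end_idx,
                    start_bp=int(positions[tract.start_idx]),
                    end_bp=int(positions[tract.end_idx]),
                    carriers=list(members),
                    subjects=[f"S{c + 1}" for c in members],
                    realized_spans={c: realized[c] for c in members},
                )
            )

    subject_ids = [f"S{i + 1}" for i in range(spec.n_subjects)]
    age = rng.normal(60.0, 8.0, size=spec.n_subjects)
    sex = rng.integers(1, 3, size=spec.n_subjects)  # 1 male, 2 female
    smoking = rng.choice(
        ["never", "former", "current"], p=[0.2, 0.4, 0.4], size=spec.n_subjects
    )
    logit = (
        spec.baseline_logit
        + tract_effect
        + spec.age_beta * (age - 60.0) / 10.0
        + spec.sex_beta * (sex == 2)
        + spec.smoking_betas[0] * (smoking == "former")
        + spec.smoking_betas[1] * (smoking == "current")
    )
    status = (rng.random(spec.n_subjects) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(spec.n_subjects)],
            "iid": subject_ids,
            "father": "0",
            "mother": "0",
            "sex": sex.astype(str),
            "phenotype": (status + 1).astype(str),  # ped convention 1/2
        },
        columns=PED_SAMPLE_COLUMNS,
    )
    genotypes = GenotypeMatrix(samples, alleles)
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {
                "fid": samples["fid"],
                "iid": subject_ids,
                "status": status,
                "age": np.round(age, 2),
                "sex": sex,
                "smoking": smoking,
            }
        )
    )
    return SimResult(genotypes, snp_map, phenotypes, truth)


def write_sim(result: SimResult, out_prefix: str) -> dict[str, str]:
    """Write .ped/.map/pheno/truth files for a simulation; returns the paths."""
    paths = {
        "ped": f"{out_prefix}.ped",
        "map": f"{out_prefix}.map",
        "pheno": f"{out_prefix}.pheno.tsv",
        "truth": f"{out_prefix}.truth.json",
    }
    write_ped_map(result.genotypes, result.snp_map, paths["ped"], paths["map"])
    result.phenotypes.df.to_csv(paths["pheno"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            [
                {
                    "cluster_id": c.cluster_id,
                    "tract_index": c.tract_index,
                    "start_idx": c.start_idx,
                    "end_idx": c.end_idx,
                    "start_bp": c.start_bp,
                    "end_bp": c.end_bp,
                    "carriers": c.carriers,
                    "subjects": c.subjects,
                    "realized_spans": {str(k): list(v) for k, v in c.realized_spans.items()},
                }
                for c in result.truth
            ],
            fh,
            indent=1,
        )
    return paths


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    o = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if o <= 0:
        return 0.0
    return min(o / (a[1] - a[0] + 1), o / (b[1] - b[0] + 1))


def truth_compare(
    truth: Sequence[TruthCluster],
    regions,
    min_reciprocal_overlap: float = 0.8,
) -> pd.DataFrame:
    """Recovery metrics per planted cluster against detected regions.

    A cluster counts as detected when some region overlaps its planted bp
    span reciprocally by at least ``min_reciprocal_overlap``. The membership
    Rand index compares planted cluster labels of the planted subjects with
    their assignment to detected regions (subjects in no region each get a
    singleton label).
    """
    from sklearn.metrics import rand_score

    region_list = list(regions)
    subjects = sorted({s for c in truth for s in c.subjects})
    true_labels = {}
    for c in truth:
        for s in c.subjects:
            true_labels[s] = c.cluster_id
    pred_labels = {}
    for i, r in enumerate(region_list):
        for s in r.present_subjects:
            pred_labels.setdefault(s, i)
    rows = []
    for c in truth:
        best, best_region = 0.0, None
        for i, r in enumerate(region_list):
            ro = _reciprocal_overlap(
                (c.start_bp, c.end_bp), (r.start_bp, r.end_bp)
            )
            if ro > best:
                best, best_region = ro, i
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "detected": best >= min_reciprocal_overlap,
                "best_overlap": best,
                "best_region": best_region,
                "n_carriers": len(c.carriers),
            }
        )
    y_true = [true_labels[s] for s in subjects]
    y_pred = []
    next_singleton = -1
    for s in subjects:
        if s in pred_labels:
            y_pred.append(pred_labels[s])
        else:
            y_pred.append(next_singleton)
            next_singleton -= 1
    df = pd.DataFrame(rows)
    df.attrs["rand_index"] = (
        float(
            rand_score(
                pd.factorize(np.asarray(y_true, dtype=object))[0],
                pd.factorize(np.asarray(y_pred, dtype=object))[0],
            )
        )
        if len(subjects) > 1
        else 1.0
    )
    return df
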