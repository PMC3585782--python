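"""Common-TOH (cTOH) regions: per-SNP accumulation of TOH calls across subjects.

A cTOH is a maximal stretch of at least ``min_snps`` consecutive same-chromosome
SNPs, each covered by at least ``min_subjects`` TOH calls. A subject is
*present* for a cTOH when at least one of its TOHs overlaps the region by one
or more SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_plink import SnpMap
from .toh_scan import TOH


@dataclass(frozen=True)
class CtohParams:
    min_subjects: int = 10  # n: minimum TOH calls per SNP (count >= n)
    min_snps: int = 100     # L: minimum consecutive qualifying SNPs

    def __post_init__(self) -> None:
        if self.min_subjects < 1 or self.min_snps < 1:
            raise ValueError("CtohParams must be >= 1")


@dataclass
class CtohRegion:
    """A common-TOH region and the TOHs/subjects overlapping it."""

    region_id: int
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    start_snp: str
    end_snp: str
    member_tohs: list[int] = field(default_factory=list)
    present_subjects: set[str] = field(default_factory=set)

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1


def toh_call_counts(tohs: Iterable[TOH], snp_map: SnpMap) -> np.ndarray:
    """Per-SNP vector (global map order): number of TOHs covering each SNP."""
    counts = np.zeros(snp_map.n_snps, dtype=np.int64)
    for t in tohs:
        s, e = snp_map.block_of(t.chrom)
        if t.start_idx < 0 or t.end_idx >= e - s or t.start_idx > t.end_idx:
            raise ValueError(
                f"TOH {t.toh_id} span [{t.start_idx},{t.end_idx}] outside "
                f"chromosome {t.chrom!r} of {e - s} SNPs"
            )
        counts[s + t.start_idx : s + t.end_idx + 1] += 1
    return counts


def call_ctoh(
    counts: np.ndarray,
    snp_map: SnpMap,
    params: CtohParams,
    tohs: Sequence[TOH] = (),
) -> list[CtohRegion]:
    """Maximal runs of SNPs with count >= min_subjects, kept iff >= min_snps long.

    When ``tohs`` is given, member TOHs and present subjects are attached.
    """
    if len(counts) != snp_map.n_snps:
        raise ValueError("counts not aligned to map")
    regions: list[CtohRegion] = []
    bp = snp_map.df["bp"].to_numpy()
    ids = snp_map.df["snp_id"].to_numpy()
    for chrom, cs, ce in snp_map.chrom_blocks:
        qual = counts[cs:ce] >= params.min_subjects
        # maximal True runs
        padded = np.concatenate(([False], qual, [False]))
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0] - 1
        for s, e in zip(starts, ends):
            if e - s + 1 < params.min_snps:
                continue
            regions.append(
                CtohRegion(
                    region_id=len(regions),
                    chrom=chrom,
                    start_idx=int(s),
                    end_idx=int(e),
                    start_bp=int(bp[cs + s]),
                    end_bp=int(bp[cs + e]),
                    start_snp=str(ids[cs + s]),
                    end_snp=str(ids[cs + e]),
                )
            )
    for r in regions:
        r.member_tohs = sorted(t.toh_id for t in tohs if _overlaps(t, r))
        r.present_subjects = ctoh_presence(r, tohs)
    return regions


def _overlaps(t: TOH, r: CtohRegion) -> bool:
    return t.chrom == r.chrom and t.start_idx <= r.end_idx and t.end_idx >= r.start_idx


def ctoh_presence(region: CtohRegion, tohs: Iterable[TOH]) -> set[str]:
    """Subjects with >= 1 SNP of TOH overlap with the region (closed intervals)."""
    return {t.subject for t in tohs if _overlaps(t, region)}
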