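"""Detection of per-subject maximal tracts of homozygosity (TOH).

A TOH is a maximal run of consecutive SNP calls on one chromosome whose first
and last calls are homozygous and non-missing, containing at most ``max_het``
heterozygous and ``max_missing`` missing calls, and meeting a minimum size:
either at least ``min_snps`` SNPs, or — when ``min_kb`` is set — a bp span of
at least ``min_kb`` kilobases together with at least ``min_snps_if_kb`` SNPs.
Maximal means no qualifying run of the same subject strictly contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_plink import GenotypeMatrix, SnpMap


@dataclass(frozen=True)
class ScanParams:
    """Run-size and allowance constraints for the homozygosity scan.

    min_snps : L, the minimum run length in SNPs (ignored when min_kb is set).
    min_kb : optional minimum bp span in kb; replaces the SNP-count criterion.
    min_snps_if_kb : minimum SNP count applied together with min_kb.
    max_het / max_missing : interior allowances per run.
    max_gap_kb : optional density guard on adjacent-SNP bp gaps inside a run.
    """

    min_snps: int = 100
    min_kb: Optional[float] = None
    min_snps_if_kb: int = 25
    max_het: int = 0
    max_missing: int = 2
    max_gap_kb: Optional[float] = None

    def __post_init__(self) -> None:
        if self.min_snps < 1 or self.min_snps_if_kb < 1:
            raise ValueError("minimum SNP counts must be >= 1")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("allowances must be non-negative")
        if self.min_kb is not None and self.min_kb < 0:
            raise ValueError("min_kb must be non-negative")


@dataclass(frozen=True)
class TOH:
    """One subject's maximal homozygous tract on one chromosome.

    start_idx/end_idx are 0-based inclusive per-chromosome SNP indices;
    start_bp/end_bp the matching 1-based map positions (closed interval).
    """

    subject: str
    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_het: int
    n_missing: int
    toh_id: int = -1

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def _call_states(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """hom, het, missing boolean vectors for one subject's chromosome calls."""
    missing = (alleles[:, 0] == "0") | (alleles[:, 1] == "0")
    hom = (alleles[:, 0] == alleles[:, 1]) & ~missing
    het = ~hom & ~missing
    return hom, het, missing


def _meets_size(n_snps: int, span_bp: int, params: ScanParams) -> bool:
    if params.min_kb is not None:
        return span_bp / 1000.0 >= params.min_kb and n_snps >= params.min_snps_if_kb
    return n_snps >= params.min_snps


def scan_subject(
    subject: str,
    chrom: str,
    alleles: np.ndarray,
    positions: np.ndarray,
    params: ScanParams,
) -> list[TOH]:
    """Return the maximal qualifying runs for one subject on one chromosome.

    ``alleles`` is (n_snps, 2) in map order; ``positions`` the matching bp
    vector. Output is left-to-right and non-nested.
    """
    n = len(positions)
    if n == 0 or len(alleles) != n:
        if len(alleles) != n:
            raise ValueError("alleles and positions length mismatch")
        return []
    hom, het, missing = _call_states(alleles)

    # Adjacent-gap density guard: a window may not straddle an oversized gap.
    if params.max_gap_kb is not None and n > 1:
        bad_gap_after = np.diff(positions) > params.max_gap_kb * 1000.0
    else:
        bad_gap_after = np.zeros(max(n - 1, 0), dtype=bool)

    # Two-pointer sweep over budget-feasible windows (constraints hereditary),
    # then trim each maximal window to homozygous endpoints.
    runs: list[tuple[int, int]] = []
    het_count = miss_count = 0
    right = -1  # last index inside the current window
    prev_reach = -1
    for left in range(n):
        if right < left - 1:
            right = left - 1
            het_count = miss_count = 0
        while right + 1 < n:
            j = right + 1
            if j > left and bad_gap_after[j - 1]:
                break
            if het_count + het[j] > params.max_het:
                break
            if miss_count + missing[j] > params.max_missing:
                break
            het_count += bool(het[j])
            miss_count += bool(missing[j])
            right = j
        if right >= left and right > prev_reach:
            # window [left, right] cannot be extended either way: trim it
            prev_reach = right
            span = np.nonzero(hom[left : right + 1])[0]
            if span.size:
                s = left + span[0]
                e = left + span[-1]
                runs.append((s, e))
        # slide: drop `left` from the window before advancing
        if right >= left:
            het_count -= bool(het[left])
            miss_count -= bool(missing[left])

    # Trimming distinct windows can produce nested or duplicate runs.
    runs = _drop_nested(runs)

    out: list[TOH] = []
    for s, e in runs:
        span_bp = int(positions[e]) - int(positions[s]) + 1
        if not _meets_size(e - s + 1, span_bp, params):
            continue
        out.append(
            TOH(
                subject=subject,
                chrom=chrom,
                start_idx=s,
                end_idx=e,
                start_bp=int(positions[s]),
                end_bp=int(positions[e]),
                n_het=int(het[s : e + 1].sum()),
                n_missing=int(missing[s : e + 1].sum()),
            )
        )
    return out


def _drop_nested(runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    # sort by (start asc, end desc): a run is nested iff some earlier-sorted
    # run already reaches at least as far right
    ordered = sorted(set(runs), key=lambda r: (r[0], -r[1]))
    kept: list[tuple[int, int]] = []
    best_end = -1
    for s, e in ordered:
        if e > best_end:
            kept.append((s, e))
            best_end = e
    return kept


def scan_all(genotypes: GenotypeMatrix, snp_map: SnpMap, params: ScanParams) -> list[TOH]:
    """Scan every subject on every chromosome; TOHs get sequential ids.

    Order is deterministic: subjects in .ped order, chromosomes in map order,
    runs left-to-right.
    """
    out: list[TOH] = []
    subject_ids = genotypes.subject_ids
    for i in range(genotypes.n_subjects):
        for chrom, s, e in snp_map.chrom_blocks:
            tohs = scan_subject(
                str(subject_ids[i]),
                chrom,
                genotypes.alleles[i, s:e],
                snp_map.df["bp"].to_numpy()[s:e],
                params,
            )
            out.extend(tohs)
    return [
        TOH(**{**t.__dict__, "toh_id": k}) for k, t in enumerate(out)
    ]


def read_toh_calls(path, snp_map: SnpMap) -> list[TOH]:
    """Read a TOH table written by :func:`tohkit.io_plink.write_toh_calls`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "chrom": str})
    row_of = {sid: i for i, sid in enumerate(snp_map.df["snp_id"])}
    out = []
    for _, r in df.iterrows():
        s, _ = snp_map.block_of(r["chrom"])
        out.append(
            TOH(
                subject=r["subject"],
                chrom=r["chrom"],
                start_idx=row_of[r["start_snp"]] - s,
                end_idx=row_of[r["end_snp"]] - s,
                start_bp=int(r["start_bp"]),
                end_bp=int(r["end_bp"]),
                n_het=int(r["n_het"]),
                n_missing=int(r["n_missing"]),
                toh_id=int(r["toh_id"]),
            )
        )
    return out


def homozygosity_rate(genotypes: GenotypeMatrix) -> float:
    """Fraction of homozygous calls among non-missing calls."""
    missing = genotypes.missing_mask()
    n_obs = (~missing).sum()
    if n_obs == 0:
        raise ValueError("homozygosity rate undefined: all calls missing")
    return float(genotypes.hom_mask().sum() / n_obs)
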