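"""Reading PLINK-style .ped/.map text genotypes and writing tabular outputs.

The text dialect accepted here is the whitespace-delimited PLINK one: a .map
file with four columns (chromosome, SNP id, genetic distance, bp position) and
a .ped file whose rows carry six leading sample columns (family id, individual
id, father, mother, sex, phenotype) followed by two allele tokens per SNP.
Any single non-whitespace token other than ``0`` is accepted as an allele, so
both ACGT and 1/2/3/4 allele dialects pass through unchanged; ``0`` marks a
missing allele and a call is missing iff either of its alleles is missing.

Coordinates: .map bp positions are 1-based and all reported regions are closed
intervals [first member SNP bp, last member SNP bp]; internal SNP indices are
0-based per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING_ALLELE = "0"

PED_SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Raised when a .ped/.map file violates the expected text dialect."""


@dataclass
class SnpMap:
    """Per-SNP records (chromosome, id, genetic distance, bp) in file order.

    Positions must be strictly increasing within a chromosome, SNP ids unique,
    and each chromosome must occupy one contiguous block of rows.
    """

    df: pd.DataFrame  # columns: chrom, snp_id, cm, bp

    def __post_init__(self) -> None:
        required = ["chrom", "snp_id", "cm", "bp"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"SnpMap frame missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["snp_id"].duplicated().any():
            dup = self.df["snp_id"][self.df["snp_id"].duplicated()].iloc[0]
            raise PlinkFormatError(f"duplicate SNP id {dup!r} in map")
        if (self.df["bp"] <= 0).any():
            raise PlinkFormatError("map bp positions must be positive")
        chroms = self.df["chrom"].to_numpy()
        seen: set[str] = set()
        blocks: list[tuple[str, int, int]] = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                c = chroms[start]
                if c in seen:
                    raise PlinkFormatError(
                        f"chromosome {c!r} appears in non-contiguous map blocks"
                    )
                seen.add(c)
                bp = self.df["bp"].to_numpy()[start:i]
                if np.any(np.diff(bp) <= 0):
                    raise PlinkFormatError(
                        f"bp positions not strictly increasing on chromosome {c!r}"
                    )
                blocks.append((c, start, i))
                start = i
        self._blocks = blocks

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chromosome, global start row, global stop row) blocks."""
        return list(self._blocks)

    def block_of(self, chrom: str) -> tuple[int, int]:
        for c, s, e in self._blocks:
            if c == chrom:
                return s, e
        raise KeyError(f"chromosome {chrom!r} not in map")

    def global_index(self, chrom: str, idx: int) -> int:
        """Map a 0-based per-chromosome SNP index to the global map row."""
        s, e = self.block_of(chrom)
        if not 0 <= idx < e - s:
            raise IndexError(f"SNP index {idx} out of range for chromosome {chrom!r}")
        return s + idx

    def positions(self, chrom: str) -> np.ndarray:
        s, e = self.block_of(chrom)
        return self.df["bp"].to_numpy()[s:e]

    def snp_ids(self, chrom: str) -> np.ndarray:
        s, e = self.block_of(chrom)
        return self.df["snp_id"].to_numpy()[s:e]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs diploid calls plus the six .ped sample columns.

    ``alleles`` has shape (n_subjects, n_snps, 2); per-call allele order is not
    semantically meaningful.
    """

    samples: pd.DataFrame  # columns PED_SAMPLE_COLUMNS
    alleles: np.ndarray

    def __post_init__(self) -> None:
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_subjects, n_snps, 2)")
        if len(self.samples) != self.alleles.shape[0]:
            raise ValueError("sample table and allele array row counts differ")

    @property
    def n_subjects(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.samples["iid"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        """Boolean (subjects, snps): call is missing (either allele ``0``)."""
        a = self.alleles
        return (a[:, :, 0] == MISSING_ALLELE) | (a[:, :, 1] == MISSING_ALLELE)

    def hom_mask(self) -> np.ndarray:
        """Boolean (subjects, snps): homozygous non-missing call."""
        a = self.alleles
        return (a[:, :, 0] == a[:, :, 1]) & ~self.missing_mask()


@dataclass
class PhenotypeTable:
    """Per-subject case-control status and covariates, keyed by individual id."""

    df: pd.DataFrame  # columns: fid, iid, status, age, sex, smoking, ...

    def __post_init__(self) -> None:
        for col in ("iid", "status"):
            if col not in self.df.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        self.df = self.df.reset_index(drop=True)
        status = set(pd.unique(self.df["status"]))
        if not status <= {0, 1}:
            raise ValueError(f"status must be binary 0/1, found {sorted(status)}")
        if self.df["iid"].duplicated().any():
            raise ValueError("duplicate individual ids in phenotype table")

    def status_of(self, subject_ids) -> np.ndarray:
        s = self.df.set_index("iid")["status"]
        missing = [i for i in subject_ids if i not in s.index]
        if missing:
            raise KeyError(f"subjects missing from phenotype table: {missing[:5]}")
        return s.loc[list(subject_ids)].to_numpy()


def read_map(map_path) -> SnpMap:
    df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": np.int64},
        comment="#",
    )
    return SnpMap(df)


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, SnpMap]:
    """Parse a .ped/.map pair into a genotype matrix and SNP map.

    Every .ped row must have exactly ``6 + 2 * n_snps`` whitespace-separated
    tokens; a mismatch raises :class:`PlinkFormatError` naming the line.
    """
    snp_map = read_map(map_path)
    n_snps = snp_map.n_snps
    sample_rows: list[list[str]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno} has {len(tokens)} fields, "
                    f"expected {6 + 2 * n_snps} for {n_snps} map SNPs"
                )
            for tok in tokens[6:]:
                if not tok or tok.isspace():
                    raise PlinkFormatError(
                        f"{ped_path}: line {lineno}: bad allele token {tok!r}"
                    )
            sample_rows.append(tokens[:6])
            allele_rows.append(np.array(tokens[6:], dtype="U8").reshape(n_snps, 2))
    samples = pd.DataFrame(sample_rows, columns=PED_SAMPLE_COLUMNS)
    if allele_rows:
        alleles = np.stack(allele_rows)
    else:
        alleles = np.empty((0, n_snps, 2), dtype="U8")
    return GenotypeMatrix(samples, alleles), snp_map


def write_ped_map(genotypes: GenotypeMatrix, snp_map: SnpMap, ped_path, map_path) -> None:
    snp_map.df.to_csv(map_path, sep="\t", header=False, index=False)
    with open(ped_path, "w") as fh:
        flat = genotypes.alleles.reshape(genotypes.n_subjects, -1)
        for row, (_, meta) in zip(flat, genotypes.samples.iterrows()):
            fh.write(" ".join(str(meta[c]) for c in PED_SAMPLE_COLUMNS))
            if row.size:
                fh.write(" " + " ".join(row))
            fh.write("\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read the tab/space separated phenotype TSV (header ``fid iid status age sex smoking``)."""
    df = pd.read_csv(path, sep=r"\s+", dtype={"fid": str, "iid": str})
    return PhenotypeTable(df)


TOH_COLUMNS = [
    "toh_id", "subject", "chrom", "start_snp", "end_snp",
    "start_bp", "end_bp", "n_snps", "n_het", "n_missing",
]


def write_toh_calls(tohs, snp_map: SnpMap, path) -> None:
    """One row per TOH, sorted by (chromosome, start_bp, subject)."""
    rows = []
    for t in tohs:
        ids = snp_map.snp_ids(t.chrom)
        rows.append({
            "toh_id": t.toh_id,
            "subject": t.subject,
            "chrom": t.chrom,
            "start_snp": ids[t.start_idx],
            "end_snp": ids[t.end_idx],
            "start_bp": t.start_bp,
            "end_bp": t.end_bp,
            "n_snps": t.n_snps,
            "n_het": t.n_het,
            "n_missing": t.n_missing,
        })
    df = pd.DataFrame(rows, columns=TOH_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "start_bp", "subject"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


REGION_COLUMNS = [
    "region", "start_snp", "end_snp", "length_bp", "n_snps",
    "n_cases", "n_controls", "p_value", "odds_ratio", "ci_95",
]


def write_regions(records, path) -> None:
    """Write region/association rows as the ten-column tab-delimited table.

    ``length_bp`` is the closed-interval span ``end_bp - start_bp + 1``.
    Each record needs: region label, start/end SNP id, start/end bp, n_snps,
    n_cases, n_controls, p_value, odds_ratio, ci_low, ci_high.
    """
    rows = []
    for r in records:
        rows.append({
            "region": r["region"],
            "start_snp": r["start_snp"],
            "end_snp": r["end_snp"],
            "length_bp": int(r["end_bp"]) - int(r["start_bp"]) + 1,
            "n_snps": r["n_snps"],
            "n_cases": r["n_cases"],
            "n_controls": r["n_controls"],
            "p_value": _fmt(r.get("p_value")),
            "odds_ratio": _fmt(r.get("odds_ratio")),
            "ci_95": _fmt_ci(r.get("ci_low"), r.get("ci_high")),
        })
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt(x) -> str:
    if x is None:
        return "NA"
    x = float(x)
    if np.isposinf(x):
        return "Inf"
    if np.isnan(x):
        return "NA"
    return f"{x:.4g}"


def _fmt_ci(low, high) -> str:
    if low is None or high is None:
        return "NA"
    return f"({_fmt(low)},{_fmt(high)})"
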