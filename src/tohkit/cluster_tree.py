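"""Repeated binary spectral clustering of TOHs within a cTOH.

Within one common-TOH region the member tracts need not share boundaries.
Two finer surrogate regions are extracted by growing a binary cluster tree
over the member TOHs:

* gTOH — groups of tracts whose pairwise *positional* overlap is a high
  fraction of each member's length (proximal boundaries);
* aTOH — groups that are additionally *allelically matched* over the overlap
  segment, isolating allele-specific homozygosity.

The tree starts from all TOHs of one cTOH as the root and repeatedly applies
normalized (Ng–Jordan–Weiss) spectral clustering with k = 2: the symmetric
normalized Laplacian ``L_sym = I - D^{-1/2} S D^{-1/2}`` of the similarity
matrix S is eigendecomposed, the eigenvectors of the two smallest eigenvalues
are row-normalized to unit length, and k-means with k = 2 partitions the rows.
A node stops splitting when the tree depth reaches ``max_depth``, the node has
fewer than ``min_node_size`` members, or a summary statistic (default: lower
quartile) of its pairwise similarities exceeds ``threshold``. Leaves that meet
the reporting gate (size and similarity) become output regions whose
boundaries are quantiles of the member start/end positions, snapped inward to
actual member SNP positions.

The pairwise similarity formulas are configuration, not hidden constants:
``kernel="min_overlap"`` uses s_ij = min(o/l_i, o/l_j) — exactly the pairwise
gTOH criterion that the overlap cover at least a fraction of each member's
length — and
``kernel="product"`` offers s_ij = o^2/(l_i l_j). Lengths are measured in SNP
counts by default (``length_unit="bp"`` switches to base pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .ctoh import CtohRegion
from .io_plink import GenotypeMatrix, SnpMap
from .toh_scan import TOH

Kind = Literal["gtoh", "atoh"]

STAT_FUNCS = {
    "minimum": np.min,
    "lower_quartile": lambda v: float(np.quantile(v, 0.25)),
    "mean": np.mean,
}


@dataclass(frozen=True)
class ClusterParams:
    """Tree growth, stopping and reporting parameters.

    gamma : minimum pairwise overlap fraction for the allelic kernel gate.
    stat : summary statistic over a node's pairwise similarities.
    threshold : stop splitting when stat > threshold; report leaves with
        stat >= threshold (strict ">" at stopping, ">=" at reporting).
    boundary_mode : "interior" uses quantile 0.75 of member starts and 0.25 of
        member ends (a conservative inner region); "literal" uses the lower
        quartile (0.25) of both. ``boundary_quantiles`` overrides either.
    """

    gamma: float = 0.5
    stat: str = "lower_quartile"
    threshold: float = 0.75
    max_depth: int = 100
    min_node_size: int = 5
    min_report_size: int = 2
    boundary_mode: str = "interior"
    boundary_quantiles: Optional[tuple[float, float]] = None
    kernel: str = "min_overlap"
    length_unit: str = "snps"

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.stat not in STAT_FUNCS:
            raise ValueError(f"stat must be one of {sorted(STAT_FUNCS)}")
        if self.kernel not in ("min_overlap", "product"):
            raise ValueError("kernel must be 'min_overlap' or 'product'")
        if self.boundary_mode not in ("interior", "literal"):
            raise ValueError("boundary_mode must be 'interior' or 'literal'")
        if self.length_unit not in ("snps", "bp"):
            raise ValueError("length_unit must be 'snps' or 'bp'")

    @property
    def quantile_pair(self) -> tuple[float, float]:
        if self.boundary_quantiles is not None:
            return self.boundary_quantiles
        return (0.75, 0.25) if self.boundary_mode == "interior" else (0.25, 0.25)


@dataclass
class ClusterNode:
    members: list[int]            # positions into the node list's TOH sequence
    depth: int
    stat_value: float             # nan for singletons (no pairs)
    children: list["ClusterNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class SurrogateRegion:
    """An output gTOH or aTOH region."""

    kind: Kind
    parent_ctoh: int
    chrom: str
    start_bp: int
    end_bp: int
    start_snp: str
    end_snp: str
    n_snps: int
    member_tohs: list[int]
    present_subjects: set[str]
    stat_value: float


# ---------------------------------------------------------------------------
# similarity kernels


def _span_overlap(a: TOH, b: TOH) -> int:
    """Overlap length in SNPs of two closed index spans (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end_idx, b.end_idx) - max(a.start_idx, b.start_idx) + 1)


def _lengths(a: TOH, b: TOH, unit: str) -> tuple[float, float, float]:
    if unit == "bp":
        o = 0.0
        if a.chrom == b.chrom:
            o = max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1)
        return o, a.end_bp - a.start_bp + 1, b.end_bp - b.start_bp + 1
    return float(_span_overlap(a, b)), float(a.n_snps), float(b.n_snps)


def positional_similarity(
    a: TOH, b: TOH, kernel: str = "min_overlap", length_unit: str = "snps"
) -> float:
    """Overlap-fraction similarity in [0, 1]; 0 across chromosomes."""
    o, la, lb = _lengths(a, b, length_unit)
    if o == 0:
        return 0.0
    if kernel == "product":
        return float(o * o / (la * lb))
    return float(min(o / la, o / lb))


def allelic_similarity(
    a: TOH,
    b: TOH,
    genotypes: GenotypeMatrix,
    snp_map: SnpMap,
    gamma: float = 0.5,
    length_unit: str = "snps",
    _row_of: Optional[dict] = None,
) -> float:
    """Fraction of overlap SNPs where both subjects carry the same homozygote.

    Pairs whose overlap is shorter than ``gamma`` of either member's length
    are assigned similarity 0.
    """
    o, la, lb = _lengths(a, b, length_unit)
    if o == 0 or min(o / la, o / lb) < gamma:
        return 0.0
    s = max(a.start_idx, b.start_idx)
    e = min(a.end_idx, b.end_idx)
    gs, _ = snp_map.block_of(a.chrom)
    if _row_of is None:
        ids = list(genotypes.subject_ids)
        _row_of = {sid: i for i, sid in enumerate(ids)}
    ra = _row_of[a.subject]
    rb = _row_of[b.subject]
    ga = genotypes.alleles[ra, gs + s : gs + e + 1]
    gb = genotypes.alleles[rb, gs + s : gs + e + 1]
    hom_a = (ga[:, 0] == ga[:, 1]) & (ga[:, 0] != "0")
    hom_b = (gb[:, 0] == gb[:, 1]) & (gb[:, 0] != "0")
    match = hom_a & hom_b & (ga[:, 0] == gb[:, 0])
    return float(match.sum() / (e - s + 1))


def build_similarity(
    tohs: Sequence[TOH],
    kind: Kind,
    params: ClusterParams,
    genotypes: Optional[GenotypeMatrix] = None,
    snp_map: Optional[SnpMap] = None,
) -> np.ndarray:
    """Symmetric similarity matrix with unit diagonal over a set of TOHs."""
    k = len(tohs)
    S = np.eye(k)
    row_of = None
    if kind == "atoh":
        if genotypes is None or snp_map is None:
            raise ValueError("allelic similarity needs genotypes and snp_map")
        row_of = {sid: i for i, sid in enumerate(genotypes.subject_ids)}
    for i in range(k):
        for j in range(i + 1, k):
            if kind == "gtoh":
                s = positional_similarity(
                    tohs[i], tohs[j], params.kernel, params.length_unit
                )
            else:
                s = allelic_similarity(
                    tohs[i], tohs[j], genotypes, snp_map,
                    gamma=params.gamma, length_unit=params.length_unit,
                    _row_of=row_of,
                )
            S[i, j] = S[j, i] = s
    return S


# ---------------------------------------------------------------------------
# spectral bipartition and tree growth


def _child_seed(seed: int, path: tuple[int, ...]) -> int:
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def binary_spectral_split(S: np.ndarray, seed: int = 0) -> tuple[list[int], list[int]]:
    """NJW spectral bipartition of the members of a similarity matrix.

    Members with all-zero off-diagonal similarity (no overlap with anyone) are
    split off as one side before the eigendecomposition; otherwise the rows of
    the two bottom eigenvectors of ``L_sym``, normalized to unit length, are
    clustered by k-means (k = 2, 10 restarts, best inertia). The first member
    always lands in the first returned side. Both sides are non-empty.
    """
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 members to split")
    off = S.copy()
    np.fill_diagonal(off, 0.0)
    isolated = np.nonzero(off.sum(axis=1) == 0)[0]
    if isolated.size and isolated.size < n:
        rest = [i for i in range(n) if i not in set(isolated.tolist())]
        return _orient(rest, list(isolated))
    if isolated.size == n:
        # mutually disjoint members: peel the first off
        return [0], list(range(1, n))

    d = S.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(n) - (d_inv_sqrt[:, None] * S) * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, :2]
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    U = U / norms[:, None]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(U)
    a = [i for i in range(n) if labels[i] == labels[0]]
    b = [i for i in range(n) if labels[i] != labels[0]]
    if not b:  # degenerate k-means outcome: fall back to a deterministic peel
        a, b = [0], list(range(1, n))
    return _orient(a, b)


def _orient(a: list[int], b: list[int]) -> tuple[list[int], list[int]]:
    return (a, b) if 0 in a else (b, a)


def node_stat(S: np.ndarray, members: Sequence[int], stat: str) -> float:
    """Summary statistic of the off-diagonal pairwise similarities of a node."""
    m = list(members)
    if len(m) < 2:
        return float("nan")
    sub = S[np.ix_(m, m)]
    vals = sub[np.triu_indices(len(m), k=1)]
    return float(STAT_FUNCS[stat](vals))


def build_tree(
    tohs: Sequence[TOH],
    kind: Kind,
    params: ClusterParams,
    seed: int = 0,
    genotypes: Optional[GenotypeMatrix] = None,
    snp_map: Optional[SnpMap] = None,
    S: Optional[np.ndarray] = None,
) -> ClusterNode:
    """Grow the binary cluster tree over the TOHs of one cTOH."""
    if S is None:
        S = build_similarity(tohs, kind, params, genotypes, snp_map)

    def grow(members: list[int], depth: int, path: tuple[int, ...]) -> ClusterNode:
        stat_value = node_stat(S, members, params.stat)
        node = ClusterNode(members=members, depth=depth, stat_value=stat_value)
        if (
            depth >= params.max_depth
            or len(members) < params.min_node_size
            or (not np.isnan(stat_value) and stat_value > params.threshold)
        ):
            return node
        sub = S[np.ix_(members, members)]
        left, right = binary_spectral_split(sub, _child_seed(seed, path))
        node.children = [
            grow([members[i] for i in left], depth + 1, path + (0,)),
            grow([members[i] for i in right], depth + 1, path + (1,)),
        ]
        return node

    return grow(list(range(len(tohs))), 0, ())


def extract_regions(
    tree: ClusterNode,
    tohs: Sequence[TOH],
    kind: Kind,
    params: ClusterParams,
    snp_map: SnpMap,
    S: Optional[np.ndarray] = None,
    parent_ctoh: int = -1,
) -> list[SurrogateRegion]:
    """One region per leaf passing the size and similarity reporting gate.

    Region bounds: quantile ``q_start`` of member start positions snapped up
    to the next member start, quantile ``q_end`` of member end positions
    snapped down to the previous member end (boundaries are real member SNPs).
    """
    q_start, q_end = params.quantile_pair
    out: list[SurrogateRegion] = []
    for leaf in tree.leaves():
        members = [tohs[i] for i in leaf.members]
        if len(members) < params.min_report_size:
            continue
        stat_value = leaf.stat_value
        if np.isnan(stat_value) or stat_value < params.threshold:
            continue
        starts = np.array(sorted(t.start_bp for t in members))
        ends = np.array(sorted(t.end_bp for t in members))
        s_q = float(np.quantile(starts, q_start))
        e_q = float(np.quantile(ends, q_end))
        start_bp = int(starts[np.searchsorted(starts, s_q, side="left")])
        e_pos = np.searchsorted(ends, e_q, side="right") - 1
        end_bp = int(ends[max(e_pos, 0)])
        if start_bp > end_bp:
            # crossed interior quantiles on a tiny leaf: fall back to medians
            start_bp = int(np.median(starts))
            end_bp = int(max(np.median(ends), start_bp))
        chrom = members[0].chrom
        pos = snp_map.positions(chrom)
        ids = snp_map.snp_ids(chrom)
        si = int(np.searchsorted(pos, start_bp, side="left"))
        ei = int(np.searchsorted(pos, end_bp, side="right")) - 1
        out.append(
            SurrogateRegion(
                kind=kind,
                parent_ctoh=parent_ctoh,
                chrom=chrom,
                start_bp=start_bp,
                end_bp=end_bp,
                start_snp=str(ids[si]),
                end_snp=str(ids[ei]),
                n_snps=ei - si + 1,
                member_tohs=[t.toh_id for t in members],
                present_subjects={t.subject for t in members},
                stat_value=stat_value,
            )
        )
    return out


def cluster_ctoh(
    region: CtohRegion,
    tohs: Sequence[TOH],
    kind: Kind,
    params: ClusterParams,
    snp_map: SnpMap,
    seed: int = 0,
    genotypes: Optional[GenotypeMatrix] = None,
) -> list[SurrogateRegion]:
    """Cluster one cTOH's member TOHs and extract its surrogate regions."""
    by_id = {t.toh_id: t for t in tohs}
    members = [by_id[i] for i in sorted(region.member_tohs)]
    if not members:
        return []
    S = build_similarity(members, kind, params, genotypes, snp_map)
    tree = build_tree(
        members, kind, params, seed=seed, genotypes=genotypes, snp_map=snp_map, S=S
    )
    return extract_regions(
        tree, members, kind, params, snp_map, S=S, parent_ctoh=region.region_id
    )


def cluster_all(
    ctohs: Sequence[CtohRegion],
    tohs: Sequence[TOH],
    kind: Kind,
    params: ClusterParams,
    snp_map: SnpMap,
    seed: int = 0,
    genotypes: Optional[GenotypeMatrix] = None,
) -> list[SurrogateRegion]:
    out: list[SurrogateRegion] = []
    for r in ctohs:
        out.extend(
            cluster_ctoh(r, tohs, kind, params, snp_map, seed=seed, genotypes=genotypes)
        )
    return out
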