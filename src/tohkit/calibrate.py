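"""Run-length parameter calibration.

Helpers for choosing the minimum TOH length L: the genome-wide chance that a
run of L consecutive SNPs is homozygous purely by chance, an LD deflation of
L by the tag-group fraction, and empirical quantiles of observed TOH lengths
obtained from a permissive rescan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class CalibrationInputs:
    """p_hom: genome-wide homozygosity rate; alpha: chance-run likelihood cap;
    tag_fraction: separable LD tag groups / total SNPs."""

    p_hom: float
    n_subjects: int
    n_snps: int
    alpha: float = 0.05
    tag_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_hom < 1:
            raise ValueError("p_hom must be in [0, 1)")
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.tag_fraction <= 1:
            raise ValueError("tag_fraction must be in (0, 1]")


def chance_likelihood(inputs: CalibrationInputs, L: int) -> float:
    """Expected genome-wide count bound n_subjects * n_snps * p_hom**L."""
    return inputs.n_subjects * inputs.n_snps * inputs.p_hom**L


def chance_run_length(inputs: CalibrationInputs) -> int:
    """Smallest integer L whose genome-wide chance-homozygosity likelihood
    ``n_subjects * n_snps * p_hom**L`` drops below alpha.

    The returned L satisfies the bound and L - 1 does not.
    """
    if inputs.p_hom == 0:
        return 1
    base = inputs.n_subjects * inputs.n_snps
    # closed form, then verify at integer boundaries against float roundoff
    L = max(1, math.ceil((math.log(inputs.alpha) - math.log(base)) / math.log(inputs.p_hom)))
    while chance_likelihood(inputs, L) >= inputs.alpha:
        L += 1
    while L > 1 and chance_likelihood(inputs, L - 1) < inputs.alpha:
        L -= 1
    return L


def ld_adjusted_length(L: int, tag_fraction: float) -> int:
    """Deflate an independent-SNP run length by the tag-group fraction.

    Round-half-up to the nearest integer (58 / 0.63 = 92.06 -> 92).
    """
    if not 0 < tag_fraction <= 1:
        raise ValueError("tag_fraction must be in (0, 1]")
    return int(math.floor(L / tag_fraction + 0.5))


def toh_length_quantiles(tohs: Sequence, probs: Iterable[float]) -> np.ndarray:
    """Linear-interpolation quantiles of TOH lengths (in SNPs)."""
    lengths = np.array([t.n_snps for t in tohs], dtype=float)
    if lengths.size == 0:
        raise ValueError("no TOHs supplied")
    probs = np.asarray(list(probs), dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probs must be in [0, 1]")
    return np.quantile(lengths, probs)
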