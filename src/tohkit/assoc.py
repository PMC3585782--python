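"""Case-control association of surrogate-region presence.

Each region's presence/absence is a binary genomic predictor of disease
status. Large tables (every cell >= 5) are tested by a covariate-adjusted
logistic model with a Wald test on the presence coefficient; any observed
cell below 5 dispatches to Fisher's exact test with the point-probability
two-sided p-value and the conditional-MLE odds ratio of the noncentral
hypergeometric model, with exact conditional 95% CI. Zero-cell tables report
an odds ratio of 0 or +inf with the corresponding one-sided-style exact
bound (e.g. "Inf (1.53, Inf)").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .io_plink import PhenotypeTable

SMALL_CELL = 5  # any observed 2x2 cell below this dispatches to Fisher


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a = cases present, b = cases absent, c = controls present, d = controls absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def min_cell(self) -> int:
        return min(self.a, self.b, self.c, self.d)


@dataclass
class AssocResult:
    region_id: object
    test: str                   # "fisher_exact" | "logistic_wald"
    p_value: float
    odds_ratio: float           # may be 0.0 or +inf
    ci_low: float
    ci_high: float
    n_cases_present: int
    n_controls_present: int


def build_table(present_subjects: Iterable[str], phenotypes: PhenotypeTable) -> ContingencyTable2x2:
    """Cross-tabulate presence against case-control status.

    Every present subject must appear in the phenotype table; the margins are
    the phenotype table's full case and control counts.
    """
    present = set(present_subjects)
    known = set(phenotypes.df["iid"])
    unknown = present - known
    if unknown:
        raise KeyError(f"present subjects missing from phenotype table: {sorted(unknown)[:5]}")
    status = phenotypes.df.set_index("iid")["status"]
    n_cases = int((status == 1).sum())
    n_controls = int((status == 0).sum())
    a = int(sum(status[s] == 1 for s in present))
    c = len(present) - a
    return ContingencyTable2x2(a, n_cases - a, c, n_controls - c)


def fisher_exact(table: ContingencyTable2x2, region_id=None) -> AssocResult:
    """Exact conditional test of a 2x2 table.

    p: two-sided point-probability rule (sum of fixed-margin tables whose
    probability does not exceed the observed one). OR: conditional MLE of the
    noncentral hypergeometric odds parameter; 95% CI by inverting the exact
    conditional tails at 0.025 each side.
    """
    arr = table.array
    p = float(_scipy_fisher(arr).pvalue)
    res = _scipy_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    return AssocResult(
        region_id=region_id,
        test="fisher_exact",
        p_value=p,
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_cases_present=table.a,
        n_controls_present=table.c,
    )


class RankDeficientDesign(ValueError):
    """The covariate design matrix is not full rank."""


def _design(presence: np.ndarray, covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    X = pd.DataFrame({"presence": presence.astype(float)})
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).copy()
        num = cov.select_dtypes(include=[np.number])
        cat = cov.select_dtypes(exclude=[np.number])
        parts = [X, num]
        if len(cat.columns):
            # categorical covariates become indicator contrasts against the
            # first (reference) level, e.g. smoking: previous/current vs never
            parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
        X = pd.concat(parts, axis=1)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficientDesign(
            f"design matrix rank-deficient (columns: {list(X.columns)})"
        )
    return X


def logistic_wald(
    presence: np.ndarray,
    phenotypes: PhenotypeTable,
    covariates: Optional[pd.DataFrame] = None,
    subject_ids: Optional[Sequence[str]] = None,
    region_id=None,
) -> AssocResult:
    """Wald test on the presence coefficient of a logistic fit.

    ``presence`` is a 0/1 vector over subjects (ordered like ``subject_ids``,
    defaulting to the phenotype table order). Separation or non-convergence
    falls back to Fisher's exact test with a warning.
    """
    if subject_ids is None:
        subject_ids = list(phenotypes.df["iid"])
    presence = np.asarray(presence, dtype=float)
    y = phenotypes.status_of(subject_ids).astype(float)
    X = _design(presence, covariates)
    a = int(((presence == 1) & (y == 1)).sum())
    c = int(((presence == 1) & (y == 0)).sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or not np.isfinite(
            fit.bse["presence"]
        ):
            raise RuntimeError("logistic fit did not converge")
        beta = float(fit.params["presence"])
        se = float(fit.bse["presence"])
    except RankDeficientDesign:
        raise
    except Exception as err:  # separation / non-convergence
        warnings.warn(
            f"logistic fit failed ({err}); falling back to Fisher's exact test",
            stacklevel=2,
        )
        n_cases = int((y == 1).sum())
        n_controls = int((y == 0).sum())
        res = fisher_exact(
            ContingencyTable2x2(a, n_cases - a, c, n_controls - c), region_id
        )
        return res
    z = 1.959963984540054  # normal 97.5% quantile
    wald = (beta / se) ** 2
    from scipy.stats import chi2

    return AssocResult(
        region_id=region_id,
        test="logistic_wald",
        p_value=float(chi2.sf(wald, df=1)),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_cases_present=a,
        n_controls_present=c,
    )


def test_regions(
    regions,
    phenotypes: PhenotypeTable,
    covariates: Optional[pd.DataFrame] = None,
    alpha: float = 0.01,
    bh_column: bool = False,
) -> list[AssocResult]:
    """Per-region dispatch: any observed cell < 5 goes to Fisher, else logistic.

    Results come back sorted by p-value. When ``bh_column`` is set, each
    result gains a ``p_bh`` attribute with the Benjamini-Hochberg adjusted
    p-value (off by default; the raw p < alpha rule is the primary output).
    """
    subject_ids = list(phenotypes.df["iid"])
    idx = {s: i for i, s in enumerate(subject_ids)}
    results: list[AssocResult] = []
    for k, region in enumerate(regions):
        rid = getattr(region, "region_id", None)
        if rid is None:
            rid = k
        present = getattr(region, "present_subjects", region)
        table = build_table(present, phenotypes)
        if table.min_cell < SMALL_CELL:
            results.append(fisher_exact(table, region_id=rid))
        else:
            presence = np.zeros(len(subject_ids))
            for s in present:
                presence[idx[s]] = 1.0
            results.append(
                logistic_wald(presence, phenotypes, covariates, subject_ids, rid)
            )
    results.sort(key=lambda r: (r.p_value, str(r.region_id)))
    if bh_column and results:
        from statsmodels.stats.multitest import multipletests

        p_bh = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, p_bh):
            r.p_bh = float(q)
    return results
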