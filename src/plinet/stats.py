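"""Nonparametric group comparisons and brain-behavior correlations.

The statistical design mirrors a small-cohort exploratory study: two-sided
Wilcoxon rank-sum tests for group differences on each network measure
(collapsed across frequency bands), Spearman rank correlations between
every measure x band and each behavioral covariate, significance at
p < 0.05 (strict), and no multiple-comparison correction by default
(Benjamini-Hochberg is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    CORRELATION_COVARIATES,
    CohortTable,
    MEASURE_NAMES,
)

log = logging.getLogger(__name__)


@dataclass
class StatResult:
    """One test: a group contrast (rank_sum) or a correlation (spearman)."""

    kind: str                  # {"rank_sum", "spearman"}
    measure: str               # measure name, possibly with band suffix
    band: str                  # band name or "collapsed"
    covariate: str             # behavioral name or "group"
    n_used: int
    statistic: float
    p: float
    rho: float | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0 <= self.p <= 1):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.rho is not None and not np.isnan(self.rho):
            if not -1 - 1e-12 <= self.rho <= 1 + 1e-12:
                raise ValueError(f"rho {self.rho} outside [-1, 1]")


def _drop_missing(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def rank_sum_test(a, b, measure: str = "", band: str = "collapsed",
                  alpha: float = 0.05) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have at most 10 non-missing values
    and the pooled data are tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a, b = _drop_missing(a), _drop_missing(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one non-missing value")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    p = float(res.pvalue)
    return StatResult(
        kind="rank_sum", measure=measure, band=band, covariate="group",
        n_used=len(a) + len(b), statistic=float(res.statistic), p=p,
        significant=bool(p < alpha),
    )


def spearman_corr(x, y, measure: str = "", band: str = "", covariate: str = "",
                  alpha: float = 0.05) -> StatResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    rho is the Pearson correlation of average ranks; the p-value uses the
    t-distribution approximation. A zero-variance rank vector (constant
    input) leaves rho undefined (NaN, flagged non-significant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input for %s/%s ~ %s: Spearman rho undefined",
                    measure, band, covariate)
        rho, p = float("nan"), float("nan")
    else:
        res = sps.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        kind="spearman", measure=measure, band=band, covariate=covariate,
        n_used=n, statistic=rho, p=p, rho=rho,
        significant=bool(p < alpha) if not np.isnan(p) else False,
    )


# ---------------------------------------------------------------------------
# Whole-cohort sweep
# ---------------------------------------------------------------------------

def _wide_measures(measures_long: pd.DataFrame) -> pd.DataFrame:
    """Long (id, band, measure, value) -> wide with (band, measure) columns."""
    return measures_long.pivot_table(
        index="id", columns=["band", "measure"], values="value", sort=False
    )


def run_comparisons(
    measures_long: pd.DataFrame,
    cohort: CohortTable,
    covariates: list[str] | None = None,
    band_collapse: str = "mean",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[StatResult]:
    """Full statistical sweep of the study design.

    (a) Rank-sum agPPA vs PPAOS per measure, collapsed across bands
    (per-subject mean by default, ``band_collapse="pool"`` pools
    band values as separate observations);
    (b) Spearman between every measure x band and each behavioral
    covariate, pairwise deletion, no correction unless ``bh_correction``.

    ``measures_long`` has columns (id, band, measure, value) as produced
    by :func:`plinet.types.measures_frame`.
    """
    covariates = covariates or CORRELATION_COVARIATES
    unknown = set(covariates) - set(cohort.df.columns)
    if unknown:
        raise KeyError(f"unknown covariate(s): {sorted(unknown)}")
    ids = set(measures_long["id"])
    if not ids <= set(cohort.ids):
        raise KeyError(f"subjects absent from cohort: {sorted(ids - set(cohort.ids))}")

    cdf = cohort.df.set_index("id")
    bands = list(dict.fromkeys(measures_long["band"]))
    results: list[StatResult] = []

    # (a) group contrasts, collapsed across bands
    for name in MEASURE_NAMES:
        sub = measures_long[measures_long["measure"] == name]
        if sub.empty:
            continue
        if band_collapse == "mean":
            per_subj = sub.groupby("id", sort=False)["value"].mean()
            grp = cdf.loc[per_subj.index, "group"]
            a = per_subj[grp == "agPPA"].to_numpy()
            b = per_subj[grp == "PPAOS"].to_numpy()
        else:  # pool band values as separate observations
            grp = cdf.loc[sub["id"], "group"].to_numpy()
            a = sub["value"].to_numpy()[grp == "agPPA"]
            b = sub["value"].to_numpy()[grp == "PPAOS"]
        results.append(rank_sum_test(a, b, measure=name, alpha=alpha))

    # (b) correlations per measure x band x covariate
    wide = _wide_measures(measures_long)
    for cov in covariates:
        yv = cdf.loc[wide.index, cov].to_numpy(dtype=float)
        if np.all(np.isnan(yv)):
            log.warning("covariate %s entirely missing: column skipped", cov)
            continue
        for band in bands:
            for name in MEASURE_NAMES:
                if (band, name) not in wide.columns:
                    continue
                xv = wide[(band, name)].to_numpy(dtype=float)
                results.append(
                    spearman_corr(xv, yv, measure=name, band=band,
                                  covariate=cov, alpha=alpha)
                )

    if bh_correction:
        _apply_bh(results, alpha)
    return results


def _apply_bh(results: list[StatResult], alpha: float) -> None:
    """Benjamini-Hochberg across the correlation results, in place."""
    corr = [r for r in results if r.kind == "spearman" and not np.isnan(r.p)]
    m = len(corr)
    if m == 0:
        return
    order = np.argsort([r.p for r in corr])
    thresh = 0.0
    for rank, idx in enumerate(order, start=1):
        if corr[idx].p <= rank / m * alpha:
            thresh = corr[idx].p
    for r in corr:
        r.significant = bool(r.p <= thresh) if thresh > 0 else False


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def results_frame(results: list[StatResult]) -> pd.DataFrame:
    rows = [
        {
            "kind": r.kind, "measure": r.measure, "band": r.band,
            "covariate": r.covariate, "n_used": r.n_used,
            "statistic": r.statistic, "rho": r.rho, "p": r.p,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["kind", "measure", "band", "covariate", "n_used",
                       "statistic", "rho", "p", "significant"],
    )


def significance_report(results: list[StatResult], path=None,
                        alpha: float = 0.05, corrected: bool = False,
                        ) -> pd.DataFrame:
    """Correlation grid of rho with ``*`` markers at p < alpha (strict).

    Rows are band x measure, columns are covariates; a provenance footer
    states the correction policy. Returns the grid; writes TSV when a
    path is given.
    """
    corr = [r for r in results if r.kind == "spearman"]
    rows = sorted(
        {(r.band, r.measure) for r in corr},
        key=lambda bm: ([r.band for r in corr].index(bm[0]),
                        MEASURE_NAMES.index(bm[1])),
    )
    cols = list(dict.fromkeys(r.covariate for r in corr))
    cell = {(r.band, r.measure, r.covariate): r for r in corr}
    grid = pd.DataFrame(index=pd.MultiIndex.from_tuples(rows, names=["band", "measure"]),
                        columns=cols, dtype=object)
    for (band, meas) in rows:
        for cov in cols:
            r = cell.get((band, meas, cov))
            if r is None or r.rho is None or np.isnan(r.rho):
                grid.loc[(band, meas), cov] = ""
            else:
                mark = " *" if (r.p < alpha) else ""
                grid.loc[(band, meas), cov] = f"{r.rho:.4f}{mark}"
    if path is not None:
        with open(path, "w") as fh:
            grid.to_csv(fh, sep="\t")
            policy = ("Benjamini-Hochberg corrected" if corrected
                      else "no multiple-comparison correction")
            fh.write(f"# * marks p < {alpha} (strict); {policy}\n")
    return grid
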