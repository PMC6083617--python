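"""Phenotype regression on PRS and best-threshold selection.

For each p-value threshold the phenotype is regressed on that threshold's
averaged PRS by ordinary least squares (one predictor, intercept included).
The fit is summarized by unadjusted R-squared, the model F statistic on
(1, n-2) degrees of freedom, and its two-sided p-value; the "best fit" across
thresholds is the model with maximal R-squared, ties going to the smaller
(more parsimonious) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EvaluationError
from .scoring import ScoreTable


@dataclass(frozen=True)
class FitResult:
    threshold: float
    n: int
    r_squared: float
    f_stat: float
    p_value: float
    slope_sign: int
    #: True when the PRS had zero variance and the fit is undefined
    degenerate: bool = False

    @property
    def r_squared_adj(self) -> float:
        if self.degenerate or self.n < 3:
            return float("nan")
        return 1.0 - (1.0 - self.r_squared) * (self.n - 1) / (self.n - 2)


def read_phenotype(path) -> pd.Series:
    """Read a two-column delimited phenotype table (sample_id, value)."""
    df = pd.read_csv(path, sep=r"\s+", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise EvaluationError(f"{path}: phenotype table needs two columns")
    return pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="coerce").values,
        index=df.iloc[:, 0].astype(str).values,
    )


def fit_prs_phenotype(
    scores: ScoreTable,
    phenotype: pd.Series,
    threshold: float,
) -> FitResult:
    """OLS of phenotype on the averaged PRS at one threshold.

    Samples with an undefined score (zero SNP count) or a missing phenotype
    are dropped pairwise; fewer than 3 complete pairs is an error.  A PRS
    with zero variance yields a flagged degenerate result rather than a fit.
    """
    try:
        t_idx = list(scores.thresholds).index(threshold)
    except ValueError:
        raise EvaluationError(f"threshold {threshold} not in score table")
    prs = pd.Series(scores.avg_scores[t_idx], index=scores.sample_ids)
    pheno = phenotype.reindex(scores.sample_ids)
    keep = prs.notna() & pheno.notna()
    x, y = prs[keep].to_numpy(), pheno[keep].to_numpy()
    n = int(keep.sum())
    if n < 3:
        raise EvaluationError(
            f"threshold {threshold}: only {n} complete (score, phenotype) pairs"
        )
    if np.ptp(x) == 0.0:
        return FitResult(threshold=threshold, n=n, r_squared=float("nan"),
                         f_stat=float("nan"), p_value=float("nan"),
                         slope_sign=0, degenerate=True)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = model.params[1]
    return FitResult(
        threshold=threshold,
        n=n,
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        slope_sign=int(np.sign(slope)),
    )


def best_fit(results: list[FitResult]) -> FitResult:
    """The result with maximal R-squared; ties broken by smaller threshold.

    Degenerate fits never win unless every fit is degenerate.
    """
    if not results:
        raise EvaluationError("no fit results to choose from")
    usable = [r for r in results if not r.degenerate] or list(results)
    return min(usable, key=lambda r: (-(r.r_squared if not r.degenerate else -np.inf),
                                      r.threshold))


def write_fit_report(results: list[FitResult], path) -> None:
    """Tab-delimited FitResult table with the best fit flagged."""
    best = best_fit(results)
    with open(path, "w") as fh:
        fh.write("threshold\tn\tr_squared\tr_squared_adj\tf_stat\tp_value\t"
                 "slope_sign\tbest_fit\n")
        for r in sorted(results, key=lambda r: r.threshold):
            fh.write(
                f"{r.threshold:g}\t{r.n}\t{r.r_squared:.10g}\t{r.r_squared_adj:.10g}\t"
                f"{r.f_stat:.10g}\t{r.p_value:.10g}\t{r.slope_sign}\t"
                f"{'*' if r is best else ''}\n"
            )
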