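"""Method-agreement analytics: Bland-Altman and all-pairs formula matrices.

Differences are always oriented ``a - b`` and every result records the
orientation string, to keep the sign convention explicit (e.g. a
negative USG - LMP mean difference means LMP overestimates GA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import PipelineError
from .formulae import predict_ga
from .fpreg import FPModel, r_squared

__all__ = ["BAResult", "bland_altman", "PairwiseBAMatrix",
           "pairwise_formula_matrix", "evaluate_on_test"]

#: Limits-of-agreement multiplier for 95% limits (no small-sample t
#: correction by default; pass ``t_correction=True`` for one).
LOA_Z = 1.96


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman summary of paired differences ``a - b`` (weeks)."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pct_outside_loa: float
    orientation: str = "a - b"
    trend_slope: Optional[float] = None
    trend_ci: Optional[tuple] = None


def bland_altman(
    ga_a,
    ga_b,
    orientation: str = "a - b",
    trend: bool = False,
    t_correction: bool = False,
) -> BAResult:
    """Bland-Altman analysis of two paired GA assignments.

    Mean and SD (n-1 denominator) of the differences, limits of
    agreement mean +/- 1.96*SD, and the strict percentage of pairs
    outside the closed LoA interval.  With ``trend=True`` an OLS slope
    of difference on pair mean is reported with its 95% CI.
    """
    a = np.asarray(ga_a, dtype=float)
    b = np.asarray(ga_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired vectors must be finite")

    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    z = LOA_Z
    if t_correction:
        from scipy.stats import t as t_dist

        z = float(t_dist.ppf(0.975, len(diff) - 1))
    lo, hi = mean_diff - z * sd_diff, mean_diff + z * sd_diff
    outside = float(np.mean((diff < lo) | (diff > hi)) * 100.0)

    slope = ci = None
    if trend:
        mean_ab = (a + b) / 2.0
        fit = sm.OLS(diff, sm.add_constant(mean_ab)).fit()
        slope = float(fit.params[1])
        ci_arr = fit.conf_int(alpha=0.05)
        ci = (float(ci_arr[1][0]), float(ci_arr[1][1]))

    return BAResult(
        n=len(diff),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=lo,
        loa_upper=hi,
        pct_outside_loa=outside,
        orientation=orientation,
        trend_slope=slope,
        trend_ci=ci,
    )


@dataclass
class PairwiseBAMatrix:
    """All ordered pairs of formula BA results on one cohort."""

    formula_ids: list
    results: dict  # (id_a, id_b) -> BAResult

    def get(self, id_a: str, id_b: str) -> BAResult:
        return self.results[(id_a, id_b)]

    def mean_diff_frame(self) -> pd.DataFrame:
        ids = self.formula_ids
        return pd.DataFrame(
            [[self.results[(r, c)].mean_diff for c in ids] for r in ids],
            index=ids,
            columns=ids,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ia, ib), res in self.results.items():
            rows.append(
                {
                    "formula_a": ia,
                    "formula_b": ib,
                    "n": res.n,
                    "mean_diff": res.mean_diff,
                    "sd_diff": res.sd_diff,
                    "loa_lower": res.loa_lower,
                    "loa_upper": res.loa_upper,
                    "pct_outside_loa": res.pct_outside_loa,
                }
            )
        return pd.DataFrame(rows)


def _method_ga(cohort: CohortTable, formula_id: str, obs: pd.DataFrame):
    if formula_id == "lmp":
        return obs["ga_lmp_weeks"].to_numpy(float)
    return predict_ga(formula_id, obs["crl_cm"].to_numpy(float))


def pairwise_formula_matrix(
    cohort: CohortTable, formula_ids: Sequence[str]
) -> PairwiseBAMatrix:
    """BA of every ordered formula pair on the cohort's CRL rows.

    Entry (i, j) has mean_diff equal to minus that of (j, i); the
    diagonal is the zero element.  The pseudo-id ``"lmp"`` compares
    against the LMP-based GA column.
    """
    ids = list(formula_ids)
    if len(ids) < 2:
        raise ValueError("need at least two formulae to compare")
    obs = cohort.observations
    mask = obs["crl_cm"].notna()
    if "lmp" in ids:
        mask &= obs["ga_lmp_weeks"].notna()
    obs = obs.loc[mask]
    if len(obs) < 2:
        raise PipelineError("fewer than 2 usable rows with CRL")

    ga = {fid: _method_ga(cohort, fid, obs) for fid in ids}
    results = {}
    for ia in ids:
        for ib in ids:
            results[(ia, ib)] = bland_altman(
                ga[ia], ga[ib], orientation=f"{ia} - {ib}"
            )
    return PairwiseBAMatrix(ids, results)


def evaluate_on_test(
    model_or_formula: Union[FPModel, str],
    test_cohort: CohortTable,
    truth_column: str = "ga_lmp_weeks",
) -> tuple[float, BAResult]:
    """R² and BA of a model/formula against a truth column on a test cohort.

    ``truth_column`` must name an observation column (LMP-based GA on
    real data; a merged true-GA column on synthetic data).
    """
    obs = test_cohort.observations
    if truth_column not in obs.columns:
        raise ValueError(f"truth column {truth_column!r} not in observations")
    usable = obs.loc[obs["crl_cm"].notna() & obs[truth_column].notna()]
    if len(usable) < 2:
        raise PipelineError("test set has fewer than 2 usable rows")
    crl = usable["crl_cm"].to_numpy(float)
    truth = usable[truth_column].to_numpy(float)
    if isinstance(model_or_formula, FPModel):
        pred = model_or_formula.predict(crl)
        label = "fp_model"
    else:
        pred = predict_ga(model_or_formula, crl)
        label = str(model_or_formula)
    r2 = r_squared(truth, pred)
    ba = bland_altman(pred, truth, orientation=f"{label} - {truth_column}")
    return r2, ba
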