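"""Preterm-birth classification and inter-method agreement.

Preterm means delivery before 37 completed weeks: GA < 37.0 exactly,
boundary 37.0 is term.  Per-method delivery GA anchors on the dating
scan's method-specific GA plus the calendar time elapsed to delivery.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable
from .errors import ValidationError
from .formulae import predict_ga

logger = logging.getLogger("gestage.ptb")

__all__ = [
    "classify_ptb",
    "PTBRate",
    "ptb_rate",
    "fisher_pairwise",
    "jaccard",
    "jaccard_matrix",
    "ClassificationMetrics",
    "classification_metrics",
    "PTBComparison",
    "ptb_report",
]

PTB_THRESHOLD_WEEKS = 37.0


def classify_ptb(ga_delivery_weeks):
    """Preterm flag(s): GA at delivery strictly below 37.0 weeks."""
    scalar = np.isscalar(ga_delivery_weeks)
    ga = np.atleast_1d(np.asarray(ga_delivery_weeks, dtype=float))
    if np.any(~np.isfinite(ga)) or np.any(ga < 0) or np.any(ga > 50):
        raise ValidationError(
            "delivery GA must be finite and within (0, 50] weeks"
        )
    flags = ga < PTB_THRESHOLD_WEEKS
    return bool(flags[0]) if scalar else flags


@dataclass(frozen=True)
class PTBRate:
    """Rate per 100 with a 95% CI on the same scale."""

    rate: float
    ci_lower: float
    ci_upper: float
    k: int
    n: int
    ci_method: str = "wilson"


def ptb_rate(flags, ci_method: str = "wilson") -> PTBRate:
    """PTB rate per 100 with 95% CI (Wilson score default,
    ``ci_method='beta'`` for exact Clopper-Pearson)."""
    flags = np.asarray(flags, dtype=bool)
    n = len(flags)
    if n == 0:
        raise ValidationError("ptb_rate needs at least one classification")
    if ci_method not in ("wilson", "beta"):
        raise ValueError("ci_method must be 'wilson' or 'beta'")
    k = int(flags.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    return PTBRate(
        rate=100.0 * k / n,
        ci_lower=100.0 * float(lo),
        ci_upper=100.0 * float(hi),
        k=k,
        n=n,
        ci_method=ci_method,
    )


def fisher_pairwise(
    k_vector: Sequence[int],
    n_vector: Sequence[int],
    correction: str = "bonferroni",
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Two-sided Fisher's exact p for every 2x2 (preterm, term) pair.

    With Bonferroni correction each p is multiplied by the number of
    pairs and capped at 1.  Diagonal is 1.
    """
    k = np.asarray(k_vector, dtype=int)
    n = np.asarray(n_vector, dtype=int)
    if k.shape != n.shape:
        raise ValueError("k and n vectors must have equal length")
    if np.any(n <= 0):
        raise ValidationError("zero denominators are not allowed")
    if np.any(k > n) or np.any(k < 0):
        raise ValidationError("counts must satisfy 0 <= k <= n")
    m = len(k)
    labels = list(labels) if labels is not None else list(range(m))
    n_pairs = m * (m - 1) // 2
    mult = n_pairs if correction == "bonferroni" else 1
    out = np.ones((m, m))
    for i, j in itertools.combinations(range(m), 2):
        table = [[k[i], n[i] - k[i]], [k[j], n[j] - k[j]]]
        _, p = fisher_exact(table, alternative="two-sided")
        p_adj = min(1.0, mult * p)
        out[i, j] = out[j, i] = p_adj
    return pd.DataFrame(out, index=labels, columns=labels)


def jaccard(preterm_set_a, preterm_set_b) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 1.0 when both sets are empty."""
    a, b = set(preterm_set_a), set(preterm_set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def jaccard_matrix(preterm_sets: Mapping[str, set]) -> pd.DataFrame:
    ids = list(preterm_sets)
    out = pd.DataFrame(1.0, index=ids, columns=ids)
    for i, j in itertools.combinations(ids, 2):
        v = jaccard(preterm_sets[i], preterm_sets[j])
        out.loc[i, j] = out.loc[j, i] = v
    return out


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    flags: tuple = ()


def classification_metrics(pred_flags, reference_flags) -> ClassificationMetrics:
    """Sensitivity, specificity and their mean (balanced accuracy).

    When the reference contains only one class the affected metric is
    NaN and named in ``flags``.
    """
    pred = np.asarray(pred_flags, dtype=bool)
    ref = np.asarray(reference_flags, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must have equal length")
    tp = int(np.sum(pred & ref))
    fn = int(np.sum(~pred & ref))
    fp = int(np.sum(pred & ~ref))
    tn = int(np.sum(~pred & ~ref))
    flags = []
    if tp + fn == 0:
        sens = float("nan")
        flags.append("sensitivity_undefined")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        spec = float("nan")
        flags.append("specificity_undefined")
    else:
        spec = tn / (tn + fp)
    bal = (sens + spec) / 2.0
    return ClassificationMetrics(sens, spec, bal, tuple(flags))


@dataclass
class PTBComparison:
    """Full inter-method PTB comparison on one cohort."""

    classifications: pd.DataFrame      # participants x methods, bool
    ga_delivery: pd.DataFrame          # participants x methods, weeks
    rates: dict                        # method -> PTBRate
    fisher_p: pd.DataFrame             # Bonferroni-adjusted p matrix
    jaccard: pd.DataFrame
    metrics: dict = field(default_factory=dict)   # method -> ClassificationMetrics
    reference: Optional[str] = None
    n_dropped_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "methods": list(self.classifications.columns),
            "reference": self.reference,
            "n_participants": len(self.classifications),
            "n_dropped_missing_outcome": self.n_dropped_missing,
            "rates": {
                m: {
                    "rate_per_100": r.rate,
                    "ci_95": [r.ci_lower, r.ci_upper],
                    "k": r.k,
                    "n": r.n,
                    "ci_method": r.ci_method,
                }
                for m, r in self.rates.items()
            },
            "fisher_p_bonferroni": self.fisher_p.to_dict(),
            "jaccard": self.jaccard.to_dict(),
            "metrics": {
                m: {
                    "sensitivity": v.sensitivity,
                    "specificity": v.specificity,
                    "balanced_accuracy": v.balanced_accuracy,
                    "flags": list(v.flags),
                }
                for m, v in self.metrics.items()
            },
        }


def ptb_report(
    cohort: CohortTable,
    formula_ids: Sequence[str],
    reference: Union[str, pd.Series, None] = None,
    anchor_scan: int = 1,
    ci_method: str = "wilson",
) -> PTBComparison:
    """Classify PTB per dating method and compare methods.

    For each method, delivery GA = method GA at the anchor dating scan
    plus (delivery_date - scan_date)/7.  ``reference`` is either a
    method id from ``formula_ids`` or a participant-indexed boolean
    Series of truth labels; metrics are only computed when a reference
    is given (never silently LMP).
    """
    ids = list(formula_ids)
    obs = cohort.observations
    anchored = obs.loc[obs["scan_index"] == anchor_scan]
    if anchored.empty:
        # fall back to each participant's earliest available scan
        anchored = obs.sort_values("scan_index").groupby(
            "participant_id", as_index=False
        ).first()
    merged = anchored.merge(cohort.outcomes, on="participant_id", how="left")

    n_missing = int(merged["delivery_date"].isna().sum())
    merged = merged.loc[merged["delivery_date"].notna()].reset_index(drop=True)
    if n_missing:
        logger.info("ptb_report: dropped %d participant(s) without delivery "
                    "date from denominators", n_missing)
    needs_crl = [f for f in ids if f != "lmp"]
    usable = merged["scan_date"].notna()
    if needs_crl:
        usable &= merged["crl_cm"].notna()
    if "lmp" in ids:
        usable &= merged["ga_lmp_weeks"].notna()
    merged = merged.loc[usable].reset_index(drop=True)
    if merged.empty:
        raise ValidationError("no participants with usable anchor scan + outcome")

    elapsed = (merged["delivery_date"] - merged["scan_date"]).dt.days / 7.0
    ga_del = pd.DataFrame(index=merged["participant_id"])
    for fid in ids:
        if fid == "lmp":
            at_scan = merged["ga_lmp_weeks"].to_numpy(float)
        else:
            at_scan = predict_ga(fid, merged["crl_cm"].to_numpy(float))
        ga_del[fid] = at_scan + elapsed.to_numpy()

    classifications = ga_del.apply(lambda col: classify_ptb(col.to_numpy()))
    rates = {fid: ptb_rate(classifications[fid], ci_method) for fid in ids}
    fisher = fisher_pairwise(
        [rates[f].k for f in ids], [rates[f].n for f in ids], labels=ids
    )
    sets = {
        fid: set(classifications.index[classifications[fid]]) for fid in ids
    }
    jac = jaccard_matrix(sets)

    metrics: dict = {}
    ref_label = None
    if reference is not None:
        if isinstance(reference, str):
            if reference not in ids:
                raise ValueError(
                    f"reference {reference!r} must be one of {ids} or a "
                    "participant-indexed boolean Series"
                )
            ref_flags = classifications[reference]
            ref_label = reference
        else:
            ref_flags = reference.reindex(classifications.index)
            if ref_flags.isna().any():
                missing = int(ref_flags.isna().sum())
                raise ValidationError(
                    f"reference labels missing for {missing} participant(s)"
                )
            ref_flags = ref_flags.astype(bool)
            ref_label = reference.name or "external_reference"
        for fid in ids:
            metrics[fid] = classification_metrics(
                classifications[fid].to_numpy(), ref_flags.to_numpy()
            )

    return PTBComparison(
        classifications=classifications,
        ga_delivery=ga_del,
        rates=rates,
        fisher_p=fisher,
        jaccard=jac,
        metrics=metrics,
        reference=ref_label,
        n_dropped_missing=n_missing,
    )
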