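"""Reference-dataset construction: clinical filtering and DBSCAN denoising.

Two routes to a cleaner training set from raw (CRL, LMP-based GA) pairs:

* :func:`clinical_filter` — config-driven exclusion predicates over
  covariates (unreliable LMP, smoking/tobacco/alcohol, BMI band).
* :func:`dbscan_filter` — density-based outlier removal in the raw
  2-D (CRL cm, GA weeks) plane with declared eps / min_points.

The DBSCAN here is a deterministic classic implementation: a core point
counts itself among its neighbours, clusters are density-connected
components of core points plus border points, and a border point
reachable from several clusters joins the cluster of its lowest-indexed
core neighbour (a fixed tie-break, unlike scan-order-dependent
implementations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cohort import CohortTable
from .errors import ConfigError

logger = logging.getLogger("gestage.denoise")

__all__ = [
    "FilterCriterion",
    "FilterCriteria",
    "default_criteria",
    "clinical_filter",
    "DBSCANParams",
    "dbscan",
    "dbscan_filter",
    "NOISE",
]

#: DBSCAN noise sentinel label.
NOISE = -1


@dataclass(frozen=True)
class FilterCriterion:
    """One exclusion predicate: rows where ``mask`` is True are excluded."""

    name: str
    columns: tuple
    mask: Callable[[pd.DataFrame], pd.Series]
    enabled: bool = True


@dataclass
class FilterCriteria:
    criteria: list = field(default_factory=list)

    def enabled(self) -> list:
        return [c for c in self.criteria if c.enabled]


def _flag_criterion(name: str, column: str) -> FilterCriterion:
    return FilterCriterion(
        name=name,
        columns=(column,),
        mask=lambda df, c=column: df[c].fillna(0).astype(float) > 0,
    )


def default_criteria(
    bmi_lower: float = 18.5, bmi_upper: float = 25.0
) -> FilterCriteria:
    """Default exclusion set: unreliable LMP, smoking/tobacco/alcohol,
    BMI outside [bmi_lower, bmi_upper)."""

    def _bmi_mask(df):
        bmi = df["bmi"].astype(float)
        return bmi.notna() & ((bmi < bmi_lower) | (bmi >= bmi_upper))

    return FilterCriteria(
        [
            _flag_criterion("unreliable_lmp", "unreliable_lmp"),
            _flag_criterion("smoker", "smoker"),
            _flag_criterion("tobacco", "tobacco"),
            _flag_criterion("alcohol", "alcohol"),
            FilterCriterion("bmi_out_of_band", ("bmi",), _bmi_mask),
        ]
    )


def clinical_filter(
    cohort: CohortTable, criteria: Optional[FilterCriteria] = None
) -> tuple[CohortTable, dict]:
    """Apply exclusion predicates; retained rows fail every predicate.

    Returns the filtered table and a log with per-criterion exclusion
    counts (a row excluded by several criteria counts in each).
    Idempotent: re-applying to the output removes nothing.
    """
    criteria = criteria or default_criteria()
    obs = cohort.observations
    missing = [
        col
        for crit in criteria.enabled()
        for col in crit.columns
        if col not in obs.columns
    ]
    if missing:
        raise ConfigError(
            f"clinical filter references missing covariate(s): {sorted(set(missing))}"
        )

    excluded = pd.Series(False, index=obs.index)
    counts: dict[str, int] = {}
    for crit in criteria.enabled():
        m = crit.mask(obs).astype(bool)
        counts[crit.name] = int(m.sum())
        excluded |= m

    retained = obs.loc[~excluded]
    log = {
        "per_criterion": counts,
        "n_excluded": int(excluded.sum()),
        "n_retained": len(retained),
        "n_input": len(obs),
    }
    logger.info("clinical filter: %s", log)
    return cohort.with_observations(retained), log


@dataclass(frozen=True)
class DBSCANParams:
    """eps / min_points in the declared 2-D space (CRL cm, GA weeks).

    ``standardize=False`` (default) keeps raw units so eps has a
    physical meaning; set True to z-score each axis first.
    """

    eps: float = 0.5
    min_points: int = 20
    standardize: bool = False

    def __post_init__(self):
        if self.eps <= 0:
            raise ConfigError("eps must be > 0")
        if self.min_points < 1:
            raise ConfigError("min_points must be >= 1")


def dbscan(points_2d, params: DBSCANParams) -> np.ndarray:
    """Classic DBSCAN labels for ``points_2d`` (n x 2).

    Returns cluster ids 0, 1, ... (numbered by each cluster's
    lowest-indexed core point) and ``NOISE`` (-1) for noise.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    if pts.ndim != 2:
        raise ValueError("points_2d must be an (n, d) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("DBSCAN requires finite coordinates")
    if params.standardize:
        sd = pts.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd

    n = len(pts)
    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(pts, r=params.eps)  # inclusive, self in
    core = np.array([len(nb) >= params.min_points for nb in neighbours])

    labels = np.full(n, NOISE, dtype=int)
    # density-connect core points (union-find on core-core neighbour pairs)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in np.flatnonzero(core):
        for j in neighbours[i]:
            if core[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    roots = {}
    for i in np.flatnonzero(core):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)  # clusters ordered by lowest core index
        labels[i] = roots[r]

    # border points: cluster of the lowest-indexed core neighbour
    for i in np.flatnonzero(~core):
        core_nb = [j for j in sorted(neighbours[i]) if core[j]]
        if core_nb:
            labels[i] = labels[core_nb[0]]
    return labels


def dbscan_filter(
    cohort: CohortTable, params: Optional[DBSCANParams] = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Remove DBSCAN-noise rows in the (CRL, GA_LMP) plane.

    Rows missing CRL or GA are ineligible and removed with reason
    ``missing_fields``; noise rows get reason ``dbscan_noise``.  Returns
    the retained table and the removed rows (with a ``reason`` column).
    """
    params = params or DBSCANParams()
    obs = cohort.observations
    eligible = obs["crl_cm"].notna() & obs["ga_lmp_weeks"].notna()
    pts = obs.loc[eligible, ["crl_cm", "ga_lmp_weeks"]].to_numpy(float)

    if len(pts) < params.min_points:
        warnings.warn(
            f"dbscan_filter: only {len(pts)} eligible rows "
            f"(< min_points={params.min_points}); all labelled noise"
        )
        labels = np.full(len(pts), NOISE, dtype=int)
    else:
        labels = dbscan(pts, params)

    keep_idx = obs.index[eligible][labels != NOISE]
    removed = obs.loc[~obs.index.isin(keep_idx)].copy()
    removed["reason"] = np.where(
        eligible.loc[removed.index], "dbscan_noise", "missing_fields"
    )
    retained = cohort.with_observations(obs.loc[keep_idx])
    n_elig = int(eligible.sum())
    retained.metadata.update(
        dbscan_params={
            "eps": params.eps,
            "min_points": params.min_points,
            "standardize": params.standardize,
            "feature_space": "raw (crl_cm, ga_lmp_weeks)"
            if not params.standardize
            else "z-scored (crl_cm, ga_lmp_weeks)",
        },
        dbscan_retained_fraction=(
            float((labels != NOISE).sum()) / n_elig if n_elig else float("nan")
        ),
    )
    logger.info(
        "dbscan_filter: retained %d / %d eligible rows (eps=%s, min_points=%s)",
        int((labels != NOISE).sum()), n_elig, params.eps, params.min_points,
    )
    return retained, removed.reset_index(drop=True)
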