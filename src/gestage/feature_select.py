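"""Covariate selection beyond CRL: Boruta-style shadow-feature selection,
GLM (L1 / stepwise-AIC) selection, their union, and candidate-equation
enumeration.

The Boruta loop: each round appends one permuted "shadow" copy per
candidate feature, fits a random-forest regressor, scores a *hit* for
every real feature whose importance exceeds the round's maximum shadow
importance, and decides confirmed/rejected via one-sided binomial tests
on the accumulated hit counts (Bonferroni-corrected across the candidate
universe).  The GLM route's criterion is unstated upstream; both modes
here (cross-validated L1 and backward stepwise by AIC) are assumptions
and the method used is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, DomainError
from .fpreg import FPPOWERS

logger = logging.getLogger("gestage.feature_select")

__all__ = [
    "SelectionResult",
    "boruta_select",
    "glm_select",
    "union_features",
    "CandidateSpec",
    "build_candidate_equations",
    "fit_candidate_specs",
    "DEFAULT_CANDIDATES",
]

#: Default candidate covariates shipped with the synthetic generator.
DEFAULT_CANDIDATES = (
    "resident_state",
    "weight",
    "bmi",
    "abdominal_girth",
    "age",
    "maternal_education",
)


@dataclass
class SelectionResult:
    """Partition of the candidate universe after a selection run."""

    confirmed: frozenset
    rejected: frozenset
    tentative: frozenset
    method: str
    importance_history: Optional[pd.DataFrame] = None
    seed: Optional[int] = None
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        sets = (self.confirmed, self.rejected, self.tentative)
        total = len(self.confirmed | self.rejected | self.tentative)
        if sum(map(len, sets)) != total:
            raise ValueError("confirmed/rejected/tentative must be disjoint")

    @property
    def universe(self) -> frozenset:
        return self.confirmed | self.rejected | self.tentative

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "confirmed": sorted(self.confirmed),
            "rejected": sorted(self.rejected),
            "tentative": sorted(self.tentative),
            "details": self.details,
        }


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.isna().any().any():
        raise ValueError("X must not contain missing values (impute upstream)")
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if float(np.var(y)) == 0.0:
        raise DomainError("y is constant; selection target must vary")


def boruta_select(
    X: pd.DataFrame,
    y,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 300,
    importance: str = "impurity",
    correction: str = "bonferroni",
    max_features: float = 1 / 3,
    n_shadow_copies: int = 3,
) -> SelectionResult:
    """Shadow-feature random-forest selection on a regression target.

    Stops at ``max_iter`` rounds or when no feature remains tentative.
    Deterministic under ``seed``.  Two guards against spurious confirms:
    the design's column order is shuffled every round (tree splitters
    break ties by column position, which would otherwise favour real
    features over shadows on a pure-noise target), and each feature
    contributes ``n_shadow_copies`` independently permuted shadows so
    the shadow-max bar sits in the tail of the chance-importance
    distribution rather than at its median.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(X, y)
    if len(X) < 10:
        raise ValueError("too few rows for forest-based selection")
    features = list(X.columns)
    m = len(features)
    divisor = m if correction == "bonferroni" else 1
    thr = alpha / divisor

    rng = np.random.default_rng(seed)
    hits = {f: 0 for f in features}
    status = {f: "tentative" for f in features}
    history = []

    n_rounds = 0
    for it in range(1, max_iter + 1):
        n_rounds = it
        shadow_blocks = []
        for rep in range(max(1, n_shadow_copies)):
            blk = X.apply(lambda col: rng.permutation(col.to_numpy()))
            blk.columns = [f"shadow{rep}__{c}" for c in X.columns]
            shadow_blocks.append(blk)
        design = pd.concat([X] + shadow_blocks, axis=1)
        col_perm = rng.permutation(design.shape[1])
        mat = design.to_numpy()[:, col_perm]

        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(mat, y)
        if importance == "permutation":
            imp_perm = permutation_importance(
                forest, mat, y, n_repeats=5,
                random_state=int(rng.integers(2**31 - 1)),
            ).importances_mean
        else:
            imp_perm = forest.feature_importances_
        imp = np.empty_like(imp_perm)
        imp[col_perm] = imp_perm
        real_imp = dict(zip(design.columns[: len(features)], imp[: len(features)]))
        shadow_max = float(imp[len(features):].max())

        row = {"iteration": it, "shadow_max": shadow_max}
        for f in features:
            row[f] = real_imp[f]
            if status[f] == "tentative" and real_imp[f] > shadow_max:
                hits[f] += 1
        history.append(row)

        for f in features:
            if status[f] != "tentative":
                continue
            if binomtest(hits[f], it, 0.5, alternative="greater").pvalue < thr:
                status[f] = "confirmed"
            elif binomtest(hits[f], it, 0.5, alternative="less").pvalue < thr:
                status[f] = "rejected"
        if all(s != "tentative" for s in status.values()):
            break

    result = SelectionResult(
        confirmed=frozenset(f for f, s in status.items() if s == "confirmed"),
        rejected=frozenset(f for f, s in status.items() if s == "rejected"),
        tentative=frozenset(f for f, s in status.items() if s == "tentative"),
        method="boruta",
        importance_history=pd.DataFrame(history),
        seed=seed,
        details={"n_rounds": n_rounds, "alpha": alpha, "correction": correction,
                 "hits": dict(hits)},
    )
    logger.info("boruta: %s", result.to_dict())
    return result


def glm_select(
    X: pd.DataFrame,
    y,
    method: str = "lasso",
    alpha_or_penalty: Optional[float] = None,
    seed: int = 0,
    cv: int = 5,
) -> SelectionResult:
    """GLM-based selection.

    ``method='lasso'`` (default): standardized L1 regression; penalty
    chosen by cross-validation when ``alpha_or_penalty`` is None, a
    fixed penalty otherwise (0 falls back to OLS; inf confirms
    nothing).  ``method='stepwise'``: backward elimination by AIC.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(X, y)
    features = list(X.columns)

    if method == "lasso":
        Xs = StandardScaler().fit_transform(X.to_numpy(float))
        penalty = alpha_or_penalty
        if penalty is not None and np.isinf(penalty):
            coefs = np.zeros(len(features))
            chosen = float("inf")
        else:
            if penalty is None:
                model = LassoCV(cv=cv, random_state=seed, max_iter=50_000)
            elif penalty == 0:
                model = LinearRegression()
            else:
                model = Lasso(alpha=penalty, max_iter=50_000)
            model.fit(Xs, y)
            coefs = np.asarray(model.coef_, dtype=float)
            chosen = float(getattr(model, "alpha_", penalty if penalty is not None else 0.0))
        confirmed = {f for f, c in zip(features, coefs) if abs(c) > 1e-10}
        details = {"penalty": chosen,
                   "coefficients": dict(zip(features, map(float, coefs)))}
    elif method == "stepwise":
        import statsmodels.api as sm

        Xmat = X.to_numpy(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(Xmat)), Xmat])) < (
            Xmat.shape[1] + 1
        ):
            raise DomainError(
                "design matrix is rank deficient; drop collinear columns or "
                "use method='lasso'"
            )
        remaining = list(features)
        alpha_level = alpha_or_penalty  # unused threshold; AIC drives steps

        def _aic(cols):
            design = sm.add_constant(X[cols].to_numpy(float)) if cols else \
                np.ones((len(X), 1))
            return sm.OLS(y, design).fit().aic

        current = _aic(remaining)
        improved = True
        while improved and remaining:
            improved = False
            options = [(c, _aic([f for f in remaining if f != c]))
                       for c in remaining]
            cand, aic = min(options, key=lambda t: t[1])
            if aic < current:
                remaining.remove(cand)
                current = aic
                improved = True
        confirmed = set(remaining)
        details = {"final_aic": float(current), "alpha": alpha_level}
    else:
        raise ValueError("method must be 'lasso' or 'stepwise'")

    return SelectionResult(
        confirmed=frozenset(confirmed),
        rejected=frozenset(features) - frozenset(confirmed),
        tentative=frozenset(),
        method=f"glm-{method}",
        seed=seed,
        details=details,
    )


def union_features(a: SelectionResult, b: SelectionResult) -> frozenset:
    """Union of the two confirmed sets (same candidate universe required)."""
    if a.universe != b.universe:
        raise ConfigError(
            "selection results come from different candidate universes"
        )
    return frozenset(a.confirmed | b.confirmed)


# ---------------------------------------------------------------------------
# candidate multivariate equations

#: transform name -> (column expansion description, per-feature variants)
_FORM_VARIANTS = {
    "linear": [("linear",)],
    "log": [("log",)],
    "polynomial": [("poly2",)],
    "fractional": [(f"pow_{p}",) for p in FPPOWERS],
}


@dataclass(frozen=True)
class CandidateSpec:
    """One multivariate model spec: CRL base terms + per-feature transforms."""

    terms: tuple  # of (column, transform) pairs; CRL base included
    crl_included: bool = True

    def describe(self) -> str:
        return " + ".join(f"{t}({c})" for c, t in self.terms)


def build_candidate_equations(
    features: Sequence[str],
    crl_included: bool = True,
    forms: Sequence[str] = ("linear",),
    max_specs: int = 100_000,
) -> list[CandidateSpec]:
    """Enumerate model specs over non-empty feature subsets x transforms.

    The first spec returned is the CRL-only baseline.  Each feature in a
    subset takes one transform variant drawn from ``forms``
    (linear -> x; log -> log x; polynomial -> x + x²; fractional -> x^p
    for each FP power).
    """
    unknown = set(forms) - set(_FORM_VARIANTS)
    if unknown:
        raise ValueError(f"unknown form(s): {sorted(unknown)}")
    variants = [v for f in forms for v in _FORM_VARIANTS[f]]
    base = (("crl_cm", "linear"), ("crl_cm", "square")) if crl_included else ()

    specs = [CandidateSpec(terms=base, crl_included=crl_included)]
    features = list(features)
    count = 1
    for r in range(1, len(features) + 1):
        for subset in combinations(features, r):
            count += len(variants) ** r
            if count > max_specs:
                raise ConfigError(
                    f"candidate enumeration exceeds {max_specs} specs; "
                    "restrict forms or features"
                )
            for choice in product(variants, repeat=r):
                terms = base + tuple(
                    (feat, var[0]) for feat, var in zip(subset, choice)
                )
                specs.append(CandidateSpec(terms=terms, crl_included=crl_included))
    return specs


def _term_columns(df: pd.DataFrame, column: str, transform: str) -> list[np.ndarray]:
    x = df[column].to_numpy(float)
    if transform == "linear":
        return [x]
    if transform == "square":
        return [x**2]
    if transform == "poly2":
        return [x, x**2]
    if transform == "log":
        if np.any(x <= 0):
            raise DomainError(f"log transform needs positive {column}")
        return [np.log(x)]
    if transform.startswith("pow_"):
        p = float(transform[4:])
        if p == 0:
            if np.any(x <= 0):
                raise DomainError(f"log power needs positive {column}")
            return [np.log(x)]
        if (p != int(p) or p < 0) and np.any(x <= 0):
            raise DomainError(f"power {p} needs positive {column}")
        return [x**p]
    raise ValueError(f"unknown transform {transform!r}")


def fit_candidate_specs(
    specs: Sequence[CandidateSpec],
    train: pd.DataFrame,
    y_col: str,
    test: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Least-squares fit of each spec; R² on train (and test if given).

    Specs whose transforms are invalid for the data (e.g. log of a
    non-positive covariate) are skipped with ``note='invalid_transform'``.
    Rows are sorted by test R² (or train R²) descending.
    """
    rows = []
    y_tr = train[y_col].to_numpy(float)
    for spec in specs:
        try:
            cols = [c for col, tr in spec.terms
                    for c in _term_columns(train, col, tr)]
        except DomainError:
            rows.append({"spec": spec.describe(), "train_r2": np.nan,
                         "test_r2": np.nan, "note": "invalid_transform"})
            continue
        design = np.column_stack([np.ones(len(train))] + cols)
        coef, _, _, _ = np.linalg.lstsq(design, y_tr, rcond=None)
        pred = design @ coef
        ss_tot = np.sum((y_tr - y_tr.mean()) ** 2)
        train_r2 = 1 - np.sum((y_tr - pred) ** 2) / ss_tot

        test_r2 = np.nan
        if test is not None:
            try:
                tcols = [c for col, tr in spec.terms
                         for c in _term_columns(test, col, tr)]
            except DomainError:
                rows.append({"spec": spec.describe(), "train_r2": train_r2,
                             "test_r2": np.nan, "note": "invalid_transform"})
                continue
            tdesign = np.column_stack([np.ones(len(test))] + tcols)
            y_te = test[y_col].to_numpy(float)
            tpred = tdesign @ coef
            test_r2 = 1 - np.sum((y_te - tpred) ** 2) / np.sum(
                (y_te - y_te.mean()) ** 2
            )
        rows.append({"spec": spec.describe(), "train_r2": float(train_r2),
                     "test_r2": float(test_r2), "note": ""})
    out = pd.DataFrame(rows)
    sort_col = "test_r2" if test is not None else "train_r2"
    return out.sort_values(sort_col, ascending=False, na_position="last"
                           ).reset_index(drop=True)
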