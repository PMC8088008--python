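"""Truncation-aware fractional-polynomial regression of GA on CRL.

The workflow mirrors model development on a CRL-truncated cohort:
denoise, supplement the >14-week tail with simulated observations from a
reference formula (Hadlock by default, which spans 15-18 weeks), then
exhaustively search fractional-polynomial forms and select by R².

Powers come from the canonical set {-2, -1, -0.5, 0, 0.5, 1, 2, 3};
power 0 denotes log(x) and a repeated power (p, p) contributes
x^p and x^p*log(x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .denoise import DBSCANParams, FilterCriteria, clinical_filter, dbscan_filter
from .errors import DomainError, PipelineError
from .formulae import get_formula

logger = logging.getLogger("gestage.fpreg")

__all__ = [
    "FPPOWERS",
    "FPModel",
    "SupplementSpec",
    "supplement_truncated",
    "fit_fp",
    "r_squared",
    "fit_garbhini_pipeline",
]

#: Canonical fractional-polynomial power set.
FPPOWERS: Tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_columns(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Fractional-polynomial basis columns (no intercept).

    Repeated powers multiply in an extra log(x) per repetition:
    (p, p) -> x^p, x^p*log(x); power 0 -> log(x).
    """
    logx = None
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        rep = seen.get(p, 0)
        if p == 0 or rep:
            if logx is None:
                logx = np.log(x)
        base = logx if p == 0 else x**p
        cols.append(base * logx**rep if rep else base)
        seen[p] = rep + 1
    return np.column_stack(cols)


@dataclass
class FPModel:
    """A fitted fractional-polynomial model of GA (weeks) on CRL (cm)."""

    degree: int
    powers: Tuple[float, ...]
    coefficients: np.ndarray  # intercept first, then one per term
    r_squared: float
    n_obs: int
    supplemented_n: int = 0
    aic: float = float("nan")
    residual_sd: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.powers) + 1:
            raise ValueError("coefficient count must be degree + 1 (with intercept)")

    def predict(self, x) -> np.ndarray:
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        design = np.column_stack([np.ones(len(x)), _fp_columns(x, self.powers)])
        out = design @ self.coefficients
        return float(out[0]) if scalar else out

    def to_yaml(self, path=None) -> str:
        payload = {
            "degree": self.degree,
            "powers": list(self.powers),
            "coefficients": [float(c) for c in self.coefficients],
            "r_squared": float(self.r_squared),
            "n_obs": self.n_obs,
            "supplemented_n": self.supplemented_n,
            "aic": float(self.aic),
            "residual_sd": float(self.residual_sd),
            "provenance": self.provenance,
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "FPModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            degree=d["degree"],
            powers=tuple(d["powers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            r_squared=d["r_squared"],
            n_obs=d["n_obs"],
            supplemented_n=d.get("supplemented_n", 0),
            aic=d.get("aic", float("nan")),
            residual_sd=d.get("residual_sd", float("nan")),
            provenance=d.get("provenance", {}),
        )


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SSres/SStot about the mean.

    May be negative when an external model is evaluated on new data.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    if len(y) < 2:
        raise ValueError("r_squared requires at least 2 points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("r_squared undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _candidate_powers(degree: int, power_set: Sequence[float]) -> list[tuple]:
    ps = sorted(power_set)
    if degree == 1:
        cands = [(p,) for p in ps]
    elif degree == 2:
        cands = [(p, q) for i, p in enumerate(ps) for q in ps[i:]]
    else:
        raise ValueError("degree must be 1 or 2")
    # simplicity order: smaller total |power| first (tie-break preference)
    cands.sort(key=lambda t: (sum(abs(p) for p in t), t))
    return cands


def fit_fp(
    x,
    y,
    degree: int = 2,
    power_set: Sequence[float] = FPPOWERS,
    powers: Optional[Sequence[float]] = None,
) -> FPModel:
    """Exhaustive fractional-polynomial OLS search, selected by R².

    Ties (within 1e-12) go to the candidate with smaller total absolute
    power.  Requires x > 0 since the power set includes log, negative
    and fractional powers.  Passing ``powers`` skips the search and fits
    that single form (degree is then taken from its length).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if powers is not None:
        degree = len(powers)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points")
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise DomainError(
            "fractional/log powers require x > 0; offending rows: "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("cannot fit: y is constant")

    n = len(x)
    candidates = (
        [tuple(float(p) for p in powers)]
        if powers is not None
        else _candidate_powers(degree, power_set)
    )
    best = None
    for powers in candidates:
        design = np.column_stack([np.ones(n), _fp_columns(x, powers)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        r2 = 1.0 - ss_res / ss_tot
        if best is None or r2 > best[0] + 1e-12:
            k = len(coef) + 1  # + error variance
            aic = n * np.log(max(ss_res, 1e-300) / n) + 2 * k
            rsd = float(np.sqrt(ss_res / max(n - len(coef), 1)))
            best = (r2, powers, coef, aic, rsd)

    r2, powers, coef, aic, rsd = best
    return FPModel(
        degree=degree,
        powers=tuple(powers),
        coefficients=coef,
        r_squared=r2,
        n_obs=n,
        aic=aic,
        residual_sd=rsd,
    )


@dataclass
class SupplementSpec:
    """Simulated tail observations from a reference formula.

    ``n_points=None`` resolves to 10% of the training rows and
    ``noise_sd_weeks=None`` to the residual SD of a pilot quadratic fit
    (both resolved inside :func:`fit_garbhini_pipeline`).
    """

    source_formula_id: str = "hadlock"
    ga_range: Tuple[float, float] = (15.0, 18.0)
    n_points: Optional[int] = None
    noise_sd_weeks: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.ga_range
        if not hi > lo:
            raise ValueError("ga_range must be increasing")
        if self.n_points is not None and self.n_points < 0:
            raise ValueError("n_points must be >= 0")


def supplement_truncated(dataset: pd.DataFrame, spec: SupplementSpec) -> pd.DataFrame:
    """Append simulated (CRL, GA) rows spanning ``spec.ga_range``.

    GA is sampled uniformly over the range, CRL obtained by inverting the
    source formula, and the GA *response* jittered by Gaussian noise.
    Appended rows carry ``supplemented=True``.  Deterministic under
    ``spec.seed``.
    """
    if not {"crl_cm", "ga_lmp_weeks"}.issubset(dataset.columns):
        raise ValueError("dataset must have crl_cm and ga_lmp_weeks columns")
    out = dataset.copy()
    if "supplemented" not in out.columns:
        out["supplemented"] = False
    n_points = spec.n_points if spec.n_points is not None else 0
    if n_points == 0:
        return out

    formula = get_formula(spec.source_formula_id)
    rng = np.random.default_rng(spec.seed)
    ga_true = rng.uniform(*spec.ga_range, size=n_points)
    crl = formula.invert(ga_true)  # DomainError if range outside image
    noise_sd = spec.noise_sd_weeks or 0.0
    ga_obs = ga_true + rng.normal(0.0, noise_sd, size=n_points) if noise_sd else ga_true

    extra = pd.DataFrame(
        {"crl_cm": crl, "ga_lmp_weeks": ga_obs, "supplemented": True}
    )
    return pd.concat([out, extra], ignore_index=True)


def fit_garbhini_pipeline(
    training_cohort: CohortTable,
    denoise_method: str = "dbscan",
    supplement_spec: Optional[SupplementSpec] = SupplementSpec(),
    degree: int = 2,
    dbscan_params: Optional[DBSCANParams] = None,
    criteria: Optional[FilterCriteria] = None,
    power_set: Sequence[float] = FPPOWERS,
) -> FPModel:
    """End-to-end: denoise -> supplement -> fractional-polynomial fit.

    Returns the selected model with stage-by-stage counts in
    ``provenance``.
    """
    n_input = training_cohort.n_o
    if denoise_method == "dbscan":
        denoised, _ = dbscan_filter(training_cohort, dbscan_params)
    elif denoise_method == "clinical":
        denoised, _ = clinical_filter(training_cohort, criteria)
    elif denoise_method in (None, "none"):
        denoised = training_cohort
    else:
        raise ValueError(f"unknown denoise method {denoise_method!r}")

    obs = denoised.observations
    data = obs.loc[
        obs["crl_cm"].notna() & obs["ga_lmp_weeks"].notna(),
        ["crl_cm", "ga_lmp_weeks"],
    ].reset_index(drop=True)
    if data.empty:
        raise PipelineError(
            f"denoiser {denoise_method!r} left no usable (CRL, GA) rows"
        )
    n_denoised = len(data)

    supplemented_n = 0
    if supplement_spec is not None:
        spec = SupplementSpec(
            source_formula_id=supplement_spec.source_formula_id,
            ga_range=supplement_spec.ga_range,
            n_points=(
                supplement_spec.n_points
                if supplement_spec.n_points is not None
                else int(round(0.1 * n_denoised))
            ),
            noise_sd_weeks=supplement_spec.noise_sd_weeks,
            seed=supplement_spec.seed,
        )
        if spec.noise_sd_weeks is None:
            # two-pass: pilot quadratic residual SD sets the jitter scale
            pilot = fit_fp(
                data["crl_cm"].to_numpy(),
                data["ga_lmp_weeks"].to_numpy(),
                degree=2,
                power_set=(1.0, 2.0),
            )
            spec.noise_sd_weeks = pilot.residual_sd
        data = supplement_truncated(data, spec)
        supplemented_n = int(data["supplemented"].sum())

    model = fit_fp(
        data["crl_cm"].to_numpy(),
        data["ga_lmp_weeks"].to_numpy(),
        degree=degree,
        power_set=power_set,
    )
    model.supplemented_n = supplemented_n
    model.provenance = {
        "n_input": n_input,
        "denoise_method": denoise_method or "none",
        "n_after_denoise": n_denoised,
        "n_supplemented": supplemented_n,
        "n_fit": model.n_obs,
        "cohort_provenance": training_cohort.metadata.get("provenance"),
    }
    logger.info("pipeline fit: %s", model.provenance)
    return model
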