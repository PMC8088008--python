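"""Synthetic cohort generator.

Emulates the statistical structure the dating analysis assumes: a true
CRL-GA growth law (any registered formula), LMP recall error (systematic
bias + rounded Gaussian noise + a gross-error fraction of +/- one cycle),
CRL measurement noise, enrolment scans with CRL truncation at 14 weeks,
an optional 11-14-week second scan, and a delivery-GA mixture with a
configurable preterm fraction.

Reproducibility contract: all randomness for participant ``i`` comes from
row ``i`` of one fixed-width uniform block drawn from a single seeded
stream, so the same seed gives byte-identical output and *adding*
participants never perturbs existing rows.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .cohort import CohortTable, derive_ga_lmp
from .errors import ConfigError, DomainError, OutOfRangeWarning
from .formulae import get_formula

__all__ = ["SyntheticConfig", "TruthTable", "generate_cohort", "truth_table"]

_N_UNIFORM_COLS = 22  # fixed per-participant randomness budget


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    LMP error convention: positive ``lmp_bias_days`` means the LMP is
    recalled *earlier* than truth, inflating LMP-based GA.  The delivery
    distribution is a two-component truncated-Gaussian mixture split at
    37 weeks, so ``preterm_fraction`` is exactly the preterm probability.
    """

    n_participants: int = 100
    seed: int = 0
    truth_formula_id: str = "garbhini_ga1"
    # uniform over whole days in this window (weeks); lower bound 7.0
    # because the default truth formula's image starts at ~6.74 weeks
    enrolment_ga_range: tuple = (7.0, 14.0)
    second_scan_prob: float = 0.8
    crl_noise_sd_cm: float = 0.1
    lmp_bias_days: float = 3.0
    lmp_noise_sd_days: float = 5.0
    gross_error_frac: float = 0.05
    gross_error_shift_days: float = 28.0
    preterm_fraction: float = 0.15
    term_mean_weeks: float = 39.0
    term_sd_weeks: float = 1.2
    preterm_mean_weeks: float = 34.5
    preterm_sd_weeks: float = 2.0
    covariate_prevalence: dict = field(
        default_factory=lambda: {
            "smoker": 0.03,
            "tobacco": 0.10,
            "alcohol": 0.02,
            "unreliable_lmp": 0.20,
        }
    )
    missing_outcome_frac: float = 0.0
    base_lmp_date: str = "2016-01-01"
    crl_truncation_weeks: float = 14.0

    def validate(self) -> None:
        probs = [
            self.second_scan_prob,
            self.gross_error_frac,
            self.preterm_fraction,
            self.missing_outcome_frac,
            *self.covariate_prevalence.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.crl_noise_sd_cm < 0 or self.lmp_noise_sd_days < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        lo, hi = self.enrolment_ga_range
        if not hi > lo or lo < 0:
            raise ConfigError("enrolment_ga_range must be an increasing window")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enrolment_ga_range"] = list(self.enrolment_ga_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "enrolment_ga_range" in data:
            data["enrolment_ga_range"] = tuple(data["enrolment_ga_range"])
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth aligned with a generated cohort."""

    scans: pd.DataFrame         # participant_id, scan_index, true_ga_weeks, true_crl_cm
    participants: pd.DataFrame  # participant_id, true_delivery_ga_weeks, true_preterm

    def to_frame(self) -> pd.DataFrame:
        return self.scans.merge(self.participants, on="participant_id", how="left")


def _ppf_normal(u: np.ndarray) -> np.ndarray:
    return norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def _empty_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    obs = pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=object),
            "scan_index": pd.Series(dtype=int),
            "scan_date": pd.Series(dtype="datetime64[ns]"),
            "lmp_date": pd.Series(dtype="datetime64[ns]"),
            "crl_cm": pd.Series(dtype=float),
            "ga_lmp_weeks": pd.Series(dtype=float),
        }
    )
    outcomes = pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=object),
            "delivery_date": pd.Series(dtype="datetime64[ns]"),
        }
    )
    return obs, outcomes


def _generate(config: SyntheticConfig) -> tuple[CohortTable, TruthTable]:
    config.validate()
    n = config.n_participants
    formula = get_formula(config.truth_formula_id)

    lo_wk, hi_wk = config.enrolment_ga_range
    trunc_day = int(round(config.crl_truncation_weeks * 7))
    max_crl_day = min(int(np.ceil(hi_wk * 7)), trunc_day) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OutOfRangeWarning)
        ga_img_lo = formula(formula.valid_crl_range[0])
        ga_img_hi = formula(formula.valid_crl_range[1])
    if lo_wk < ga_img_lo - 1e-9 or max_crl_day / 7.0 > ga_img_hi + 1e-9:
        raise ConfigError(
            f"truth formula {config.truth_formula_id!r} is not invertible over "
            f"the enrolment GA window [{lo_wk}, {min(hi_wk, trunc_day / 7.0)}) wk "
            f"(image [{ga_img_lo:.3f}, {ga_img_hi:.3f}] wk)"
        )

    if n == 0:
        obs, outcomes = _empty_cohort()
        cohort = CohortTable.from_frames(obs, outcomes, provenance="synthetic")
        cohort.metadata.update(seed=config.seed, config=config.to_dict())
        truth = TruthTable(
            scans=pd.DataFrame(columns=["participant_id", "scan_index",
                                        "true_ga_weeks", "true_crl_cm"]),
            participants=pd.DataFrame(columns=["participant_id",
                                               "true_delivery_ga_weeks",
                                               "true_preterm"]),
        )
        return cohort, truth

    u = np.random.Generator(np.random.PCG64(config.seed)).random(
        (n, _N_UNIFORM_COLS)
    )
    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    base = pd.Timestamp(config.base_lmp_date)

    day_lo, day_hi = int(round(lo_wk * 7)), int(round(hi_wk * 7))
    scan1_day = (day_lo + np.floor(u[:, 0] * (day_hi - day_lo))).astype(int)
    true_lmp_off = np.floor(u[:, 1] * 365).astype(int)
    true_lmp = base + pd.to_timedelta(true_lmp_off, unit="D")

    def _scan_block(day: np.ndarray, z_noise: np.ndarray):
        ga_true = day / 7.0
        has_crl = day < trunc_day
        true_crl = np.full(len(day), np.nan)
        if has_crl.any():
            true_crl[has_crl] = formula.invert(ga_true[has_crl])
        obs_crl = np.where(
            has_crl,
            np.maximum(true_crl + config.crl_noise_sd_cm * z_noise, 0.05),
            np.nan,
        )
        return ga_true, true_crl, obs_crl

    ga1_true, crl1_true, crl1_obs = _scan_block(scan1_day, _ppf_normal(u[:, 2]))

    eligible2 = scan1_day < 77  # enrolled before 11 weeks
    has2 = eligible2 & (u[:, 3] < config.second_scan_prob)
    scan2_day = (77 + np.floor(u[:, 4] * 21)).astype(int)  # 11-14 wk window
    ga2_true, crl2_true, crl2_obs = _scan_block(scan2_day, _ppf_normal(u[:, 5]))

    lmp_noise = np.round(config.lmp_noise_sd_days * _ppf_normal(u[:, 6])).astype(int)
    gross = (u[:, 7] < config.gross_error_frac).astype(int)
    sign = np.where(u[:, 8] < 0.5, -1, 1)
    shift = gross * sign * int(round(config.gross_error_shift_days))
    observed_lmp = (
        true_lmp
        - pd.to_timedelta(int(round(config.lmp_bias_days)), unit="D")
        - pd.to_timedelta(lmp_noise, unit="D")
        - pd.to_timedelta(shift, unit="D")
    )

    preterm = u[:, 9] < config.preterm_fraction
    a_pre = (20.0 - config.preterm_mean_weeks) / config.preterm_sd_weeks
    b_pre = (37.0 - config.preterm_mean_weeks) / config.preterm_sd_weeks
    a_term = (37.0 - config.term_mean_weeks) / config.term_sd_weeks
    b_term = (45.0 - config.term_mean_weeks) / config.term_sd_weeks
    u_del = np.clip(u[:, 10], 1e-12, 1 - 1e-12)
    ga_del = np.where(
        preterm,
        truncnorm.ppf(u_del, a_pre, b_pre,
                      loc=config.preterm_mean_weeks, scale=config.preterm_sd_weeks),
        truncnorm.ppf(u_del, a_term, b_term,
                      loc=config.term_mean_weeks, scale=config.term_sd_weeks),
    )
    # floor to whole days so the calendar date never crosses the 37-wk boundary
    delivery_day = np.floor(ga_del * 7).astype(int)
    true_delivery_ga = delivery_day / 7.0
    missing_outcome = u[:, 11] < config.missing_outcome_frac
    delivery_date = true_lmp + pd.to_timedelta(delivery_day, unit="D")
    delivery_date = delivery_date.where(~missing_outcome, pd.NaT)

    prev = config.covariate_prevalence
    covs = pd.DataFrame(
        {
            "smoker": (u[:, 12] < prev.get("smoker", 0.0)).astype(int),
            "tobacco": (u[:, 13] < prev.get("tobacco", 0.0)).astype(int),
            "alcohol": (u[:, 14] < prev.get("alcohol", 0.0)).astype(int),
            "unreliable_lmp": (u[:, 15] < prev.get("unreliable_lmp", 0.0)).astype(int),
            "bmi": np.round(np.clip(21.5 + 3.5 * _ppf_normal(u[:, 16]), 14, 40), 2),
            "age": np.clip(np.round(23 + 3 * _ppf_normal(u[:, 17])), 18, 45).astype(int),
            "weight": np.round(np.clip(47 + 8 * _ppf_normal(u[:, 18]), 30, 100), 1),
            "abdominal_girth": np.round(
                np.clip(80 + 8 * _ppf_normal(u[:, 19]), 55, 120), 1
            ),
            "maternal_education": np.floor(u[:, 20] * 7).astype(int),
            "resident_state": np.floor(u[:, 21] * 4).astype(int),
        }
    )

    def _rows(day, crl_obs, ga_true, crl_true, index_mask, scan_index):
        idx = np.flatnonzero(index_mask)
        obs = pd.DataFrame(
            {
                "participant_id": pid[idx],
                "scan_index": scan_index,
                "scan_date": (true_lmp + pd.to_timedelta(day, unit="D"))[idx],
                "lmp_date": observed_lmp[idx],
                "crl_cm": crl_obs[idx],
                "ga_lmp_weeks": np.nan,
            }
        )
        obs = pd.concat([obs.reset_index(drop=True),
                         covs.iloc[idx].reset_index(drop=True)], axis=1)
        truth = pd.DataFrame(
            {
                "participant_id": pid[idx],
                "scan_index": scan_index,
                "true_ga_weeks": ga_true[idx],
                "true_crl_cm": crl_true[idx],
            }
        )
        return obs, truth

    all_mask = np.ones(n, dtype=bool)
    obs1, truth1 = _rows(scan1_day, crl1_obs, ga1_true, crl1_true, all_mask, 1)
    obs2, truth2 = _rows(scan2_day, crl2_obs, ga2_true, crl2_true, has2, 2)

    obs = pd.concat([obs1, obs2], ignore_index=True)
    truth_scans = pd.concat([truth1, truth2], ignore_index=True)
    order = np.lexsort((obs["scan_index"].to_numpy(),
                        obs["participant_id"].to_numpy()))
    obs = obs.iloc[order].reset_index(drop=True)
    truth_scans = truth_scans.iloc[order].reset_index(drop=True)

    outcomes = pd.DataFrame(
        {"participant_id": pid, "delivery_date": delivery_date}
    )
    truth_participants = pd.DataFrame(
        {
            "participant_id": pid,
            "true_delivery_ga_weeks": true_delivery_ga,
            "true_preterm": true_delivery_ga < 37.0,
        }
    )

    cohort = CohortTable.from_frames(obs, outcomes, provenance="synthetic")
    cohort.metadata.update(seed=config.seed, config=config.to_dict())
    cohort = derive_ga_lmp(cohort)
    cohort.metadata["provenance"] = "synthetic"
    return cohort, TruthTable(truth_scans, truth_participants)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Generate a synthetic cohort; deterministic under ``config.seed``."""
    cohort, _ = _generate(config)
    return cohort


def truth_table(config: SyntheticConfig, cohort: CohortTable) -> TruthTable:
    """Per-row ground truth for a cohort produced by :func:`generate_cohort`.

    The truth is re-derived deterministically from ``config`` and checked
    against the cohort's identity (provenance, seed, participant ids).
    """
    if cohort.metadata.get("provenance") != "synthetic":
        raise ConfigError("truth_table requires a synthetic cohort")
    if cohort.metadata.get("seed") != config.seed:
        raise ConfigError(
            f"cohort was generated with seed {cohort.metadata.get('seed')}, "
            f"config has seed {config.seed}"
        )
    regen, truth = _generate(config)
    if not regen.observations["participant_id"].equals(
        cohort.observations["participant_id"]
    ):
        raise ConfigError("cohort does not match the supplied config")
    return truth
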