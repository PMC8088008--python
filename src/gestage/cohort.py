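"""Cohort data model and CSV I/O.

One CSV row per ultrasound observation; participant-level outcome
(delivery date) repeats across a participant's rows and is normalised
into a separate outcomes frame on read.  Validation is collect-and-report:
rows violating hard invariants are rejected with a per-row reason that is
kept on the returned table (``exclusion_log``) and can be written as JSON
lines, so a messy CSV yields a usable table plus an exclusion trail.

Dates are ISO-8601 strings on disk; gestational age is decimal weeks
(day difference / 7) everywhere, never completed-weeks integers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("gestage.cohort")

__all__ = [
    "ScanObservation",
    "ParticipantOutcome",
    "CohortTable",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
    "derive_ga_lmp",
    "write_exclusion_log",
]

#: Core (non-covariate) observation columns, in serialization order.
CORE_COLUMNS = [
    "participant_id",
    "scan_index",
    "scan_date",
    "lmp_date",
    "crl_cm",
    "ga_lmp_weeks",
]

DEFAULT_SCHEMA: dict = {
    "participant_id": "participant_id",
    "scan_date": "scan_date",
    "lmp_date": "lmp_date",
    "delivery_date": "delivery_date",
    "crl_cm": "crl_cm",
    "scan_index": "scan_index",
    # optional: list of raw measurement columns averaged into crl_cm
    "crl_columns": None,
    # plausibility bound, cm; CRL at 14 weeks is ~8.5 cm
    "crl_max_cm": 10.0,
}


@dataclass(frozen=True)
class ScanObservation:
    """One ultrasound observation (row-level view of the table)."""

    participant_id: str
    scan_date: Optional[date]
    lmp_date: Optional[date] = None
    crl_cm: Optional[float] = None
    ga_lmp_weeks: Optional[float] = None
    covariates: Mapping = field(default_factory=dict)
    scan_index: int = 1


@dataclass(frozen=True)
class ParticipantOutcome:
    """Participant-level delivery outcome."""

    participant_id: str
    delivery_date: Optional[date] = None
    ga_delivery_weeks: Mapping[str, float] = field(default_factory=dict)


@dataclass
class CohortTable:
    """Observations + outcomes + provenance metadata.

    ``observations`` has the CORE_COLUMNS plus arbitrary covariate
    columns; ``outcomes`` has ``participant_id`` and ``delivery_date``.
    """

    observations: pd.DataFrame
    outcomes: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    exclusion_log: list = field(default_factory=list)

    @property
    def n_o(self) -> int:
        return len(self.observations)

    @property
    def n_p(self) -> int:
        return self.observations["participant_id"].nunique()

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.observations.columns if c not in CORE_COLUMNS]

    @classmethod
    def from_frames(
        cls,
        observations: pd.DataFrame,
        outcomes: Optional[pd.DataFrame] = None,
        provenance: str = "unspecified",
        exclusion_log: Optional[list] = None,
    ) -> "CohortTable":
        obs = observations.reset_index(drop=True)
        if outcomes is None:
            outcomes = pd.DataFrame(
                {"participant_id": pd.Series(dtype=object),
                 "delivery_date": pd.Series(dtype="datetime64[ns]")}
            )
        outcomes = outcomes.reset_index(drop=True)
        if outcomes["participant_id"].duplicated().any():
            raise ValidationError(
                "an observation's participant_id must resolve to at most one "
                "outcome; duplicate participant_id in outcomes"
            )
        table = cls(obs, outcomes, metadata={"provenance": provenance},
                    exclusion_log=list(exclusion_log or []))
        table.metadata.update(n_p=table.n_p, n_o=table.n_o)
        return table

    def with_observations(self, obs: pd.DataFrame) -> "CohortTable":
        """Copy of this table restricted to ``obs`` (outcomes subset too)."""
        obs = obs.reset_index(drop=True)
        pids = set(obs["participant_id"])
        outcomes = self.outcomes[
            self.outcomes["participant_id"].isin(pids)
        ].reset_index(drop=True)
        meta = dict(self.metadata)
        out = CohortTable(obs, outcomes, meta, list(self.exclusion_log))
        out.metadata.update(n_p=out.n_p, n_o=out.n_o)
        return out

    def iter_observations(self) -> Iterator[ScanObservation]:
        cov_cols = self.covariate_columns
        for _, row in self.observations.iterrows():
            yield ScanObservation(
                participant_id=row["participant_id"],
                scan_date=_to_date(row["scan_date"]),
                lmp_date=_to_date(row["lmp_date"]),
                crl_cm=None if pd.isna(row["crl_cm"]) else float(row["crl_cm"]),
                ga_lmp_weeks=(
                    None if pd.isna(row["ga_lmp_weeks"])
                    else float(row["ga_lmp_weeks"])
                ),
                covariates={c: row[c] for c in cov_cols},
                scan_index=int(row["scan_index"]),
            )

    def iter_outcomes(self) -> Iterator[ParticipantOutcome]:
        for _, row in self.outcomes.iterrows():
            yield ParticipantOutcome(
                participant_id=row["participant_id"],
                delivery_date=_to_date(row["delivery_date"]),
            )


def _to_date(value) -> Optional[date]:
    if pd.isna(value):
        return None
    return pd.Timestamp(value).date()


def _parse_date_column(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse to datetime; second return marks non-empty unparseable cells."""
    stripped = raw.astype("string").str.strip()
    nonempty = stripped.notna() & (stripped != "")
    parsed = pd.to_datetime(stripped, errors="coerce", format="ISO8601")
    bad = nonempty & parsed.isna()
    return parsed, bad


def read_cohort(path, schema_config: Optional[Mapping] = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Rows violating hard invariants (unparseable dates, scan before LMP,
    implausible CRL, pregnancy not beyond 20 weeks) are rejected and
    logged, not fatal — unless every row fails.
    """
    schema = dict(DEFAULT_SCHEMA)
    schema.update(schema_config or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    required = [schema["participant_id"], schema["scan_date"]]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} in {path}")

    n_in = len(raw)
    if n_in == 0:
        warnings.warn(f"{path}: header-only cohort file (0 observations)")

    obs = pd.DataFrame(index=raw.index)
    obs["participant_id"] = raw[schema["participant_id"]].astype(str)

    reasons: dict[int, str] = {}

    def _reject(mask: pd.Series, reason: str) -> None:
        for i in raw.index[mask]:
            reasons.setdefault(int(i), reason)

    _reject(obs["participant_id"].str.strip() == "", "missing participant_id")

    for key in ("scan_date", "lmp_date", "delivery_date"):
        col = schema[key]
        if col in raw.columns:
            parsed, bad = _parse_date_column(raw[col])
            obs[key] = parsed
            _reject(bad, f"unparseable {key}")
        else:
            obs[key] = pd.NaT
    _reject(obs["scan_date"].isna() & ~pd.Series(
        [reasons.get(int(i), "").startswith("unparseable") for i in raw.index],
        index=raw.index), "missing scan_date")

    # CRL: either a single column or the mean of raw measurement columns
    crl_cols = schema.get("crl_columns")
    if crl_cols:
        missing_crl = [c for c in crl_cols if c not in raw.columns]
        if missing_crl:
            raise SchemaError(f"missing CRL measurement column(s): {missing_crl}")
        vals = raw[crl_cols].apply(lambda s: pd.to_numeric(s, errors="coerce"))
        obs["crl_cm"] = vals.mean(axis=1, skipna=False)
    elif schema["crl_cm"] in raw.columns:
        obs["crl_cm"] = pd.to_numeric(raw[schema["crl_cm"]], errors="coerce")
    else:
        obs["crl_cm"] = np.nan

    crl_max = float(schema["crl_max_cm"])
    has_crl = obs["crl_cm"].notna()
    implausible = has_crl & ((obs["crl_cm"] <= 0) | (obs["crl_cm"] > crl_max))
    if implausible.any():
        logger.info("CRL plausibility bound (0, %.2f] cm rejected %d row(s)",
                    crl_max, int(implausible.sum()))
    _reject(implausible, "implausible CRL")

    both_dates = obs["scan_date"].notna() & obs["lmp_date"].notna()
    _reject(both_dates & (obs["scan_date"] < obs["lmp_date"]), "negative GA")

    early_end = (
        obs["delivery_date"].notna()
        & obs["lmp_date"].notna()
        & ((obs["delivery_date"] - obs["lmp_date"]).dt.days <= 140)
    )
    _reject(early_end, "pregnancy not beyond 20 weeks")

    if schema["scan_index"] in raw.columns:
        obs["scan_index"] = pd.to_numeric(
            raw[schema["scan_index"]], errors="coerce"
        ).fillna(1).astype(int)
    else:
        obs["scan_index"] = (
            obs.sort_values("scan_date")
            .groupby("participant_id")
            .cumcount()
            .reindex(obs.index)
            + 1
        )

    core_src = {schema[k] for k in
                ("participant_id", "scan_date", "lmp_date", "delivery_date",
                 "crl_cm", "scan_index") if schema[k] in raw.columns}
    core_src.update(crl_cols or [])
    core_src.add("ga_lmp_weeks")
    for col in raw.columns:
        if col not in core_src:
            obs[col] = raw[col].apply(
                lambda v: np.nan if v == "" else _maybe_number(v)
            )

    exclusion_log = [
        {
            "row": i,
            "participant_id": str(raw.at[i, schema["participant_id"]]),
            "reason": reasons[i],
        }
        for i in sorted(reasons)
    ]
    for entry in exclusion_log:
        logger.info("rejected row %(row)s (%(participant_id)s): %(reason)s",
                    entry)

    keep = ~obs.index.isin(list(reasons))
    if n_in > 0 and not keep.any():
        raise ValidationError(
            f"{path}: all {n_in} rows failed validation; first reasons: "
            f"{[e['reason'] for e in exclusion_log[:5]]}"
        )
    obs = obs.loc[keep].reset_index(drop=True)

    outcomes = (
        obs.groupby("participant_id", as_index=False)["delivery_date"].first()
        if len(obs)
        else pd.DataFrame({"participant_id": pd.Series(dtype=object),
                           "delivery_date": pd.Series(dtype="datetime64[ns]")})
    )
    obs = obs.drop(columns=["delivery_date"])
    obs["ga_lmp_weeks"] = np.nan
    obs = obs[CORE_COLUMNS + [c for c in obs.columns if c not in CORE_COLUMNS]]

    table = CohortTable.from_frames(
        obs, outcomes, provenance=str(path), exclusion_log=exclusion_log
    )
    table.metadata["n_rejected"] = len(exclusion_log)
    table.metadata["n_input_rows"] = n_in
    return derive_ga_lmp(table)


def _maybe_number(v):
    if v is np.nan or v is None:
        return np.nan
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    return int(f) if f.is_integer() and "." not in str(v) and "e" not in str(v).lower() else f


def derive_ga_lmp(cohort: CohortTable) -> CohortTable:
    """Populate ``ga_lmp_weeks`` = (scan_date - lmp_date) / 7 in decimal weeks.

    Rows without an LMP date keep an empty GA and are counted in
    ``metadata['n_missing_lmp']``.
    """
    obs = cohort.observations.copy()
    both = obs["scan_date"].notna() & obs["lmp_date"].notna()
    ga = (obs.loc[both, "scan_date"] - obs.loc[both, "lmp_date"]).dt.days / 7.0
    obs["ga_lmp_weeks"] = np.nan
    obs.loc[both, "ga_lmp_weeks"] = ga
    n_missing = int((~both).sum())
    if n_missing:
        logger.info("ga_lmp_weeks left empty for %d row(s) missing LMP", n_missing)
    out = replace(cohort, observations=obs)
    out.metadata = dict(cohort.metadata, n_missing_lmp=n_missing)
    return out


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort as a flat CSV (ISO-8601 dates, empty string for NA).

    Round-trips with :func:`read_cohort` on all modelled fields.
    """
    obs = cohort.observations.copy()
    merged = obs.merge(cohort.outcomes, on="participant_id", how="left")
    for col in ("scan_date", "lmp_date", "delivery_date"):
        merged[col] = merged[col].map(
            lambda v: "" if pd.isna(v) else pd.Timestamp(v).date().isoformat()
        )
    merged = merged.drop(columns=["ga_lmp_weeks"])
    cols = ["participant_id", "scan_index", "scan_date", "lmp_date",
            "crl_cm", "delivery_date"]
    cols += [c for c in merged.columns if c not in cols]
    merged[cols].to_csv(path, index=False, na_rep="")


def write_exclusion_log(log: list, path) -> None:
    """Write an exclusion log as JSON lines (one rejected row per line)."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
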