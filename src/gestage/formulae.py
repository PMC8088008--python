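"""Registry of CRL-based gestational-age dating formulae.

Every formula maps crown-rump length (cm) to gestational age (decimal
weeks).  Entries registered with other raw unit conventions (CRL in mm,
GA in days) are normalised at call time; the raw convention is recorded
on the entry.

The built-in registry ships ``garbhini_ga1`` (quadratic, coefficients as
published) plus six comparator formulae transcribed from their original
publications.  Comparator coefficients are best-effort transcriptions and
should be treated as provisional; any entry can be replaced via
:func:`register_from_dict` or a YAML registry file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Mapping, Tuple

import numpy as np
import yaml
from scipy.optimize import brentq

from .errors import (
    DomainError,
    DuplicateFormulaError,
    FormulaLookupError,
    OutOfRangeWarning,
)

__all__ = [
    "DatingFormula",
    "predict_ga",
    "predict_ga_garbhini",
    "invert_formula",
    "register_formula",
    "register_from_dict",
    "get_formula",
    "list_formulae",
    "unregister_formula",
    "registry_to_yaml",
    "load_registry_yaml",
    "GARBHINI_GA1_COEFFS",
]

#: Published Garbhini-GA1 quadratic: GA = a2*CRL^2 + a1*CRL + a0 (weeks, cm).
GARBHINI_GA1_COEFFS = {"a2": -0.02294, "a1": 1.15018, "a0": 6.73526}

_MONOTONE_GRID_N = 1000


@dataclass(frozen=True)
class DatingFormula:
    """A named CRL (cm) -> GA (weeks) mapping with provenance.

    ``raw_fn`` operates in the formula's native units (``crl_unit`` in
    {"cm", "mm"}, ``ga_unit`` in {"weeks", "days"}); calling the object
    always takes cm and returns weeks.
    """

    formula_id: str
    raw_fn: Callable[[np.ndarray], np.ndarray]
    valid_crl_range: Tuple[float, float]
    coefficients: Mapping[str, float] = field(default_factory=dict)
    expression: str = ""
    source: str = ""
    crl_unit: str = "cm"
    ga_unit: str = "weeks"

    def __call__(self, crl_cm):
        """Evaluate GA (weeks) at CRL (cm); warns outside the valid range."""
        scalar = np.isscalar(crl_cm)
        crl = np.asarray(crl_cm, dtype=float)
        if np.any(crl < 0):
            raise DomainError(
                f"{self.formula_id}: negative CRL is not a physical length"
            )
        lo, hi = self.valid_crl_range
        if np.any((crl < lo) | (crl > hi)):
            warnings.warn(
                f"{self.formula_id}: CRL outside validated range "
                f"[{lo}, {hi}] cm; extrapolating",
                OutOfRangeWarning,
                stacklevel=2,
            )
        raw = crl * 10.0 if self.crl_unit == "mm" else crl
        ga = np.asarray(self.raw_fn(raw), dtype=float)
        if self.ga_unit == "days":
            ga = ga / 7.0
        return float(ga) if scalar else ga

    def invert(self, ga_weeks, tol: float = 1e-9):
        """CRL (cm) such that ``self(crl) == ga_weeks`` within ``tol`` weeks.

        Uses bisection over the validated range (formulae are registered
        strictly increasing there).
        """
        scalar = np.isscalar(ga_weeks)
        ga = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
        lo, hi = self.valid_crl_range
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OutOfRangeWarning)
            ga_lo, ga_hi = self(lo), self(hi)
        out = np.empty_like(ga)
        for i, g in enumerate(ga):
            if not (ga_lo - tol <= g <= ga_hi + tol):
                raise DomainError(
                    f"{self.formula_id}: GA {g:.4f} wk outside attainable "
                    f"image [{ga_lo:.4f}, {ga_hi:.4f}] over CRL range"
                )
            g_clamped = min(max(g, ga_lo), ga_hi)

            def _f(c, target=g_clamped):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OutOfRangeWarning)
                    return self(c) - target

            out[i] = brentq(_f, lo, hi, xtol=1e-12)
        return float(out[0]) if scalar else out


_REGISTRY: Dict[str, DatingFormula] = {}


def _check_monotone(formula: DatingFormula) -> None:
    lo, hi = formula.valid_crl_range
    if not hi > lo:
        raise DomainError(f"{formula.formula_id}: empty CRL range")
    grid = np.linspace(lo, hi, _MONOTONE_GRID_N)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OutOfRangeWarning)
        ga = formula(grid)
    if not np.all(np.isfinite(ga)):
        raise DomainError(f"{formula.formula_id}: non-finite GA on valid range")
    if np.any(ga <= 0):
        raise DomainError(f"{formula.formula_id}: non-positive GA on valid range")
    if np.any(np.diff(ga) <= 0):
        raise DomainError(
            f"{formula.formula_id}: GA not strictly increasing in CRL over "
            f"[{lo}, {hi}] cm; registration rejected"
        )


def register_formula(formula: DatingFormula, *, overwrite: bool = False) -> DatingFormula:
    """Add a formula to the registry after monotonicity/finiteness checks."""
    if formula.formula_id in _REGISTRY and not overwrite:
        raise DuplicateFormulaError(
            f"formula id {formula.formula_id!r} already registered"
        )
    _check_monotone(formula)
    _REGISTRY[formula.formula_id] = formula
    return formula


def unregister_formula(formula_id: str) -> None:
    _REGISTRY.pop(formula_id, None)


def get_formula(formula_id: str) -> DatingFormula:
    try:
        return _REGISTRY[formula_id]
    except KeyError:
        raise FormulaLookupError(
            f"unknown formula id {formula_id!r}; available: "
            f"{sorted(_REGISTRY)}"
        ) from None


def list_formulae() -> list[str]:
    return sorted(_REGISTRY)


def predict_ga(formula_id: str, crl_cm):
    """Dispatch: GA (weeks) of the registered formula at CRL (cm)."""
    return get_formula(formula_id)(crl_cm)


def predict_ga_garbhini(crl_cm):
    """Garbhini-GA1 quadratic, GA = -0.02294 CRL^2 + 1.15018 CRL + 6.73526."""
    return predict_ga("garbhini_ga1", crl_cm)


def invert_formula(formula_id: str, ga_weeks, tol: float = 1e-9):
    """CRL (cm) whose predicted GA equals ``ga_weeks`` within ``tol``."""
    return get_formula(formula_id).invert(ga_weeks, tol=tol)


# ---------------------------------------------------------------------------
# expression-string entries (YAML override path)

_EXPR_NAMESPACE = {
    "log": np.log,
    "ln": np.log,
    "sqrt": np.sqrt,
    "exp": np.exp,
    "pi": math.pi,
}


def _compile_expression(expression: str) -> Callable:
    code = compile(expression, "<formula>", "eval")
    for name in code.co_names:
        if name not in _EXPR_NAMESPACE and name != "crl":
            raise DomainError(f"unknown symbol {name!r} in formula expression")

    def fn(crl):
        return eval(code, {"__builtins__": {}}, {**_EXPR_NAMESPACE, "crl": crl})

    return fn


def register_from_dict(spec: Mapping, *, overwrite: bool = False) -> DatingFormula:
    """Register a formula from a plain mapping (as read from YAML).

    Required keys: ``id``, ``expression`` (in terms of ``crl``),
    ``valid_crl_range``.  Optional: ``crl_unit``, ``ga_unit``,
    ``coefficients``, ``source``.
    """
    formula = DatingFormula(
        formula_id=spec["id"],
        raw_fn=_compile_expression(spec["expression"]),
        valid_crl_range=tuple(float(v) for v in spec["valid_crl_range"]),
        coefficients=dict(spec.get("coefficients", {})),
        expression=spec["expression"],
        source=spec.get("source", ""),
        crl_unit=spec.get("crl_unit", "cm"),
        ga_unit=spec.get("ga_unit", "weeks"),
    )
    return register_formula(formula, overwrite=overwrite)


def registry_to_yaml(path=None) -> str:
    """Serialize the registry (expression strings + provenance) to YAML."""
    entries = []
    for fid in list_formulae():
        f = _REGISTRY[fid]
        entries.append(
            {
                "id": f.formula_id,
                "expression": f.expression,
                "valid_crl_range": list(f.valid_crl_range),
                "crl_unit": f.crl_unit,
                "ga_unit": f.ga_unit,
                "coefficients": dict(f.coefficients),
                "source": f.source,
            }
        )
    text = yaml.safe_dump(entries, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_registry_yaml(path, *, overwrite: bool = True) -> list[DatingFormula]:
    """Load/override registry entries from a YAML file of entry mappings."""
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    return [register_from_dict(e, overwrite=overwrite) for e in entries]


# ---------------------------------------------------------------------------
# built-in registry
#
# Comparator coefficients transcribed from the original publications
# (the exact versions used by any given cohort study may differ —
# provisional; override via register_from_dict / load_registry_yaml).

register_from_dict(
    {
        "id": "garbhini_ga1",
        "expression": "-0.02294*crl**2 + 1.15018*crl + 6.73526",
        "valid_crl_range": [0.0, 10.0],
        "crl_unit": "cm",
        "ga_unit": "weeks",
        "coefficients": GARBHINI_GA1_COEFFS,
        "source": "Garbhini-GA1 first-trimester quadratic (GARBH-Ini cohort)",
    }
)

register_from_dict(
    {
        "id": "hadlock",
        "expression": (
            "exp(1.684969 + 0.315646*crl - 0.049306*crl**2 "
            "+ 0.004057*crl**3 - 0.000120456*crl**4)"
        ),
        "valid_crl_range": [0.2, 13.0],
        "crl_unit": "cm",
        "ga_unit": "weeks",
        "coefficients": {
            "b0": 1.684969,
            "b1": 0.315646,
            "b2": -0.049306,
            "b3": 0.004057,
            "b4": -0.000120456,
        },
        "source": "Hadlock et al. 1992, Radiology 182:501-505 (5-18 wk)",
    }
)

register_from_dict(
    {
        "id": "robinson_fleming",
        "expression": "8.052*sqrt(1.037*crl) + 23.73",
        "valid_crl_range": [0.1, 9.0],
        "crl_unit": "mm",
        "ga_unit": "days",
        "coefficients": {"slope": 8.052, "machine_corr": 1.037, "intercept": 23.73},
        "source": "Robinson & Fleming 1975, BJOG 82:702-710",
    }
)

register_from_dict(
    {
        "id": "mclennan_schluter",
        "expression": "32.61967 + 2.62975*crl - 0.42399*crl*log(crl)",
        "valid_crl_range": [0.1, 9.5],
        "crl_unit": "mm",
        "ga_unit": "days",
        "coefficients": {"b0": 32.61967, "b1": 2.62975, "b_xlogx": -0.42399},
        "source": "McLennan & Schluter 2008, Aust NZ J Obstet Gynaecol 48:493-499",
    }
)

register_from_dict(
    {
        "id": "sahota",
        "expression": "26.643 + 7.822*sqrt(crl)",
        "valid_crl_range": [0.1, 9.5],
        "crl_unit": "mm",
        "ga_unit": "days",
        "coefficients": {"intercept": 26.643, "slope_sqrt": 7.822},
        "source": "Sahota et al. 2009, Ultrasound Obstet Gynecol 33:157-160",
    }
)

register_from_dict(
    {
        "id": "verburg",
        "expression": "exp(1.4653 + 0.001737*crl + 0.2313*log(crl))",
        "valid_crl_range": [0.1, 9.5],
        "crl_unit": "mm",
        "ga_unit": "weeks",
        "coefficients": {"b0": 1.4653, "b1": 0.001737, "b_log": 0.2313},
        "source": "Verburg et al. 2008, Ultrasound Obstet Gynecol 31:388-396",
    }
)

register_from_dict(
    {
        "id": "intergrowth",
        "expression": "40.9041 + 3.21585*sqrt(crl) + 0.348956*crl",
        "valid_crl_range": [0.1, 10.0],
        "crl_unit": "mm",
        "ga_unit": "days",
        "coefficients": {"b0": 40.9041, "b_sqrt": 3.21585, "b1": 0.348956},
        "source": "Papageorghiou et al. 2014, Ultrasound Obstet Gynecol 44:641-648",
    }
)

#: Formula ids shipped by default (guaranteed present after import).
BUILTIN_FORMULAE: Tuple[str, ...] = tuple(list_formulae())
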