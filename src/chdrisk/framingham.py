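"""Framingham-style 10-year absolute CHD risk from conventional risk factors.

The engine evaluates a sex-specific Cox proportional-hazards linear
predictor over categorized covariates and converts it to absolute risk via

    P = 1 - s(10) ** exp(A),

where ``A`` is the linear predictor centred at the model's reference
covariates and ``s(10)`` the baseline 10-year survival.  The engine is
coefficient-agnostic: any bundle following the JSON schema below can be
plugged in, and the packaged default transcribes the published
total-cholesterol prediction equations of the Framingham Heart Study
(Wilson et al. 1998).

Bundle schema (per sex): a list of terms, each one of

* ``polynomial`` — ``sum_j c_j * x**(j+1)`` over the raw covariate;
* ``categorical`` — covariate binned by ``edges`` (right-open bins), one
  coefficient per bin;
* ``blood_pressure`` — SBP and DBP staged separately on their own edges,
  the *higher* stage wins (standard JNC staging convention);
* ``binary`` — coefficient applied when the indicator is set;

plus ``reference`` (the linear predictor at reference covariates, which is
subtracted to give the centred ``A``) and ``s10``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import CovariateRangeError, PanelFormatError, ValidationError

__all__ = [
    "RISK_CATEGORIES",
    "CATEGORY_EDGES",
    "RiskFactorProfile",
    "FraminghamModel",
    "default_model",
    "frs_linear_predictor",
    "ten_year_risk",
    "assign_category",
    "cohort_risk",
]

#: Ordered 10-year risk categories with half-open probability bins
#: [0, 0.05), [0.05, 0.10), [0.10, 0.20), [0.20, 1].
RISK_CATEGORIES = ("low", "intermediate", "intermediate_high", "high")
CATEGORY_EDGES = (0.05, 0.10, 0.20)

_TERM_TYPES = {"polynomial", "categorical", "blood_pressure", "binary"}
_SEXES = {"female", "male"}


@dataclass(frozen=True)
class RiskFactorProfile:
    """One individual's conventional CHD risk factors."""

    age: float
    sex: str
    tc: float
    hdl: float
    sbp: float
    dbp: float
    diabetes: bool
    smoker: bool

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("age", "tc", "hdl", "sbp", "dbp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.hdl >= self.tc:
            raise ValidationError(f"HDL ({self.hdl}) must be below total cholesterol ({self.tc})")


def _validate_term(term: Mapping[str, Any]) -> None:
    if "covariate" not in term or "type" not in term or "coefficients" not in term:
        raise PanelFormatError(f"model term missing covariate/type/coefficients: {term}")
    t = term["type"]
    if t not in _TERM_TYPES:
        raise PanelFormatError(f"unknown term type {t!r}")
    if t == "categorical":
        edges = term.get("edges")
        if not edges or list(edges) != sorted(edges) or len(set(edges)) != len(edges):
            raise PanelFormatError(f"{term['covariate']}: edges must be strictly increasing")
        if len(term["coefficients"]) != len(edges) + 1:
            raise PanelFormatError(
                f"{term['covariate']}: need {len(edges) + 1} coefficients for "
                f"{len(edges)} edges"
            )
    if t == "blood_pressure":
        for key in ("sbp_edges", "dbp_edges"):
            edges = term.get(key)
            if not edges or list(edges) != sorted(edges):
                raise PanelFormatError(f"blood_pressure term: bad {key}")
            if len(term["coefficients"]) != len(edges) + 1:
                raise PanelFormatError("blood_pressure term: coefficient/edge count mismatch")


@dataclass(frozen=True)
class FraminghamModel:
    """Coefficient bundle: per-sex term lists, reference values and s(10)."""

    name: str
    sex_models: Mapping[str, Mapping[str, Any]]
    covariate_ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sex in _SEXES:
            if sex not in self.sex_models:
                raise PanelFormatError(f"model {self.name!r} lacks a {sex!r} component")
            m = self.sex_models[sex]
            s10 = m.get("s10")
            if s10 is None or not (0.0 < s10 < 1.0):
                raise ValidationError(f"{sex} s10={s10} must lie strictly inside (0, 1)")
            for term in m.get("terms", []):
                _validate_term(term)

    @classmethod
    def from_json(cls, path: str | Path) -> "FraminghamModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            name=doc.get("name", Path(path).stem),
            sex_models=doc["sex_models"],
            covariate_ranges={k: tuple(v) for k, v in doc.get("covariate_ranges", {}).items()},
        )

    def s10(self, sex: str) -> float:
        return float(self.sex_models[sex]["s10"])

    def reference(self, sex: str) -> float:
        return float(self.sex_models[sex].get("reference", 0.0))

    def _check_range(self, name: str, values: np.ndarray) -> None:
        rng = self.covariate_ranges.get(name)
        if rng is None:
            return
        lo, hi = rng
        bad = (values < lo) | (values > hi)
        if np.any(bad):
            worst = float(values[bad][0])
            raise CovariateRangeError(
                f"covariate {name!r} value {worst} outside model range [{lo}, {hi}]"
            )

    def linear_predictor(self, sex: str, covariates: Mapping[str, np.ndarray]) -> np.ndarray:
        """Centred linear predictor A for arrays of covariates of one sex."""
        model = self.sex_models[sex]
        n = len(np.atleast_1d(next(iter(covariates.values()))))
        total = np.zeros(n, dtype=float)
        for term in model["terms"]:
            name = term["covariate"]
            coefs = np.asarray(term["coefficients"], dtype=float)
            kind = term["type"]
            if kind == "blood_pressure":
                sbp = np.atleast_1d(np.asarray(covariates["sbp"], dtype=float))
                dbp = np.atleast_1d(np.asarray(covariates["dbp"], dtype=float))
                self._check_range("sbp", sbp)
                self._check_range("dbp", dbp)
                stage_s = np.searchsorted(term["sbp_edges"], sbp, side="right")
                stage_d = np.searchsorted(term["dbp_edges"], dbp, side="right")
                total += coefs[np.maximum(stage_s, stage_d)]
                continue
            x = np.atleast_1d(np.asarray(covariates[name], dtype=float))
            if kind == "polynomial":
                self._check_range(name, x)
                for j, c in enumerate(coefs):
                    total += c * x ** (j + 1)
            elif kind == "categorical":
                self._check_range(name, x)
                total += coefs[np.searchsorted(term["edges"], x, side="right")]
            elif kind == "binary":
                total += coefs[0] * (x != 0)
        return total - self.reference(sex)


def default_model() -> FraminghamModel:
    """The packaged total-cholesterol Framingham coefficient bundle."""
    ref = resources.files("chdrisk.data").joinpath("framingham_wilson1998_tc.json")
    with resources.as_file(ref) as p:
        return FraminghamModel.from_json(p)


def frs_linear_predictor(profile: RiskFactorProfile, model: FraminghamModel) -> float:
    """Centred log relative hazard A for one individual."""
    cov = {
        "age": np.array([profile.age]),
        "tc": np.array([profile.tc]),
        "hdl": np.array([profile.hdl]),
        "sbp": np.array([profile.sbp]),
        "dbp": np.array([profile.dbp]),
        "diabetes": np.array([float(profile.diabetes)]),
        "smoker": np.array([float(profile.smoker)]),
    }
    return float(model.linear_predictor(profile.sex, cov)[0])


def ten_year_risk(A, s10):
    """Absolute 10-year risk ``P = 1 - s10 ** exp(A)``.

    Strictly increasing in A, strictly decreasing in s10, always in (0, 1)
    for finite A.
    """
    s10 = np.asarray(s10, dtype=float)
    if np.any((s10 <= 0) | (s10 >= 1)):
        raise ValidationError("baseline survival s10 must lie strictly inside (0, 1)")
    out = 1.0 - np.power(s10, np.exp(np.asarray(A, dtype=float)))
    if out.ndim == 0:
        return float(out)
    return out


def assign_category(P):
    """Map risk probabilities to the four ordered categories.

    The partition is half-open: [0, 5%), [5%, 10%), [10%, 20%), [20%, 100%].
    Accepts a scalar or array; returns a label or array of labels.
    """
    p = np.asarray(P, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("risk probabilities must lie in [0, 1]")
    idx = np.searchsorted(CATEGORY_EDGES, p, side="right")
    if np.ndim(idx) == 0:
        return RISK_CATEGORIES[int(idx)]
    return np.asarray(RISK_CATEGORIES, dtype=object)[idx]


def cohort_risk(cohort: pd.DataFrame, model: FraminghamModel) -> pd.DataFrame:
    """Vectorized risk assessment for a cohort table.

    Expects the cohort schema of :mod:`chdrisk.synthetic_cohort` (sex coded
    ``F``/``M``).  Returns ``id, frs_A, frs_risk, frs_category`` in the
    input row order.
    """
    df = cohort.reset_index(drop=True)
    A = np.empty(len(df), dtype=float)
    s10 = np.empty(len(df), dtype=float)
    for code, sex in (("F", "female"), ("M", "male")):
        mask = (df["sex"] == code).to_numpy()
        if not mask.any():
            continue
        sub = df.loc[mask]
        cov = {
            "age": sub["age"].to_numpy(float),
            "tc": sub["tc"].to_numpy(float),
            "hdl": sub["hdl"].to_numpy(float),
            "sbp": sub["sbp"].to_numpy(float),
            "dbp": sub["dbp"].to_numpy(float),
            "diabetes": sub["diabetes"].to_numpy(float),
            "smoker": sub["smoker"].to_numpy(float),
        }
        A[mask] = model.linear_predictor(sex, cov)
        s10[mask] = model.s10(sex)
    risk = ten_year_risk(A, s10)
    return pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "frs_A": A,
            "frs_risk": risk,
            "frs_category": assign_category(risk),
            "s10": s10,
        }
    )
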