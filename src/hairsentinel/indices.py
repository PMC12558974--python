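"""Derived health indices: stress impact, nutrient ratios and deficiency,
scalp health, and the hormonal fluctuation index (HFI).

These composite scores turn raw survey answers into the quantities the
anomaly-detection and forecasting layers operate on:

* ``SIS = daily_stress / 7 * stress_frequency`` — stress intensity
  normalised to a daily scale by the weekly recurrence.
* nutrient intake ratio — weekly intake events scaled by the gender- and
  age-specific recommended daily allowance (RDA, the "bio-profile scaler"):
  ``freq * per_day / per_week``; 1.0 means full adherence.
* ``NDS = 1 - (protein_ratio + omega_ratio + iron_ratio)`` — positive
  values flag a nutritional deficiency.
* ``SHS`` — a linear combination of shampoo type, conditioner use and hair
  strength, fit by ordinary least squares and optionally refined by an
  EM shrinkage procedure for noisy or partially missing scores.
* ``HFI = (SIS + daily_stress + hairfall_rate - sleeping_hours)
  / (protein_ratio + iron_ratio + omega_ratio + 1)`` — the +1 keeps the
  denominator >= 1 so the index is always finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError, DomainError, FittingError, LookupError_, RefinementError

__all__ = [
    "RDATable",
    "DerivedIndices",
    "LinearModel",
    "EMState",
    "stress_impact_score",
    "nutrient_intake_ratio",
    "nutrient_deficiency_score",
    "hormonal_fluctuation_index",
    "fit_linear_model",
    "scalp_health_score",
    "em_refine",
    "EMRefiner",
    "compute_indices",
    "NUTRIENTS",
]

NUTRIENTS = ("protein", "iron", "omega3")

#: Adult per-day requirements (NIH-style): protein g, iron mg, omega-3 g.
_DEFAULT_RDA = {
    ("protein", "male"): 56.0,
    ("protein", "female"): 46.0,
    ("iron", "male"): 8.0,
    ("iron", "female"): 18.0,
    ("omega3", "male"): 1.6,
    ("omega3", "female"): 1.1,
}


@dataclass
class RDAEntry:
    per_day: float
    per_week: float

    def __post_init__(self) -> None:
        if self.per_day <= 0 or self.per_week <= 0:
            raise DomainError("RDA requirements must be positive")


@dataclass
class RDATable:
    """Recommended dietary allowances keyed by (nutrient, gender, age band).

    Age bands are half-open ``[lo, hi)`` intervals in years. The default
    table carries a single adult band with NIH-style values; everything is
    overridable via JSON.
    """

    # (nutrient, gender) -> list of (age_lo, age_hi, RDAEntry)
    entries: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RDATable":
        table = cls()
        for (nutrient, gender), per_day in _DEFAULT_RDA.items():
            table.add(nutrient, gender, 0.0, 200.0, per_day)
        return table

    def add(self, nutrient: str, gender: str, age_lo: float, age_hi: float,
            per_day: float, per_week: float | None = None) -> None:
        if per_week is None:
            per_week = 7.0 * per_day
        entry = RDAEntry(per_day=float(per_day), per_week=float(per_week))
        self.entries.setdefault((nutrient, gender), []).append((age_lo, age_hi, entry))

    def lookup(self, nutrient: str, gender: str, age: float) -> RDAEntry:
        bands = self.entries.get((nutrient, gender))
        if bands is None:
            raise LookupError_(f"no RDA entry for nutrient={nutrient!r}, gender={gender!r}")
        for lo, hi, entry in bands:
            if lo <= age < hi:
                return entry
        raise LookupError_(
            f"no RDA age band covers age={age} for nutrient={nutrient!r}, gender={gender!r}"
        )

    def to_json(self) -> str:
        payload = [
            {"nutrient": n, "gender": g, "age_lo": lo, "age_hi": hi,
             "per_day": e.per_day, "per_week": e.per_week}
            for (n, g), bands in sorted(self.entries.items())
            for lo, hi, e in bands
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RDATable":
        table = cls()
        for row in json.loads(text):
            table.add(row["nutrient"], row["gender"], row["age_lo"], row["age_hi"],
                      row["per_day"], row.get("per_week"))
        return table


@dataclass
class DerivedIndices:
    """All composite scores for one survey record."""

    sis: float
    protein_ratio: float
    iron_ratio: float
    omega_ratio: float
    nds: float
    hfi: float
    shs: float | None = None
    shs_refined: float | None = None

    @property
    def deficient(self) -> bool:
        return self.nds > 0

    def as_dict(self) -> dict:
        return {
            "sis": self.sis, "protein_ratio": self.protein_ratio,
            "iron_ratio": self.iron_ratio, "omega_ratio": self.omega_ratio,
            "nds": self.nds, "hfi": self.hfi, "shs": self.shs,
            "shs_refined": self.shs_refined,
        }


def stress_impact_score(daily_stress, stress_frequency):
    """``daily_stress / 7 * stress_frequency``.

    ``daily_stress`` is the 1-10 self-reported level, ``stress_frequency``
    the number of stressed days per week (0-7). Accepts scalars or arrays.
    """
    ds = np.asarray(daily_stress, dtype=float)
    sf = np.asarray(stress_frequency, dtype=float)
    if np.any(ds < 1) or np.any(ds > 10):
        raise DomainError("daily_stress must lie in [1, 10]")
    if np.any(sf < 0) or np.any(sf > 7):
        raise DomainError("stress_frequency must lie in [0, 7]")
    out = ds / 7.0 * sf
    return float(out) if out.ndim == 0 else out


def nutrient_intake_ratio(freq_per_week, nutrient: str, gender: str, age: float,
                          rda: RDATable):
    """Weekly intake events scaled by the bio-profile (RDA) scaler.

    ``freq * per_day / per_week`` — with the default per_week = 7*per_day
    this is simply freq/7, i.e. the fraction of days the nutrient was taken.
    """
    entry = rda.lookup(nutrient, gender, age)
    freq = np.asarray(freq_per_week, dtype=float)
    if np.any(freq < 0):
        raise DomainError("intake frequency must be >= 0")
    out = freq * entry.per_day / entry.per_week
    return float(out) if out.ndim == 0 else out


def nutrient_deficiency_score(protein_ratio, omega_ratio, iron_ratio):
    """``1 - (protein_ratio + omega_ratio + iron_ratio)``; > 0 means deficient."""
    p = np.asarray(protein_ratio, dtype=float)
    o = np.asarray(omega_ratio, dtype=float)
    i = np.asarray(iron_ratio, dtype=float)
    if np.any(p < 0) or np.any(o < 0) or np.any(i < 0):
        raise DomainError("intake ratios must be >= 0")
    out = 1.0 - (p + o + i)
    return float(out) if out.ndim == 0 else out


def hormonal_fluctuation_index(sis, daily_stress, hairfall_rate, sleeping_hours,
                               protein_ratio, iron_ratio, omega_ratio):
    """(SIS + daily stress + hairfall rate − sleeping hours) / (ratios + 1).

    The +1 stabilising term keeps the denominator >= 1 even at zero intake,
    so the index is finite for every admissible input.
    """
    p = np.asarray(protein_ratio, dtype=float)
    i = np.asarray(iron_ratio, dtype=float)
    o = np.asarray(omega_ratio, dtype=float)
    sl = np.asarray(sleeping_hours, dtype=float)
    if np.any(p < 0) or np.any(i < 0) or np.any(o < 0):
        raise DomainError("intake ratios must be >= 0")
    if np.any(sl < 0):
        raise DomainError("sleeping_hours must be >= 0")
    num = (np.asarray(sis, dtype=float) + np.asarray(daily_stress, dtype=float)
           + np.asarray(hairfall_rate, dtype=float) - sl)
    out = num / (p + i + o + 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class LinearModel:
    """OLS fit: ``intercept + dot(coefficients, features)``."""

    intercept: float
    coefficients: dict  # feature name -> weight
    residual_sd: float

    def predict(self, features: Mapping[str, float]) -> float:
        missing = set(self.coefficients) - set(features)
        if missing:
            raise ContractError(f"missing features: {sorted(missing)}")
        return self.intercept + sum(w * float(features[name])
                                    for name, w in self.coefficients.items())

    def predict_matrix(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        if list(names) != list(self.coefficients):
            raise ContractError(
                f"feature names {list(names)} do not match model {list(self.coefficients)}")
        w = np.array([self.coefficients[n] for n in names])
        return self.intercept + np.asarray(X, dtype=float) @ w


def fit_linear_model(X, y, feature_names: Sequence[str] | None = None) -> LinearModel:
    """Ordinary least squares with an explicit intercept.

    Raises :class:`FittingError` naming the collinear columns when the
    design (with intercept) is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ContractError("X must be 2-D")
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(d)]
    if len(feature_names) != d:
        raise ContractError("feature_names length must match column count")
    if n <= d:
        raise FittingError(f"need more rows ({n}) than features ({d})")
    if np.isnan(X).any() or np.isnan(y).any():
        raise FittingError("design or target contains missing values")

    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < d + 1:
        # pivoted QR: columns past the numerical rank are linear combinations
        # of earlier ones
        from scipy.linalg import qr

        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        dependent = sorted(piv[np.sum(diag > tol):].tolist())
        names = ["intercept"] + list(feature_names)
        bad = [names[j] for j in dependent]
        raise FittingError(f"rank-deficient design; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = max(n - d - 1, 1)
    return LinearModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(feature_names, beta[1:])},
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


#: Feature set the scalp-health regression is defined on.
SHS_FEATURES = ("shampoo_type", "conditioner_used", "hair_strength")


def scalp_health_score(features: Mapping[str, float], model: LinearModel) -> float:
    """Linear scalp score ``w0 + w1*shampoo + w2*conditioner + w3*strength``."""
    if not set(model.coefficients) <= set(features):
        missing = sorted(set(model.coefficients) - set(features))
        raise ContractError(f"feature names do not match the fitted model; missing {missing}")
    return model.predict(features)


@dataclass
class EMState:
    """State of the EM shrinkage refinement of noisy/missing scores."""

    mu: float
    sigma2: float
    rho: float
    iteration: int
    refined: np.ndarray
    observed: np.ndarray
    converged: bool


def em_refine(observed, rho: float, tol: float = 1e-10, max_iter: int = 500) -> EMState:
    """Refine noisy scores with missing entries by EM-style shrinkage.

    E-step: ``z_i = mu + rho*(y_i - mu)`` for observed entries, ``z_i = mu``
    for missing ones. M-step: ``mu = mean(z)``, ``sigma2 = var(z)``
    (population variance). Iterates until both parameter increments fall
    below ``tol`` or ``max_iter`` is reached. ``rho`` in [0, 1] weights how
    much an observation is trusted over the pooled mean.
    """
    y = np.asarray(observed, dtype=float)
    if not (0.0 <= rho <= 1.0):
        raise DomainError("rho must lie in [0, 1]")
    mask = ~np.isnan(y)
    if mask.sum() < 2:
        raise RefinementError("need at least 2 observed entries")

    mu = float(y[mask].mean())
    sigma2 = float(y[mask].var())
    refined = np.where(mask, mu + rho * (y - mu), mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        refined = np.where(mask, mu + rho * (y - mu), mu)
        mu_new = float(refined.mean())
        sigma2_new = float(refined.var())
        if abs(mu_new - mu) < tol and abs(sigma2_new - sigma2) < tol:
            mu, sigma2 = mu_new, sigma2_new
            converged = True
            break
        mu, sigma2 = mu_new, sigma2_new
    # refresh the E-step at the final parameters
    refined = np.where(mask, mu + rho * (y - mu), mu)
    return EMState(mu=mu, sigma2=sigma2, rho=rho, iteration=it,
                   refined=refined, observed=y, converged=converged)


class EMRefiner:
    """Estimator wrapper around :func:`em_refine` (fit/transform style)."""

    def __init__(self, rho: float = 0.5, tol: float = 1e-10, max_iter: int = 500):
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"rho": self.rho, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "EMRefiner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ContractError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, y) -> "EMRefiner":
        state = em_refine(y, rho=self.rho, tol=self.tol, max_iter=self.max_iter)
        self.mu_ = state.mu
        self.sigma2_ = state.sigma2
        self.refined_ = state.refined
        self.n_iter_ = state.iteration
        self.converged_ = state.converged
        self.state_ = state
        return self

    def fit_transform(self, y) -> np.ndarray:
        return self.fit(y).refined_


def compute_indices(record: Mapping, rda: RDATable,
                    shs_model: LinearModel | None = None,
                    encoded_shs_features: Mapping[str, float] | None = None) -> DerivedIndices:
    """Compute every derived index for one survey record.

    ``record`` must expose daily_stress_level, stress_frequency, the three
    weekly intake frequencies, gender, age, hairfall_rate and sleeping_hours.
    When a fitted scalp model and the encoded shampoo/conditioner/strength
    features are supplied, the SHS is evaluated as well.
    """
    sis = stress_impact_score(record["daily_stress_level"], record["stress_frequency"])
    gender, age = str(record["gender"]), float(record["age"])
    pr = nutrient_intake_ratio(record["protein_freq"], "protein", gender, age, rda)
    ir = nutrient_intake_ratio(record["iron_freq"], "iron", gender, age, rda)
    om = nutrient_intake_ratio(record["omega_freq"], "omega3", gender, age, rda)
    nds = nutrient_deficiency_score(pr, om, ir)
    hfi = hormonal_fluctuation_index(
        sis, record["daily_stress_level"], record["hairfall_rate"],
        record["sleeping_hours"], pr, ir, om)
    shs = None
    if shs_model is not None and encoded_shs_features is not None:
        shs = scalp_health_score(encoded_shs_features, shs_model)
    return DerivedIndices(sis=sis, protein_ratio=pr, iron_ratio=ir, omega_ratio=om,
                          nds=nds, hfi=hfi, shs=shs)
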