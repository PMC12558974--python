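"""Synthetic survey cohorts and per-user daily index series.

The original 750-participant survey behind this framework is private, so
this module generates cohorts that follow the published schema: ordinal
hair indicators within their printed bounds (hairfall rate 1-5, density and
strength 1-10, thickness 1-5), lifestyle fields, stress metrics and weekly
nutrient intake frequencies. Distributions are deliberately simple and
fully configurable: ordinals uniform within bounds, sleeping hours
Normal(7, 1) clipped to [3, 12], intake frequencies Binomial(7, p) with
per-nutrient (optionally gender-conditional) propensities.

Daily series carry the hormonal fluctuation index (HFI) computed from the
stored covariates through :mod:`hairsentinel.indices`, so every stored
derived value is reproducible from the stored raw fields. Anomalies are
injected as additive HFI shifts (realised through the daily-stress
covariate so self-consistency is preserved) and/or hairfall-rate jumps,
with a labelled mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .indices import RDATable, hormonal_fluctuation_index, nutrient_intake_ratio, stress_impact_score

__all__ = [
    "CohortConfig",
    "CohortTable",
    "AnomalySpec",
    "UserSeries",
    "ORDINAL_BOUNDS",
    "CATEGORY_LEVELS",
    "generate_cohort",
    "generate_user_series",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_series_csv",
    "read_series_csv",
]

#: Ordinal survey fields and their inclusive bounds (from the survey schema).
ORDINAL_BOUNDS: dict[str, tuple[int, int]] = {
    "hairfall_rate": (1, 5),
    "hair_density": (1, 10),
    "hair_strength": (1, 10),
    "hair_thickness": (1, 5),
    "wash_frequency": (1, 7),
    "daily_stress_level": (1, 10),
    "stress_frequency": (0, 7),
    "junk_food": (0, 7),
}

CATEGORY_LEVELS: dict[str, list[str]] = {
    "gender": ["female", "male"],
    "hair_type": ["straight", "wavy", "curly", "coily"],
    "scalp_condition": ["dry", "normal", "oily", "dandruff"],
    "shampoo_type": ["organic", "mild", "chemical"],
    "stressor_type": ["exams", "professional", "personal", "health"],
    "water_intake_range": ["<1 L", "1-2 L", "2-3 L", ">3 L"],
}

BOOLEAN_FIELDS = [
    "hairfall_problem", "hair_treatment", "conditioner_used",
    "supplement_used", "hereditary", "self_reported_deficiency",
]

INTAKE_FIELDS = ["protein_freq", "iron_freq", "omega_freq"]


@dataclass
class CohortConfig:
    """Generation parameters; defaults define the study conditions."""

    age_range: tuple[int, int] = (18, 60)
    sleep_mean: float = 7.0
    sleep_sd: float = 1.0
    sleep_clip: tuple[float, float] = (3.0, 12.0)
    #: Binomial(7, p) propensities per nutrient, optionally per gender.
    intake_propensity: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {
            "protein_freq": 0.6,
            "iron_freq": {"female": 0.45, "male": 0.55},
            "omega_freq": 0.35,
        })
    bool_probability: Mapping[str, float] = field(
        default_factory=lambda: {
            "hairfall_problem": 0.5, "hair_treatment": 0.3,
            "conditioner_used": 0.6, "supplement_used": 0.3,
            "hereditary": 0.35, "self_reported_deficiency": 0.25,
        })

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid age_range {self.age_range}")
        if self.sleep_sd <= 0:
            raise ConfigurationError("sleep_sd must be positive")
        clo, chi = self.sleep_clip
        if not (0 < clo < chi < 24):
            raise ConfigurationError(f"invalid sleep_clip {self.sleep_clip}")
        for name in INTAKE_FIELDS:
            p = self.intake_propensity.get(name, 0.5)
            values = p.values() if isinstance(p, Mapping) else [p]
            if any(not (0.0 <= v <= 1.0) for v in values):
                raise ConfigurationError(f"intake propensity for {name} outside [0, 1]")
        for name, p in self.bool_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability for {name} outside [0, 1]")


@dataclass
class CohortTable:
    """Ordered survey records with optional per-record anomaly labels."""

    records: pd.DataFrame
    anomaly_labels: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if ("user_id" in self.records.columns and len(self.records)
                and self.records["user_id"].duplicated().any()):
            raise ConfigurationError("user_id values must be unique")
        if self.anomaly_labels is not None and len(self.anomaly_labels) != len(self.records):
            raise ConfigurationError("anomaly_labels length must match records")

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(n: int, seed: int, config: CohortConfig | None = None) -> CohortTable:
    """Generate ``n`` survey records. Identical seed+config give identical output."""
    if n < 0:
        raise DomainError("n must be >= 0")
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    cols: dict[str, object] = {}
    cols["user_id"] = [f"u{i:05d}" for i in range(n)]
    lo, hi = config.age_range
    cols["age"] = rng.integers(lo, hi + 1, size=n)
    gender = rng.choice(CATEGORY_LEVELS["gender"], size=n)
    cols["gender"] = gender
    for name, (blo, bhi) in ORDINAL_BOUNDS.items():
        cols[name] = rng.integers(blo, bhi + 1, size=n)
    for name, levels in CATEGORY_LEVELS.items():
        if name == "gender":
            continue
        cols[name] = rng.choice(levels, size=n)
    for name in BOOLEAN_FIELDS:
        cols[name] = rng.random(n) < config.bool_probability[name]
    sleep = rng.normal(config.sleep_mean, config.sleep_sd, size=n)
    cols["sleeping_hours"] = np.clip(sleep, *config.sleep_clip).round(2)
    for name in INTAKE_FIELDS:
        p = config.intake_propensity.get(name, 0.5)
        if isinstance(p, Mapping):
            probs = np.array([p[g] for g in gender])
        else:
            probs = np.full(n, float(p))
        cols[name] = rng.binomial(7, probs)

    df = pd.DataFrame(cols)
    return CohortTable(records=df, seed=seed)


@dataclass
class AnomalySpec:
    """Additive anomaly injection into a daily series.

    ``hfi_shift`` moves the HFI by exactly that amount on the listed days
    (realised through the daily-stress covariate so the stored HFI stays
    recomputable from stored covariates); ``rate_jump`` adds to the 1-5
    hairfall rate, clipped to its bounds.
    """

    days: Sequence[int]
    hfi_shift: float = 0.0
    rate_jump: int = 0


@dataclass
class UserSeries:
    """Daily HFI series plus the covariates it was computed from."""

    user_id: str
    frame: pd.DataFrame  # indexed by date: hfi, hairfall_rate, covariates, anomaly

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame.index)

    @property
    def hfi(self) -> np.ndarray:
        return self.frame["hfi"].to_numpy()


#: Covariate columns stored alongside hfi/hairfall_rate in a UserSeries.
SERIES_COVARIATES = ["sis", "daily_stress", "sleep", "protein_ratio", "iron_ratio", "omega_ratio"]


def generate_user_series(record: Mapping, days: int, seed: int,
                         anomaly_spec: AnomalySpec | None = None,
                         rda: RDATable | None = None,
                         start: str = "2025-02-01") -> UserSeries:
    """Simulate a daily index series for one survey record.

    Daily stress wanders around the record's reported level, sleep around
    the reported hours, and nutrient ratios drift slowly around the weekly
    intake-frequency ratios. The HFI is then computed exactly from these
    stored covariates, so re-feeding them to the indices module reproduces
    the stored series.
    """
    if days < 1:
        raise DomainError("days must be >= 1")
    rda = rda or RDATable.default()
    rng = np.random.default_rng(seed)
    gender, age = str(record["gender"]), float(record["age"])

    base_stress = float(record["daily_stress_level"])
    stress = np.clip(base_stress + rng.normal(0, 0.8, size=days), 1.0, 10.0)
    sleep = np.clip(float(record["sleeping_hours"]) + rng.normal(0, 0.5, size=days), 1.0, 14.0)
    rate = np.clip(np.rint(float(record["hairfall_rate"]) + rng.normal(0, 0.6, size=days)),
                   1, 5).astype(int)

    ratios = {}
    for name, nutrient in zip(INTAKE_FIELDS, ("protein", "iron", "omega3")):
        base = nutrient_intake_ratio(float(record[name]), nutrient, gender, age, rda)
        drift = np.clip(base + 0.05 * np.cumsum(rng.normal(0, 0.2, size=days)) / np.sqrt(days)
                        + rng.normal(0, 0.02, size=days), 0.0, 1.5)
        ratios[nutrient] = drift

    stress_freq = float(record["stress_frequency"])
    anomaly = np.zeros(days, dtype=bool)
    if anomaly_spec is not None:
        for day in anomaly_spec.days:
            if not (0 <= day < days):
                raise DomainError(f"anomaly day {day} outside series of length {days}")
            anomaly[day] = True
        if anomaly_spec.rate_jump:
            rate[anomaly] = np.clip(rate[anomaly] + anomaly_spec.rate_jump, 1, 5)
        if anomaly_spec.hfi_shift:
            # HFI numerator = sis + stress + rate - sleep with
            # sis = stress*sf/7, so d(HFI)/d(stress) = (1 + sf/7)/denom;
            # shifting stress by shift*denom/(1+sf/7) moves HFI by exactly
            # hfi_shift while keeping it recomputable from covariates.
            denom = (ratios["protein"][anomaly] + ratios["iron"][anomaly]
                     + ratios["omega3"][anomaly] + 1.0)
            stress[anomaly] += anomaly_spec.hfi_shift * denom / (1.0 + stress_freq / 7.0)

    sis = stress / 7.0 * stress_freq
    hfi = hormonal_fluctuation_index(sis, stress, rate, sleep,
                                     ratios["protein"], ratios["iron"], ratios["omega3"])

    frame = pd.DataFrame({
        "hfi": np.atleast_1d(hfi),
        "hairfall_rate": rate,
        "sis": sis,
        "daily_stress": stress,
        "sleep": sleep,
        "protein_ratio": ratios["protein"],
        "iron_ratio": ratios["iron"],
        "omega_ratio": ratios["omega3"],
        "anomaly": anomaly,
    }, index=pd.date_range(start, periods=days, freq="D"))
    frame.index.name = "date"
    return UserSeries(user_id=str(record["user_id"]), frame=frame)


def write_cohort_csv(table: CohortTable, path) -> None:
    df = table.records.copy()
    if table.anomaly_labels is not None:
        df["anomaly_label"] = table.anomaly_labels
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> CohortTable:
    df = pd.read_csv(path)
    labels = None
    if "anomaly_label" in df.columns:
        labels = df.pop("anomaly_label").to_numpy(dtype=bool)
    return CohortTable(records=df, anomaly_labels=labels)


def write_series_csv(series: UserSeries, path) -> None:
    df = series.frame.reset_index()
    df.insert(0, "user_id", series.user_id)
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_series_csv(path) -> list[UserSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for uid, grp in df.groupby("user_id", sort=False):
        frame = grp.drop(columns=["user_id"]).set_index("date")
        out.append(UserSeries(user_id=str(uid), frame=frame))
    return out
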