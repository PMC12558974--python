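"""Anomaly severity classification against a matched historical record.

A user's current HFI and hairfall rate are compared with the matched
record's values; the absolute deltas are run through threshold rules:

* severe  — ΔHFI > 1.5 or ΔRate > 2 (default profile)
* mild    — else ΔHFI > 0.8 or ΔRate >= 1
* normal  — otherwise

Note the deliberately mixed operators: the severe rate clause is strict
(> 2) while the mild rate clause is inclusive (>= 1). Deltas are absolute
values: drops in HFI are as anomalous as rises; the signed direction is
kept in provenance only. An alternate "case-study" profile (severe
ΔHFI > 1.0) is shipped because the source material states both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cohort import CohortTable
from .errors import ConfigurationError, ContractError, DomainError
from .indices import DerivedIndices, RDATable, compute_indices
from .matching import (DEFAULT_MATCH_FIELDS, KMeansMatcher, MatchResult,
                       default_k, find_exact_match)
from .preprocessing import EncodedMatrix, EncodingSpec, FeatureScaler, encode_record, encode_table

__all__ = [
    "SeverityConfig",
    "SEVERITY_PROFILES",
    "SeverityAssessment",
    "classify_severity",
    "forecast_severity",
    "assess_user",
    "SEVERITY_ORDER",
]

SEVERITY_ORDER = {"normal": 0, "mild": 1, "severe": 2}


@dataclass
class SeverityConfig:
    hfi_severe: float = 1.5
    rate_severe: float = 2.0
    hfi_mild: float = 0.8
    rate_mild: float = 1.0
    tau_forecast: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.hfi_mild < self.hfi_severe):
            raise ConfigurationError("need 0 < hfi_mild < hfi_severe")
        if not (0 < self.rate_mild <= self.rate_severe):
            raise ConfigurationError("need 0 < rate_mild <= rate_severe")
        if self.tau_forecast <= 0:
            raise ConfigurationError("tau_forecast must be > 0")


#: Named threshold profiles; "default" follows the algorithm description,
#: "case-study" the alternative thresholds quoted in the worked cases.
SEVERITY_PROFILES = {
    "default": SeverityConfig(),
    "case-study": SeverityConfig(hfi_severe=1.0, rate_severe=2.0,
                                 hfi_mild=0.5, rate_mild=1.0),
}


@dataclass
class SeverityAssessment:
    delta_hfi: float
    delta_rate: float
    label: str
    triggered_rules: list = field(default_factory=list)
    matched: MatchResult | None = None
    query_indices: DerivedIndices | None = None
    matched_indices: DerivedIndices | None = None
    signed_delta_hfi: float | None = None
    signed_delta_rate: float | None = None


def classify_severity(delta_hfi: float, delta_rate: float,
                      config: SeverityConfig | None = None) -> SeverityAssessment:
    """Threshold rules on absolute index deltas; see module docstring."""
    config = config or SeverityConfig()
    if delta_hfi < 0 or delta_rate < 0:
        raise DomainError("deltas must be absolute values (>= 0)")
    rules = []
    if delta_hfi > config.hfi_severe:
        rules.append("severe:hfi")
    if delta_rate > config.rate_severe:
        rules.append("severe:rate")
    if rules:
        label = "severe"
    else:
        if delta_hfi > config.hfi_mild:
            rules.append("mild:hfi")
        if delta_rate >= config.rate_mild:
            rules.append("mild:rate")
        label = "mild" if rules else "normal"
    return SeverityAssessment(delta_hfi=float(delta_hfi), delta_rate=float(delta_rate),
                              label=label, triggered_rules=rules)


def forecast_severity(forecast_value: float, config: SeverityConfig) -> int:
    """Binary severity of a forecast: 1 iff the value reaches the cutoff τ."""
    return int(forecast_value >= config.tau_forecast)


def assess_user(query: Mapping, cohort: CohortTable, rda: RDATable | None = None,
                config: SeverityConfig | None = None,
                encoding_spec: EncodingSpec | None = None,
                match_fields=DEFAULT_MATCH_FIELDS,
                k: int | None = None, seed: int = 0) -> SeverityAssessment:
    """Full assessment pipeline for one user.

    exact match -> (else) k-means cluster nearest on scaled features ->
    derived indices for both records -> absolute deltas -> severity rules.
    """
    from .preprocessing import default_encoding_spec

    if len(cohort) == 0:
        raise ContractError("cohort is empty")
    rda = rda or RDATable.default()
    config = config or SeverityConfig()
    spec = encoding_spec or default_encoding_spec()

    match = find_exact_match(query, cohort, match_fields)
    if match is None:
        fields = [c for c in cohort.records.columns if c != "user_id"]
        matrix = encode_table(cohort, spec, fields)
        scaler = FeatureScaler(method="zscore")
        keep = [name for name in matrix.column_names
                if matrix.column(name).std() > 0]
        scaler = FeatureScaler(method="zscore", columns=keep)
        scaled = scaler.fit_transform(matrix)
        qvec = encode_record(query, spec, fields)
        qmat = EncodedMatrix(values=qvec[None, :], column_names=fields)
        qscaled = scaler.transform(qmat).values[0]
        matcher = KMeansMatcher(k=k if k is not None else default_k(len(cohort)),
                                seed=seed).fit(scaled, cohort.records["user_id"])
        match = matcher.query(qscaled)

    matched_row = cohort.records.iloc[match.row_index]
    qi = compute_indices(query, rda)
    mi = compute_indices(matched_row, rda)
    signed_hfi = qi.hfi - mi.hfi
    signed_rate = float(query["hairfall_rate"]) - float(matched_row["hairfall_rate"])
    assessment = classify_severity(abs(signed_hfi), abs(signed_rate), config)
    assessment.matched = match
    assessment.query_indices = qi
    assessment.matched_indices = mi
    assessment.signed_delta_hfi = signed_hfi
    assessment.signed_delta_rate = signed_rate
    return assessment
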