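"""Configuration for the synthetic urgent-and-emergency-care generator.

The defaults encode the study conditions the pipeline is designed for:
per-source identifier completeness taken from the national data the linkage
methodology was developed on (NHS number recorded for 99.7% of inpatient
episodes, 98.0% of ED attendances, 96.3% of telephone-helpline calls and
only 14.4% of ambulance incidents), an ambulance conveyance rate of 60.1%,
and a majority (~54%) of inpatient admissions being non-emergency.  Event
volumes are scaled to a desk-size population; the per-capita ordering of the
four sources (ED and inpatient busiest, helpline and ambulance lighter) is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Mapping

SOURCES = ("NHS111", "AMB", "ED", "IP")

DISPOSITIONS = ("self_care", "primary_care", "ed_advised", "ambulance_dispatched")


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is out of range."""


def _default_event_rates() -> dict:
    return {"NHS111": 0.5, "AMB": 0.4, "ED": 0.8, "IP": 0.35}


def _default_nhs_presence() -> dict:
    # per-source completeness of the national patient identifier
    return {"NHS111": 0.963, "AMB": 0.144, "ED": 0.980, "IP": 0.997}


def _default_dob_presence() -> dict:
    return {"NHS111": 0.95, "AMB": 0.85, "ED": 0.97, "IP": 0.99}


def _default_name_presence() -> dict:
    # helpline calls never carry names; ambulance crews usually record them
    return {"NHS111": 0.0, "AMB": 0.90, "ED": 0.98, "IP": 0.99}


def _default_postcode_presence() -> dict:
    return {"NHS111": 0.90, "AMB": 0.95, "ED": 0.95, "IP": 0.97}


def _default_sex_presence() -> dict:
    return {"NHS111": 0.98, "AMB": 0.97, "ED": 0.99, "IP": 0.99}


def _default_disposition_probs() -> dict:
    return {
        "self_care": 0.30,
        "primary_care": 0.30,
        "ed_advised": 0.25,
        "ambulance_dispatched": 0.15,
    }


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic generator.

    Probabilities are unitless in [0, 1]; event rates are expected events per
    person over the whole period (Poisson means); time offsets are minutes.
    """

    n_persons: int = 20_000
    period_start: date = date(2016, 4, 1)
    period_end: date = date(2017, 3, 31)

    event_rates: Mapping[str, float] = field(default_factory=_default_event_rates)
    nhs_number_presence: Mapping[str, float] = field(default_factory=_default_nhs_presence)
    dob_presence: Mapping[str, float] = field(default_factory=_default_dob_presence)
    name_presence: Mapping[str, float] = field(default_factory=_default_name_presence)
    postcode_presence: Mapping[str, float] = field(default_factory=_default_postcode_presence)
    sex_presence: Mapping[str, float] = field(default_factory=_default_sex_presence)

    conveyance_prob: float = 0.601
    # ED arrival offset from ambulance arrival at destination, minutes;
    # default lies inside the -60/+180 linkage window
    ed_offset_minutes: tuple = (-15.0, 90.0)
    ed_offset_out_of_window_prob: float = 0.0
    admission_prob_given_ed: float = 0.30
    nonemergency_admission_rate: float = 0.54

    typo_rate: float = 0.05
    dob_transposition_rate: float = 0.02
    leading_zero_loss_rate: float = 0.10
    duplicate_rate_at_year_boundary: float = 0.01

    twin_fraction: float = 0.02
    communal_postcode_fraction: float = 0.01
    incident_at_home_prob: float = 0.5

    n_sites: int = 5
    n_postcodes: int = 4000
    n_communal_postcodes: int = 5
    disposition_probs: Mapping[str, float] = field(default_factory=_default_disposition_probs)

    seed: int = 0

    _PROB_FIELDS = (
        "conveyance_prob",
        "ed_offset_out_of_window_prob",
        "admission_prob_given_ed",
        "nonemergency_admission_rate",
        "typo_rate",
        "dob_transposition_rate",
        "leading_zero_loss_rate",
        "duplicate_rate_at_year_boundary",
        "twin_fraction",
        "communal_postcode_fraction",
        "incident_at_home_prob",
    )
    _PROB_MAPS = (
        "nhs_number_presence",
        "dob_presence",
        "name_presence",
        "postcode_presence",
        "sex_presence",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigurationError("n_persons must be >= 0")
        if not self.period_start < self.period_end:
            raise ConfigurationError("period_start must be before period_end")
        for name in self._PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in self._PROB_MAPS:
            m = getattr(self, name)
            for src in SOURCES:
                if src not in m:
                    raise ConfigurationError(f"{name} missing source {src!r}")
                if not 0.0 <= m[src] <= 1.0:
                    raise ConfigurationError(
                        f"{name}[{src!r}] must be in [0, 1], got {m[src]!r}"
                    )
        for src in SOURCES:
            if src not in self.event_rates:
                raise ConfigurationError(f"event_rates missing source {src!r}")
            if self.event_rates[src] < 0:
                raise ConfigurationError(f"event_rates[{src!r}] must be >= 0")
        lo, hi = self.ed_offset_minutes
        if lo > hi:
            raise ConfigurationError("ed_offset_minutes must be (low, high) with low <= high")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_communal_postcodes > self.n_postcodes:
            raise ConfigurationError("n_communal_postcodes must be <= n_postcodes")
        if abs(sum(self.disposition_probs.get(d, 0.0) for d in DISPOSITIONS) - 1.0) > 1e-9:
            raise ConfigurationError("disposition_probs must sum to 1 over the code set")
        if not 0 <= self.seed < 2**63:
            raise ConfigurationError("seed must be a non-negative integer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["period_start"] = self.period_start.isoformat()
        d["period_end"] = self.period_end.isoformat()
        d["ed_offset_minutes"] = list(self.ed_offset_minutes)
        return d
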