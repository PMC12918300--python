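"""Configuration objects: contract types, simulation parameters, panel windows.

The synthetic-registry generator is parameterised by :class:`SimulationConfig`,
whose defaults emulate an unbalanced panel of ~160 primary care centres (PCCs)
in a 1.4M-resident Swedish region over 2010–2019: a mix of permanent, fixed-term,
freelance, registrar and foundation physicians, per-contract exit hazards,
practice openings/closures, and practice-level case-mix (ACG-style) and
deprivation (CNI-style) scores centred on 1.

Analysis windows (which practices and practice-years enter the turnover panel)
are described by :class:`PanelDefinition`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Optional

import yaml

from .errors import ConfigurationError

__all__ = [
    "ContractType",
    "TEMPORARY_CONTRACTS",
    "SimulationConfig",
    "PanelDefinition",
]


class ContractType(str, enum.Enum):
    """Closed enumeration of physician contract types.

    ``permanent`` and ``registrar`` physicians are long-stay employees (the
    registrar is a GP trainee placed at one practice for several years);
    ``fixed_term``, ``freelance`` and ``foundation`` are the temporary
    contracts that cover unfilled vacancies and short placements.
    """

    PERMANENT = "permanent"
    FIXED_TERM = "fixed_term"
    FREELANCE = "freelance"
    REGISTRAR = "registrar"
    FOUNDATION = "foundation"


#: Contract types counted as temporary workers in the mixture decomposition.
TEMPORARY_CONTRACTS = (
    ContractType.FIXED_TERM,
    ContractType.FREELANCE,
    ContractType.FOUNDATION,
)

_SUBTYPES = ("public", "investor_chain", "gp_partnership", "local_chain", "gp_owned")
_LOCATIONS = ("city", "commuting", "town", "rural")
#: Hazard-shift keys accepted in ``covariate_effects``. Tercile keys shift the
#: monthly exit hazard per tercile step (relative to the middle tercile);
#: indicator keys shift it additively for the flagged practices.
_TERCILE_EFFECT_KEYS = ("size", "morbidity", "deprivation", "workload")
_INDICATOR_EFFECT_KEYS = ("private", "town")


def _default_subtype_probs() -> dict:
    # 55% public; the private 45% split 39:9:7:15 between investor chains,
    # a national GP partnership, local chains and GP-owned independents.
    return {
        "public": 0.55,
        "investor_chain": 0.2507,
        "gp_partnership": 0.0579,
        "local_chain": 0.0450,
        "gp_owned": 0.0964,
    }


def _default_location_probs() -> dict:
    return {"city": 0.49, "commuting": 0.11, "town": 0.17, "rural": 0.23}


def _default_temp_type_probs() -> dict:
    return {"fixed_term": 0.45, "freelance": 0.40, "foundation": 0.15}


def _default_exit_hazards() -> dict:
    # Monthly probabilities that an ongoing spell ends. permanent 0.0134 gives
    # an annual spell-end probability 1-(1-q)^12 ~ 14.9%, matching the ~15%
    # turnover of permanently employed GPs; registrar 0.011 gives ~12.4%
    # (registrars ~13%). freelance 0.25 gives mean 4-month engagements.
    # fixed_term is the geometric parameter of the contract length drawn at
    # hire (mean = fixed_contract_mean_months); foundation placements have a
    # fixed length (foundation_months) and the entry is kept for validation.
    return {
        "permanent": 0.0134,
        "registrar": 0.011,
        "freelance": 0.25,
        "fixed_term": 0.25,
        "foundation": 1.0 / 6.0,
    }


def _default_covariate_effects() -> dict:
    # Additive monthly-hazard shifts giving the observed association structure
    # its qualitative shape: higher turnover with deprivation and workload,
    # lower in large and privately run practices, higher in towns. At the
    # default permanent hazard the annual rate responds by ~830 points per
    # unit of monthly hazard, so 0.003/step ~ 2.5 points per tercile step.
    # Magnitudes are kept small enough that the summed shifts stay within the
    # additive-hazard model's linear range (combined negative extremes would
    # otherwise clip at the hazard floor and attenuate the contrasts).
    # Tercile effects are centred on the middle tercile so the
    # workforce-average hazard is unchanged. Morbidity is left at zero: its
    # observed association is non-monotone and not representable as a linear
    # per-step shift.
    return {
        "size": -0.003,
        "deprivation": 0.003,
        "workload": 0.0035,
        "private": -0.004,
        "town": 0.006,
        "morbidity": 0.0,
    }


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and 0.0 <= float(value) <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_distribution(name: str, probs: Mapping[str, float], support: tuple) -> None:
    if set(probs) - set(support):
        raise ConfigurationError(
            f"{name} has unknown categories {sorted(set(probs) - set(support))}"
        )
    for key, p in probs.items():
        _check_prob(f"{name}[{key}]", p)
    total = float(sum(probs.values()))
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ConfigurationError(f"{name} must sum to 1, got {total}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic care-registry generator.

    The defaults are the package's reference study conditions; see
    ``docs/methods.md`` for the rationale behind each value.
    """

    n_practices: int = 157
    years: tuple = (2010, 2019)
    seed: int = 0
    share_private: float = 0.45
    ownership_subtype_probs: Mapping[str, float] = field(default_factory=_default_subtype_probs)
    location_probs: Mapping[str, float] = field(default_factory=_default_location_probs)
    mean_permanent_staff: float = 5.6
    registrars_per_practice: float = 0.5
    private_staff_factor: float = 0.85
    temporary_share: float = 0.20
    temp_type_probs: Mapping[str, float] = field(default_factory=_default_temp_type_probs)
    exit_hazard_by_contract: Mapping[str, float] = field(default_factory=_default_exit_hazards)
    fixed_contract_mean_months: float = 4.0
    foundation_months: int = 6
    consult_days_per_month: tuple = (13.5, 3.5)  # (mean, sd) of a rounded normal
    visits_per_day_iqr: tuple = (6.0, 8.0)
    patients_per_practice: tuple = (8665.0, 3802.0)  # (mean, sd), truncated at 500
    morbidity_sd: float = 0.11
    deprivation_sd: float = 0.36
    p_open_close: tuple = (0.10, 0.07)  # (P(opens mid-panel), P(closes mid-panel))
    open_month: Optional[int] = None  # None -> uniform over 1..12
    rampup_months: int = 18  # newly opened practices build up below-threshold activity
    leave_prob: float = 0.10
    leave_max_days: int = 300
    return_prob: float = 0.0
    covariate_effects: Mapping[str, float] = field(default_factory=_default_covariate_effects)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SimulationConfig":
        """Check all invariants; raise :class:`ConfigurationError` naming the field."""
        if not (isinstance(self.n_practices, int) and self.n_practices >= 1):
            raise ConfigurationError(f"n_practices must be a positive integer, got {self.n_practices!r}")
        y0, y1 = self.years
        if not (isinstance(y0, int) and isinstance(y1, int) and y0 <= y1):
            raise ConfigurationError(f"years must be an inclusive (start, end) span, got {self.years!r}")
        _check_prob("share_private", self.share_private)
        _check_distribution("ownership_subtype_probs", self.ownership_subtype_probs, _SUBTYPES)
        _check_distribution("location_probs", self.location_probs, _LOCATIONS)
        if self.mean_permanent_staff <= 0:
            raise ConfigurationError(f"mean_permanent_staff must be > 0, got {self.mean_permanent_staff}")
        if self.registrars_per_practice < 0:
            raise ConfigurationError(f"registrars_per_practice must be >= 0, got {self.registrars_per_practice}")
        if self.private_staff_factor <= 0:
            raise ConfigurationError(f"private_staff_factor must be > 0, got {self.private_staff_factor}")
        _check_prob("temporary_share", self.temporary_share)
        if self.temporary_share >= 1.0:
            raise ConfigurationError("temporary_share must be < 1")
        if self.temp_type_probs:
            _check_distribution(
                "temp_type_probs", self.temp_type_probs,
                tuple(c.value for c in TEMPORARY_CONTRACTS),
            )
        elif self.temporary_share > 0:
            raise ConfigurationError("temp_type_probs is empty but temporary_share > 0")
        known = {c.value for c in ContractType}
        for key, q in self.exit_hazard_by_contract.items():
            if key not in known:
                raise ConfigurationError(f"exit_hazard_by_contract has unknown contract {key!r}")
            _check_prob(f"exit_hazard_by_contract[{key}]", q)
        if self.temporary_share > 0:
            for temp in ("freelance", "fixed_term"):
                if self.temp_type_probs.get(temp, 0) > 0 and not self.exit_hazard_by_contract.get(temp, 0) > 0:
                    raise ConfigurationError(
                        f"exit_hazard_by_contract[{temp}] must be strictly positive for temporary types"
                    )
        if self.fixed_contract_mean_months < 1:
            raise ConfigurationError(f"fixed_contract_mean_months must be >= 1, got {self.fixed_contract_mean_months}")
        if not (isinstance(self.foundation_months, int) and self.foundation_months >= 1):
            raise ConfigurationError(f"foundation_months must be a positive integer, got {self.foundation_months!r}")
        mu, sd = self.consult_days_per_month
        if mu < 0 or sd < 0:
            raise ConfigurationError(f"consult_days_per_month (mean, sd) must be non-negative, got {self.consult_days_per_month!r}")
        lo, hi = self.visits_per_day_iqr
        if not (0 < lo <= hi):
            raise ConfigurationError(f"visits_per_day_iqr must satisfy 0 < p25 <= p75, got {self.visits_per_day_iqr!r}")
        pm, ps = self.patients_per_practice
        if pm <= 0 or ps < 0:
            raise ConfigurationError(f"patients_per_practice (mean, sd) invalid: {self.patients_per_practice!r}")
        if self.morbidity_sd < 0:
            raise ConfigurationError(f"morbidity_sd must be >= 0, got {self.morbidity_sd}")
        if self.deprivation_sd < 0:
            raise ConfigurationError(f"deprivation_sd must be >= 0, got {self.deprivation_sd}")
        p_open, p_close = self.p_open_close
        _check_prob("p_open_close[open]", p_open)
        _check_prob("p_open_close[close]", p_close)
        if self.open_month is not None and not (1 <= self.open_month <= 12):
            raise ConfigurationError(f"open_month must be in 1..12 or None, got {self.open_month!r}")
        if self.rampup_months < 0:
            raise ConfigurationError(f"rampup_months must be >= 0, got {self.rampup_months}")
        _check_prob("leave_prob", self.leave_prob)
        if not (0 < self.leave_max_days < 365):
            raise ConfigurationError(
                f"leave_max_days must be in (0, 365) so leaves never split spells, got {self.leave_max_days}"
            )
        _check_prob("return_prob", self.return_prob)
        allowed = set(_TERCILE_EFFECT_KEYS) | set(_INDICATOR_EFFECT_KEYS)
        for key in self.covariate_effects:
            if key not in allowed:
                raise ConfigurationError(
                    f"covariate_effects has unknown key {key!r}; allowed: {sorted(allowed)}"
                )
        return self

    # -- conveniences -------------------------------------------------------

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("ownership_subtype_probs", "location_probs", "temp_type_probs",
                    "exit_hazard_by_contract", "covariate_effects"):
            d[key] = dict(d[key])
        for key in ("years", "consult_days_per_month", "visits_per_day_iqr",
                    "patients_per_practice", "p_open_close"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        for key in ("years", "consult_days_per_month", "visits_per_day_iqr",
                    "patients_per_practice", "p_open_close"):
            if key in kwargs and isinstance(kwargs[key], (list, tuple)):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    # Expected temporary spell length in months under the configured mix; the
    # final (exit) month of a spell is partial and never qualifies for the
    # workforce, so slot counts are scaled by mean/(mean-1) to make
    # `temporary_share` the share of measured member-months.
    def expected_temp_months(self) -> tuple:
        total = 0.0
        active = 0.0
        for name, p in self.temp_type_probs.items():
            if p <= 0:
                continue
            if name == "freelance":
                mean = 1.0 / self.exit_hazard_by_contract.get("freelance", 0.25)
            elif name == "fixed_term":
                mean = self.fixed_contract_mean_months
            else:  # foundation
                mean = float(self.foundation_months)
            total += p * mean
            active += p * max(mean - 1.0, 0.0)
        return total, active


@dataclass(frozen=True)
class PanelDefinition:
    """Which practices and practice-years enter the turnover panel.

    ``final_turnover_year`` is the last year for which monthly rates are
    computed; it must leave room for the horizon (and ideally the 365-day gap
    confirmation) before the end of the data.
    """

    start_year: int = 2010
    end_year: int = 2018
    min_years_operating: int = 2
    exclude_closure_year: bool = True
    final_turnover_year: Optional[int] = None

    def validate(self) -> "PanelDefinition":
        final = self.final_year
        if not (self.start_year <= final <= self.end_year):
            raise ConfigurationError(
                f"final_turnover_year must lie in [{self.start_year}, {self.end_year}], got {final}"
            )
        if self.min_years_operating < 1:
            raise ConfigurationError(
                f"min_years_operating must be >= 1, got {self.min_years_operating}"
            )
        return self

    @property
    def final_year(self) -> int:
        return self.end_year if self.final_turnover_year is None else self.final_turnover_year

    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "min_years_operating": self.min_years_operating,
            "exclude_closure_year": self.exclude_closure_year,
            "final_turnover_year": self.final_year,
        }
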