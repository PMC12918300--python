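"""Synthetic care-registry generator.

Emulates the statistical structure of a regional consultation database: an
unbalanced panel of primary care centres (PCCs) staffed by permanent,
registrar, fixed-term, freelance and foundation physicians, each physician
providing consultations on a random number of distinct days per month, with
per-contract monthly exit hazards, within-spell leaves (consultation-free gaps
shorter than a year), practice openings/closures, monthly registration counts,
and practice-level case-mix/deprivation scores.

Modelling conventions (see docs/methods.md for the full account):

* Exits are memoryless per month within each contract type; fixed-term
  contracts draw their length at hire and end at expiry; foundation
  placements have a fixed length.
* A physician's final month is a *partial* month with 1-9 consultation days
  (below every workforce threshold), i.e. they wind down and leave mid-month;
  the employment record ends on the last day of that month. Under this
  convention the probability that a current workforce member's spell ends
  within h months is exactly 1 - (1 - q)^h for monthly hazard q.
* ``temporary_share`` is the target share of temporary contracts among
  *measured* workforce member-months; because a temporary spell of mean M
  months has only M-1 full months, temporary slot counts are scaled by
  M/(M-1).
* Practice-level covariates can shift the monthly exit hazard of permanent
  and registrar staff (``covariate_effects``): tercile effects are applied
  per step relative to the middle tercile, indicator effects additively.
  These shifts are the ground truth recovered by the association analysis.
* Randomness uses one substream per (practice, purpose), spawned from the
  root seed, so adding a practice does not perturb the draws of the others.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ContractType, SimulationConfig, TEMPORARY_CONTRACTS
from .covariates import tercile_code
from .errors import ConfigurationError

__all__ = [
    "SyntheticRegistry",
    "generate_registry",
    "generate_covariate_panel",
    "expected_annual_turnover",
    "sample_practice_panel",
]

_HAZARD_FLOOR = 1e-4
_HAZARD_CEIL = 0.95


@dataclass
class SyntheticRegistry:
    """The four input tables of the analysis plus the simulation ground truth."""

    events: pd.DataFrame        # physician_id, practice_id, date, n_visits
    employment: pd.DataFrame    # physician_id, practice_id, contract, start_date, end_date
    registration: pd.DataFrame  # practice_id, month, patients
    attributes: pd.DataFrame    # practice_id, ownership, ..., open_year, close_year (+ internals)
    truth: pd.DataFrame         # per-practice hazards and coded covariates


# ---------------------------------------------------------------------------
# attribute pass


def _practice_rng(seed: int, practice_index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(practice_index), int(purpose)])


def _draw_attributes(config: SimulationConfig) -> pd.DataFrame:
    y0, y1 = config.years
    sub_names = list(config.ownership_subtype_probs)
    sub_probs = np.array([config.ownership_subtype_probs[k] for k in sub_names], dtype=float)
    sub_probs = sub_probs / sub_probs.sum()
    loc_names = list(config.location_probs)
    loc_probs = np.array([config.location_probs[k] for k in loc_names], dtype=float)
    loc_probs = loc_probs / loc_probs.sum()
    pm, ps = config.patients_per_practice
    mu_temp, active_temp = config.expected_temp_months()
    slot_adj = (mu_temp / active_temp) if active_temp > 0 else 1.0
    p_open, p_close = config.p_open_close

    rows = []
    for i in range(config.n_practices):
        rng = _practice_rng(config.seed, i, 0)
        subtype = sub_names[rng.choice(len(sub_names), p=sub_probs)]
        ownership = "public" if subtype == "public" else "private"
        location = loc_names[rng.choice(len(loc_names), p=loc_probs)]
        morbidity = max(0.05, 1.0 + rng.normal(0.0, config.morbidity_sd)) if config.morbidity_sd > 0 else 1.0
        deprivation = max(0.05, 1.0 + rng.normal(0.0, config.deprivation_sd)) if config.deprivation_sd > 0 else 1.0
        patients = max(500.0, rng.normal(pm, ps)) if ps > 0 else pm

        open_year, close_year = y0, None
        if y1 - y0 >= 2 and rng.random() < p_open:
            open_year = int(rng.integers(y0 + 1, y1))  # opens strictly inside the panel
        open_month = int(config.open_month) if config.open_month is not None else int(rng.integers(1, 13))
        if open_year == y0:
            open_month = 1
        if rng.random() < p_close and open_year + 1 <= y1 - 1:
            close_year = int(rng.integers(open_year + 1, y1))
        close_month = int(rng.integers(1, 13)) if close_year is not None else 0

        staff_scale = (patients / pm) ** 0.7 if pm > 0 else 1.0
        staff_mean = config.mean_permanent_staff * staff_scale
        if ownership == "private":
            staff_mean *= config.private_staff_factor
        n_perm = max(1, int(rng.poisson(staff_mean)))
        n_reg = int(rng.poisson(config.registrars_per_practice))
        s = config.temporary_share
        if s > 0:
            exact = s / (1.0 - s) * (n_perm + n_reg) * slot_adj
            n_temp = int(np.floor(exact)) + int(rng.random() < (exact - np.floor(exact)))
        else:
            n_temp = 0
        active_heads = n_perm + n_reg + n_temp * (active_temp / mu_temp if mu_temp > 0 else 0.0)
        workload_proxy = patients / max(active_heads, 0.5)

        rows.append({
            "practice_id": f"p{i:03d}",
            "ownership": ownership,
            "ownership_subtype": subtype,
            "location": location,
            "morbidity": morbidity,
            "deprivation": deprivation,
            "open_year": open_year,
            "close_year": close_year,
            "patients_base": patients,
            "n_permanent_slots": n_perm,
            "n_registrar_slots": n_reg,
            "n_temporary_slots": n_temp,
            "open_month": open_month,
            "close_month": close_month,
            "workload_proxy": workload_proxy,
        })
    attrs = pd.DataFrame(rows)
    attrs["close_year"] = attrs["close_year"].astype("Int64")
    return attrs


def generate_covariate_panel(config: SimulationConfig, attributes: pd.DataFrame) -> pd.DataFrame:
    """Per-practice exit hazards implied by the configured covariate effects.

    Takes the (extended) attribute table produced by the generator's first
    pass and returns the simulation ground truth: tercile codes of the drawn
    covariates, indicator flags, and the monthly exit hazards of permanent
    and registrar staff after applying ``covariate_effects``. Tercile effects
    shift the hazard per step relative to the middle tercile (so a zero-mean
    code distribution leaves the average hazard at its base value); indicator
    effects (``private``, ``town``) shift it additively.
    """
    config.validate()
    attrs = attributes.reset_index(drop=True)
    if attrs["practice_id"].duplicated().any():
        raise ConfigurationError("attributes must contain one row per practice")
    effects = dict(config.covariate_effects)
    truth = pd.DataFrame({"practice_id": attrs["practice_id"].astype(str)})
    truth["private"] = (attrs["ownership"].astype(str) == "private").astype(int)
    truth["town"] = (attrs["location"].astype(str) == "town").astype(int)

    tercile_sources = {
        "size": "patients_base",
        "morbidity": "morbidity",
        "deprivation": "deprivation",
        "workload": "workload_proxy",
    }
    shift = np.zeros(len(attrs))
    for name, col in tercile_sources.items():
        if col not in attrs.columns:
            if effects.get(name, 0.0) != 0.0:
                raise ConfigurationError(
                    f"covariate_effects[{name!r}] requires attribute column {col!r}"
                )
            codes = np.full(len(attrs), 2)
        elif int(attrs[col].notna().sum()) >= 3:
            codes = tercile_code(attrs[col]).to_numpy()
        else:  # too few practices to form terciles: everyone mid-tercile
            codes = np.full(len(attrs), 2)
        truth[f"{name}_code"] = codes
        shift += effects.get(name, 0.0) * (codes - 2)
    shift += effects.get("private", 0.0) * truth["private"].to_numpy()
    shift += effects.get("town", 0.0) * truth["town"].to_numpy()

    base_perm = config.exit_hazard_by_contract.get("permanent", 0.0)
    base_reg = config.exit_hazard_by_contract.get("registrar", base_perm)
    truth["hazard_shift"] = shift
    truth["hazard_permanent"] = np.clip(base_perm + shift, _HAZARD_FLOOR if base_perm > 0 else 0.0, _HAZARD_CEIL)
    truth["hazard_registrar"] = np.clip(base_reg + shift, _HAZARD_FLOOR if base_reg > 0 else 0.0, _HAZARD_CEIL)
    truth["expected_annual_turnover"] = [
        expected_annual_turnover(config, q) for q in truth["hazard_permanent"]
    ]
    return truth


def expected_annual_turnover(config: SimulationConfig, hazard_permanent: float) -> float:
    """Analytic 12-month turnover (percent) for a practice with the given hazard.

    Mixture of the permanent/registrar geometric survival term
    100*(1-(1-q)^12) and the temporary component, weighted by the measured
    temporary member-month share. Used as the simulation-truth reference in
    recovery tests; exact for the no-temporaries case.
    """
    q = float(hazard_permanent)
    perm = 1.0 - (1.0 - q) ** 12
    s = config.temporary_share
    if s <= 0:
        return 100.0 * perm
    mu_temp, active_temp = config.expected_temp_months()
    if active_temp <= 0:
        return 100.0 * perm
    # member-month-weighted P(spell ends within 12 months) across temp types
    num = 0.0
    den = 0.0
    for name, p in config.temp_type_probs.items():
        if name == "freelance":
            h = config.exit_hazard_by_contract["freelance"]
            mean, p_end = 1.0 / h, 1.0 - (1.0 - h) ** 12
        elif name == "fixed_term":
            mean = config.fixed_contract_mean_months
            h = 1.0 / mean
            p_end = 1.0 - (1.0 - h) ** 12  # geometric length drawn at hire is memoryless
        else:  # foundation: remaining placement is at most foundation_months - 1
            mean = float(config.foundation_months)
            p_end = 1.0 if mean - 1 <= 12 else 0.0
        w = p * max(mean - 1.0, 0.0)
        num += w * p_end
        den += w
    temp_end = num / den if den > 0 else 1.0
    return 100.0 * ((1.0 - s) * perm + s * temp_end)


# ---------------------------------------------------------------------------
# event pass


def _month_index(year: int, month: int, y0: int) -> int:
    return (year - y0) * 12 + (month - 1)


def _spell_chain(rng, contract_picker, start_m, end_m, closes_at_end):
    """Occupant sequence for one staffing slot over months [start_m, end_m].

    Yields dicts with contract, start month, last month, and whether the last
    month is a partial wind-down month. ``closes_at_end`` marks a practice
    closure: everyone active in the final month winds down mid-month.
    """
    spells = []
    s = start_m
    while s <= end_m:
        contract, dur = contract_picker(rng)
        e = s + dur - 1
        if e >= end_m:
            spells.append({
                "contract": contract, "start_m": s, "last_m": end_m,
                "partial_last": bool(closes_at_end), "ongoing": not closes_at_end,
            })
            break
        spells.append({
            "contract": contract, "start_m": s, "last_m": e,
            "partial_last": True, "ongoing": False,
        })
        s = e + 1
    return spells


def _duration(rng, hazard: float, cap: int) -> int:
    if hazard <= 0:
        return cap
    if hazard >= 1:
        return 1
    return int(rng.geometric(hazard))


def generate_registry(config: SimulationConfig) -> SyntheticRegistry:
    """Generate a full synthetic registry (events, employment, registration,
    attributes) plus the covariate ground truth. Deterministic given
    ``config`` (including its seed)."""
    config.validate()
    y0, y1 = config.years
    panel_end_m = _month_index(y1, 12, y0)
    n_months = panel_end_m + 1
    attrs = _draw_attributes(config)
    truth = generate_covariate_panel(config, attrs)
    hazards_perm = dict(zip(truth["practice_id"], truth["hazard_permanent"]))
    hazards_reg = dict(zip(truth["practice_id"], truth["hazard_registrar"]))

    mu_days, sd_days = config.consult_days_per_month
    v_lo, v_hi = config.visits_per_day_iqr
    v_mu = 0.5 * (v_lo + v_hi)
    v_sd = max((v_hi - v_lo) / 1.349, 1e-9)  # IQR of a normal = 1.349 sd
    temp_names = list(config.temp_type_probs)
    temp_probs = np.array([config.temp_type_probs[k] for k in temp_names], dtype=float)
    temp_probs = temp_probs / temp_probs.sum() if temp_probs.sum() > 0 else temp_probs
    leave_months_max = max(1, min(9, config.leave_max_days // 31))

    # precompute month structure
    month_year = np.repeat(np.arange(y0, y1 + 1), 12)
    month_no = np.tile(np.arange(1, 13), y1 - y0 + 1)
    month_days = np.array([
        calendar.monthrange(int(yy), int(mm))[1] for yy, mm in zip(month_year, month_no)
    ])
    month_start_ts = pd.to_datetime({
        "year": month_year, "month": month_no, "day": np.ones(n_months, dtype=int)
    })
    month_end_ts = month_start_ts + pd.to_timedelta(month_days - 1, unit="D")

    ev_phys, ev_prac, ev_mi, ev_day, ev_visits = [], [], [], [], []
    emp_rows = []
    reg_rows = []

    for i, prac in attrs.iterrows():
        pid = prac["practice_id"]
        rng = _practice_rng(config.seed, i, 1)
        q_perm = hazards_perm[pid]
        q_reg = hazards_reg[pid]
        start_m = _month_index(int(prac["open_year"]), int(prac["open_month"]), y0)
        if pd.notna(prac["close_year"]):
            end_m = _month_index(int(prac["close_year"]), int(prac["close_month"]), y0)
            closes = True
        else:
            end_m = panel_end_m
            closes = False
        rampup_until = start_m + config.rampup_months if start_m > 0 else start_m
        horizon = end_m - start_m + 1

        def perm_picker(rng, q=q_perm, cap=horizon):
            return ContractType.PERMANENT.value, _duration(rng, q, cap)

        def reg_picker(rng, q=q_reg, cap=horizon):
            return ContractType.REGISTRAR.value, _duration(rng, q, cap)

        def temp_picker(rng, cap=horizon):
            name = temp_names[rng.choice(len(temp_names), p=temp_probs)]
            if name == "freelance":
                dur = _duration(rng, config.exit_hazard_by_contract["freelance"], cap)
            elif name == "fixed_term":
                dur = _duration(rng, 1.0 / config.fixed_contract_mean_months, cap)
            else:
                dur = config.foundation_months
            return name, dur

        slots = (
            [perm_picker] * int(prac["n_permanent_slots"])
            + [reg_picker] * int(prac["n_registrar_slots"])
            + [temp_picker] * int(prac["n_temporary_slots"])
        )
        phys_counter = 0
        past_permanent = []  # (physician_id, exit_month) available for returns

        for picker in slots:
            for spell in _spell_chain(rng, picker, start_m, end_m, closes):
                contract = spell["contract"]
                returner = None
                if (
                    contract == ContractType.PERMANENT.value
                    and config.return_prob > 0
                    and rng.random() < config.return_prob
                ):
                    eligible = [p for p, e in past_permanent if e <= spell["start_m"] - 13]
                    if eligible:
                        returner = eligible[int(rng.integers(len(eligible)))]
                        # a rehired physician leaves the pool: no overlapping
                        # third spell in another slot
                        past_permanent = [(p, e) for p, e in past_permanent if p != returner]
                if returner is not None:
                    phys = returner
                else:
                    phys = f"{pid}_gp{phys_counter:03d}"
                    phys_counter += 1

                s_m, l_m = spell["start_m"], spell["last_m"]
                months = np.arange(s_m, l_m + 1)
                skip = np.zeros(len(months), dtype=bool)
                # within-spell leave: a consultation-free block of full months,
                # short enough that the 365-day gap rule absorbs it
                n_full = len(months) - (1 if spell["partial_last"] else 0)
                if (
                    config.leave_prob > 0
                    and n_full >= 18
                    and rng.random() < config.leave_prob
                ):
                    L = int(rng.integers(1, leave_months_max + 1))
                    lo, hi = 1, n_full - L - 1
                    if hi >= lo:
                        a = int(rng.integers(lo, hi + 1))
                        skip[a:a + L] = True

                for k, m in enumerate(months):
                    if skip[k]:
                        continue
                    dim = int(month_days[m])
                    partial = (spell["partial_last"] and m == l_m) or (m < rampup_until)
                    if partial:
                        c = int(rng.integers(1, 10))
                    else:
                        c = int(np.clip(np.rint(rng.normal(mu_days, sd_days)), 0, dim))
                    if c == 0:
                        continue
                    days = np.sort(rng.choice(dim, size=min(c, dim), replace=False)) + 1
                    visits = np.maximum(1, np.rint(rng.normal(v_mu, v_sd, size=len(days)))).astype(int)
                    ev_phys.extend([phys] * len(days))
                    ev_prac.extend([pid] * len(days))
                    ev_mi.extend([m] * len(days))
                    ev_day.extend(days.tolist())
                    ev_visits.extend(visits.tolist())

                end_date = pd.NaT if spell["ongoing"] else month_end_ts[l_m]
                emp_rows.append({
                    "physician_id": phys, "practice_id": pid, "contract": contract,
                    "start_date": month_start_ts[s_m], "end_date": end_date,
                })
                if contract == ContractType.PERMANENT.value and not spell["ongoing"]:
                    past_permanent.append((phys, l_m))

        # registration counts
        rng_reg = _practice_rng(config.seed, i, 2)
        for m in range(start_m, end_m + 1):
            noise = float(np.exp(rng_reg.normal(0.0, 0.01)))
            reg_rows.append({
                "practice_id": pid,
                "month": pd.Period(year=int(month_year[m]), month=int(month_no[m]), freq="M"),
                "patients": int(round(prac["patients_base"] * noise)),
            })

    mi = np.asarray(ev_mi, dtype=int)
    dates = (
        pd.DatetimeIndex(month_start_ts.to_numpy()[mi])
        + pd.to_timedelta(np.asarray(ev_day, dtype=int) - 1, unit="D")
        if len(mi)
        else pd.DatetimeIndex([], dtype="datetime64[ns]")
    )
    events = pd.DataFrame({
        "physician_id": ev_phys,
        "practice_id": ev_prac,
        "date": dates,
        "n_visits": ev_visits,
    }).sort_values(["practice_id", "physician_id", "date"], ignore_index=True)
    employment = pd.DataFrame(
        emp_rows,
        columns=["physician_id", "practice_id", "contract", "start_date", "end_date"],
    ).sort_values(["practice_id", "physician_id", "start_date"], ignore_index=True)
    registration = pd.DataFrame(reg_rows, columns=["practice_id", "month", "patients"])
    if len(registration):
        registration["month"] = pd.PeriodIndex(registration["month"], freq="M")
    return SyntheticRegistry(
        events=events,
        employment=employment,
        registration=registration,
        attributes=attrs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fast practice-level panel for estimator studies


def sample_practice_panel(
    n_practices: int,
    seed: int,
    coefficients: dict | None = None,
    intercept: float = 28.0,
    noise_scale: float = 6.0,
) -> tuple:
    """Draw a practice-level panel with exactly known regression coefficients.

    A lightweight stand-in for repeated full-registry simulation in estimator
    calibration studies: covariate codes are drawn independently (terciles
    uniform on {1,2,3}, location uniform over four classes, private with
    probability 0.45), and the practice-level turnover outcome is the linear
    predictor plus heteroskedastic normal noise whose scale depends on the
    workload tercile and ownership — so robust and classical standard errors
    genuinely differ.

    Returns ``(turnover, profiles, truth)`` where ``truth`` maps design-column
    names (including ``const``) to the exact generating coefficients.
    """
    rng = np.random.default_rng(seed)
    betas = {
        "size_2": -2.5, "size_3": -9.0,
        "workload_2": 5.0, "workload_3": 10.0,
        "morbidity_2": 2.0, "morbidity_3": -8.5,
        "deprivation_2": 3.0, "deprivation_3": 8.5,
        "location_commuting": 0.0, "location_town": 10.0, "location_rural": 0.5,
        "private": -6.0,
    }
    if coefficients:
        betas.update(coefficients)
    codes = {
        name: rng.integers(1, 4, size=n_practices)
        for name in ("size_code", "workload_code", "morbidity_code", "deprivation_code")
    }
    location = rng.choice(["city", "commuting", "town", "rural"], size=n_practices)
    private = (rng.random(n_practices) < 0.45).astype(int)
    lin = np.full(n_practices, float(intercept))
    for stem in ("size", "workload", "morbidity", "deprivation"):
        lin += betas[f"{stem}_2"] * (codes[f"{stem}_code"] == 2)
        lin += betas[f"{stem}_3"] * (codes[f"{stem}_code"] == 3)
    for loc in ("commuting", "town", "rural"):
        lin += betas[f"location_{loc}"] * (location == loc)
    lin += betas["private"] * private
    sigma = noise_scale * (1.0 + 0.5 * private + 0.35 * (codes["workload_code"] - 1))
    y = lin + rng.normal(0.0, 1.0, size=n_practices) * sigma

    ids = [f"p{i:03d}" for i in range(n_practices)]
    profiles = pd.DataFrame({
        "practice_id": ids,
        "size_code": codes["size_code"],
        "workload_code": codes["workload_code"],
        "morbidity_code": codes["morbidity_code"],
        "deprivation_code": codes["deprivation_code"],
        "location": location,
        "ownership": np.where(private == 1, "private", "public"),
        "private": private,
    })
    turnover = pd.DataFrame({"practice_id": ids, "rate": y, "n_years": 9})
    truth = dict(betas)
    truth["const"] = float(intercept)
    return turnover, profiles, truth
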