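"""Turnover rates at every level and horizon.

Computes the monthly 12-month turnover rate per practice, aggregates to
practice-years (imputing workforce-free years with the practice mean) and to
practice level, profiles turnover across the 6-60-month horizons
(follow-up measured through 2014 so the five-year horizon fits), and runs
the January-workforce rate for permanently employed GPs and registrars from
the employment records.
"""

from pathlib import Path

import pandas as pd

from gp_turnover import (
    HORIZONS, PanelDefinition, annual_turnover, boxplot_summary,
    impute_missing, monthly_turnover, panel_pairs, permanent_turnover,
    practice_average,
)
from gp_turnover import io as gio

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = PanelDefinition(start_year=2010, end_year=2018)

if __name__ == "__main__":
    roster = gio.read_table(ROOT / "roster_10d.csv", month_columns=["month"])
    spells = gio.read_table(ROOT / "spells.csv")
    for col in ("first_date", "last_date"):
        spells[col] = pd.to_datetime(spells[col])
    attributes = gio.read_attributes(ROOT / "registry" / "attributes.csv")
    employment = gio.read_employment(ROOT / "registry" / "employment.csv")
    data_end = pd.Timestamp(f"{PANEL.end_year + 1}-12-31")

    monthly = monthly_turnover(roster, spells, horizon_months=12, data_end=data_end)
    monthly = monthly[monthly["month"].dt.year <= PANEL.final_year].reset_index(drop=True)
    annual = annual_turnover(monthly, panel=panel_pairs(attributes, PANEL))
    observed = annual.groupby("practice_id")["rate"].transform(lambda s: s.notna().any())
    annual = annual[observed].reset_index(drop=True)
    annual = impute_missing(annual)
    practice = practice_average(annual)
    gio.write_table(monthly, ROOT / "monthly_turnover.csv")
    gio.write_table(annual, ROOT / "annual_turnover.csv")
    gio.write_table(practice, ROOT / "practice_turnover.csv")

    r = annual["rate"]
    print(f"annual turnover ({len(annual)} practice-years, "
          f"{int(annual.imputed.sum())} imputed): mean {r.mean():.0f}%, "
          f"median {r.median():.0f}%, IQR {r.quantile(0.25):.0f}-{r.quantile(0.75):.0f}%")

    rows = []
    for h in HORIZONS:
        mh = monthly_turnover(roster, spells, horizon_months=h, data_end=data_end)
        mh = mh[mh["month"].dt.year <= 2014]
        ah = annual_turnover(mh)
        summary = boxplot_summary(ah["rate"]).assign(horizon_months=h)
        rows.append(summary)
        print(f"  within {h:>2} months: median practice-year turnover "
              f"{summary.iloc[0]['median']:.0f}%")
    gio.write_table(pd.concat(rows, ignore_index=True).drop(columns="outliers"),
                    ROOT / "turnover_by_horizon.csv")

    for contract in ("permanent", "registrar"):
        table = permanent_turnover(employment, PANEL.end_year, contract=contract)
        gio.write_table(table, ROOT / f"turnover_{contract}_{PANEL.end_year}.csv")
        print(f"{contract} January-workforce turnover in {PANEL.end_year}: "
              f"mean {table['rate'].mean():.0f}% across {len(table)} practices")
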