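"""Build regular-workforce rosters and physician-practice spells.

Reads the simulated registry, applies the study-population filters
(>= 2 years of operation, closure year excluded), builds the monthly roster
at the 10-day threshold (15/20 as sensitivity), and segments consultation
histories into spells at the 365-day gap rule. Reports roster-size means and
the fraction of physicians who ever returned to a practice.
"""

from pathlib import Path

import pandas as pd

from gp_turnover import (
    PanelDefinition, apply_panel_filters, build_spells, build_workforce,
    return_fraction, workforce_sizes,
)
from gp_turnover import io as gio

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = PanelDefinition(start_year=2010, end_year=2018)

if __name__ == "__main__":
    events = gio.read_events(ROOT / "registry" / "events.csv")
    attributes = gio.read_attributes(ROOT / "registry" / "attributes.csv")
    data_end = events["date"].max()

    filtered, report = apply_panel_filters(events, attributes, PANEL)
    print(f"panel: {report['n_practices_included']}/{report['n_practices_total']} practices "
          f"({len(report['excluded_practices'])} operating <2 years), "
          f"{report['n_practice_years']} practice-years, "
          f"{report['n_closures_in_window']} closures")

    spells = build_spells(filtered, gap_days=365, data_end=data_end)
    gio.write_table(spells, ROOT / "spells.csv")
    frac = return_fraction(spells)
    print(f"spells: {len(spells):,}; {100 * frac:.1f}% of physicians ever "
          f"returned to a practice they had left")

    for min_days in (10, 15, 20):
        roster = build_workforce(filtered, min_days=min_days)
        sizes = workforce_sizes(roster)
        name = f"roster_{min_days}d.csv"
        gio.write_table(roster, ROOT / name)
        print(f"roster at >={min_days} consultation days/month: "
              f"mean size {sizes['size'].mean():.1f} "
              f"(IQR {sizes['size'].quantile(0.25):.1f}-{sizes['size'].quantile(0.75):.1f})")
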