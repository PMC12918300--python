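"""Generate the reference synthetic care registry.

An unbalanced panel of 157 primary care practices over 2010-2019: permanent,
registrar and short-contract physicians with per-contract exit hazards,
practice openings/closures with a slow staffing ramp-up, registration counts,
and practice covariates whose configured hazard effects are the ground truth
for the association analysis. Writes the four input tables plus the
simulation truth under results/registry/.
"""

from pathlib import Path

from gp_turnover import SimulationConfig, generate_registry
from gp_turnover import io as gio

OUT = Path(__file__).resolve().parent.parent / "results" / "registry"
SEED = 20100101

config = SimulationConfig(n_practices=157, years=(2010, 2019), seed=SEED,
                          return_prob=0.3)

if __name__ == "__main__":
    registry = generate_registry(config)
    OUT.mkdir(parents=True, exist_ok=True)
    gio.write_events(registry.events, OUT / "events.csv")
    gio.write_employment(registry.employment, OUT / "employment.csv")
    gio.write_registration(registry.registration, OUT / "registration.csv")
    gio.write_attributes(registry.attributes, OUT / "attributes.csv")
    gio.write_table(registry.truth, OUT / "simulation_truth.csv")

    attrs = registry.attributes
    print(f"registry: {len(registry.events):,} consultation-day records, "
          f"{registry.events.physician_id.nunique():,} physicians, "
          f"{config.n_practices} practices over {config.years[0]}-{config.years[1]}")
    print(f"  private share {(attrs.ownership == 'private').mean():.2f}, "
          f"openings {int((attrs.open_year > config.years[0]).sum())}, "
          f"closures {int(attrs.close_year.notna().sum())}")
    print(f"  daily visits IQR "
          f"{registry.events.n_visits.quantile(0.25):.0f}-"
          f"{registry.events.n_visits.quantile(0.75):.0f}")
    print(f"wrote inputs to {OUT}")
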