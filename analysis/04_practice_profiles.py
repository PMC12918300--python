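"""Tercile-coded practice covariate profiles.

Assembles size (registered patients), morbidity and deprivation scores,
ownership (with subtype), municipality class and workload (patients per
workforce physician), coding the continuous measures into terciles of the
practice-level distribution with 0 reserved for missing.
"""

from pathlib import Path

from gp_turnover import build_profiles
from gp_turnover import io as gio

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    attributes = gio.read_attributes(ROOT / "registry" / "attributes.csv")
    registration = gio.read_registration(ROOT / "registry" / "registration.csv")
    roster = gio.read_table(ROOT / "roster_10d.csv", month_columns=["month"])
    practice = gio.read_table(ROOT / "practice_turnover.csv")

    profiles, report = build_profiles(
        attributes, registration, roster,
        practices=practice["practice_id"],
    )
    gio.write_table(profiles, ROOT / "profiles.csv")
    print(f"profiles for {report['n_practices']} practices "
          f"({len(report['missing_attributes'])} missing attributes)")
    print(f"  mean registered patients {profiles.size_patients.mean():,.0f}, "
          f"mean workload {profiles.workload.mean():,.0f} patients/GP")
    print(f"  private share {profiles.private.mean():.2f}")
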