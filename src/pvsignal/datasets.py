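"""Packaged reference data for the 25 antitumor antibodies.

Two small CSVs ship with the package:

* ``antibody_ir_counts.csv`` — per-antibody infusion-reaction case counts and
  report totals from the JADER database (April 2004 – February 2022 window),
  together with the published ROR, 95% CI and signal flag for each drug.
  The corresponding universe totals are 97,567 intravenous-biologic cases of
  which 1,762 reported an infusion reaction.
* ``antibody_attributes.csv`` — curated attributes per antibody: ADCC
  activity (determined from package inserts and published articles),
  antibody type (mouse / chimeric / humanized / fully human) and molecular
  target.  Curation is data, not computation: it is shipped, not derived.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import DisproportionalityModel

__all__ = [
    "REFERENCE_N_TOTAL",
    "REFERENCE_N_EVENT",
    "EVENT_PT_CODES",
    "load_antibody_counts",
    "load_antibody_attributes",
    "reference_model",
]

#: intravenous-biologic analysis universe: total cases and infusion-reaction cases
REFERENCE_N_TOTAL = 97_567
REFERENCE_N_EVENT = 1_762

#: MedDRA Preferred Terms defining an infusion reaction:
#: infusion-related reaction and cytokine release syndrome
EVENT_PT_CODES = ("10051792", "10052015")


def _read(name: str) -> pd.DataFrame:
    with resources.files("pvsignal.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_antibody_counts() -> pd.DataFrame:
    """Per-antibody IR counts, report totals and published ROR/CI/signal."""
    return _read("antibody_ir_counts.csv")


def load_antibody_attributes() -> pd.DataFrame:
    """Curated ADCC status, antibody type and target per antibody."""
    return _read("antibody_attributes.csv")


def reference_model() -> DisproportionalityModel:
    """The 25-antibody screen built from the packaged counts and totals."""
    counts = load_antibody_counts().rename(columns={"ir_cases": "event_cases"})
    return DisproportionalityModel.from_counts(
        counts[["drug_name", "event_cases", "report_total"]],
        n_total=REFERENCE_N_TOTAL,
        n_event=REFERENCE_N_EVENT,
        attributes=load_antibody_attributes(),
    )
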