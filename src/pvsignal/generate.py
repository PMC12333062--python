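"""Synthetic spontaneous-report database with planted disproportionality.

Emulates a case-keyed report database in the four-table JADER layout so the
whole pipeline is testable without the real download.  Effects are planted on
the odds scale: a case whose suspected drug carries multiplier ``r`` has
target-event probability ``r*q / (1 - q + r*q)`` where ``q`` is the
background event rate, so the population reporting odds ratio of that drug
against the background pool equals ``r`` and the ROR estimator is the
natural parameter of the simulation.

Each synthetic case carries exactly one suspected drug by default (pooled
group counts are then sums of per-drug counts, matching the additive
construction used in the stratified analysis); ``multi_drug_prob`` adds a
second suspected background mention to a fraction of cases.  A single seed
drives everything through per-table child streams, so output is
byte-identical for identical configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ingest import ReportTables

__all__ = [
    "DrugProfile",
    "GeneratorConfig",
    "generate_database",
    "write_tables",
    "load_config",
    "load_config_dict",
]

#: default target-event Preferred Terms: infusion-related reaction and
#: cytokine release syndrome
DEFAULT_EVENT_PTS: dict[str, str] = {
    "10051792": "Infusion related reaction",
    "10052015": "Cytokine release syndrome",
}

#: non-target decoy PTs drawn for every case so reaction tables are never
#: degenerate on the target event
DEFAULT_DECOY_PTS: dict[str, str] = {
    "10037660": "Pyrexia",
    "10028813": "Nausea",
    "10019211": "Headache",
    "10012735": "Diarrhoea",
    "10037844": "Rash",
    "10016256": "Fatigue",
}

_BACKGROUND_DRUG = "background biologic"


@dataclass(frozen=True)
class DrugProfile:
    """One simulated drug: share of cases, planted odds multiplier, route,
    and the fraction of its mentions downgraded from suspected to
    concomitant (role noise)."""

    name: str
    share: float
    planted_ror: float = 1.0
    route: str = "intravenous"
    role_noise: float = 0.0


@dataclass
class GeneratorConfig:
    n_cases: int = 10_000
    background_event_rate: float = 0.02
    drug_profiles: Sequence[DrugProfile] = field(default_factory=tuple)
    event_pt_codes: Sequence[str] = tuple(DEFAULT_EVENT_PTS)
    decoy_pt_codes: Sequence[str] = tuple(DEFAULT_DECOY_PTS)
    multi_drug_prob: float = 0.0
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0.0 < self.background_event_rate < 1.0:
            raise ValueError("background_event_rate must lie in (0, 1)")
        total_share = 0.0
        for p in self.drug_profiles:
            if p.planted_ror <= 0:
                raise ValueError(f"planted_ror must be > 0 for drug {p.name!r}")
            if not 0.0 <= p.share <= 1.0:
                raise ValueError(f"share must lie in [0, 1] for drug {p.name!r}")
            if not 0.0 <= p.role_noise <= 1.0:
                raise ValueError(f"role_noise must lie in [0, 1] for drug {p.name!r}")
            total_share += p.share
        if total_share > 1.0 + 1e-12:
            raise ValueError("drug shares must sum to <= 1")
        if not self.event_pt_codes:
            raise ValueError("event_pt_codes must be nonempty")
        return self


def _event_probability(planted_ror: float, q: float) -> float:
    # odds multiplication: odds -> r * q/(1-q), back to probability
    return planted_ror * q / (1.0 - q + planted_ror * q)


def generate_database(config: GeneratorConfig) -> ReportTables:
    """Draw a complete four-table synthetic database.

    Every case identifier appears exactly once in demographics and carries at
    least one drug mention and at least one reaction row (a decoy PT, plus a
    target PT for event cases).
    """
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_case, rng_demo, rng_reac, rng_hist = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    n = cfg.n_cases
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    profiles = list(cfg.drug_profiles)
    names = [p.name for p in profiles] + [_BACKGROUND_DRUG]
    shares = np.array([p.share for p in profiles] + [0.0])
    shares[-1] = max(0.0, 1.0 - shares[:-1].sum())
    shares = shares / shares.sum()
    assigned = rng_case.choice(len(names), size=n, p=shares)

    q = cfg.background_event_rate
    p_event = np.array(
        [_event_probability(p.planted_ror, q) for p in profiles] + [q]
    )[assigned]
    has_event = rng_case.random(n) < p_event

    routes = np.array([p.route for p in profiles] + ["intravenous"])[assigned]
    role_noise = np.array([p.role_noise for p in profiles] + [0.0])[assigned]
    roles = np.where(rng_case.random(n) < role_noise, "concomitant", "suspected")

    drug_rows = {
        "case_id": case_ids,
        "drug_name": np.array(names, dtype=object)[assigned],
        "role": roles,
        "route": routes,
    }
    drugs = pd.DataFrame(drug_rows)
    if cfg.multi_drug_prob > 0:
        extra = rng_case.random(n) < cfg.multi_drug_prob
        drugs = pd.concat(
            [
                drugs,
                pd.DataFrame(
                    {
                        "case_id": case_ids[extra],
                        "drug_name": _BACKGROUND_DRUG,
                        "role": "suspected",
                        "route": "intravenous",
                    }
                ),
            ],
            ignore_index=True,
        )
        drugs = drugs.drop_duplicates().sort_values(["case_id", "drug_name"]).reset_index(drop=True)

    demographics = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": rng_demo.choice(["male", "female"], size=n),
            "age": rng_demo.choice(["40s", "50s", "60s", "70s", "80s"], size=n),
            "weight": rng_demo.choice(["40-50kg", "50-60kg", "60-70kg"], size=n),
        }
    )

    pt_names = {**DEFAULT_EVENT_PTS, **DEFAULT_DECOY_PTS}
    decoys = np.asarray(list(cfg.decoy_pt_codes), dtype=object)
    reac_frames = [
        pd.DataFrame(
            {
                "case_id": case_ids,
                "pt_code": rng_reac.choice(decoys, size=n),
                "outcome": rng_reac.choice(["recovered", "recovering", "unknown"], size=n),
            }
        )
    ]
    ev_ids = case_ids[has_event]
    if len(ev_ids):
        codes = np.asarray(list(cfg.event_pt_codes), dtype=object)
        reac_frames.append(
            pd.DataFrame(
                {
                    "case_id": ev_ids,
                    "pt_code": rng_reac.choice(codes, size=len(ev_ids)),
                    "outcome": rng_reac.choice(
                        ["recovered", "recovering", "unknown"], size=len(ev_ids)
                    ),
                }
            )
        )
    reactions = pd.concat(reac_frames, ignore_index=True)
    reactions["pt_name"] = reactions["pt_code"].map(lambda c: pt_names.get(c, f"PT {c}"))
    reactions = (
        reactions[["case_id", "pt_code", "pt_name", "outcome"]]
        .sort_values(["case_id", "pt_code"])
        .reset_index(drop=True)
    )

    with_hist = rng_hist.random(n) < 0.3
    history = pd.DataFrame(
        {
            "case_id": case_ids[with_hist],
            "disease": rng_hist.choice(
                ["hypertension", "diabetes mellitus", "none reported"],
                size=int(with_hist.sum()),
            ),
        }
    )

    return ReportTables(demographics, drugs, reactions, history)


def write_tables(tables: ReportTables, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables as UTF-8 CSVs with header rows; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ReportTables._fields:
        path = outdir / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        paths[name] = path
    return paths


def load_config(path: str | Path, seed: int | None = None) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML file.

    Expected keys mirror the dataclass fields; drug profiles live under
    ``drugs`` as a list of mappings.  ``seed`` overrides the file's seed.
    """
    raw = yaml.safe_load(Path(path).read_text())
    return load_config_dict(raw.get("simulate", raw), seed=seed)


def load_config_dict(sim: dict, seed: int | None = None) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from an already-parsed mapping."""
    profiles = tuple(DrugProfile(**d) for d in sim.get("drugs", []))
    cfg = GeneratorConfig(
        n_cases=int(sim.get("n_cases", 10_000)),
        background_event_rate=float(sim.get("background_event_rate", 0.02)),
        drug_profiles=profiles,
        event_pt_codes=tuple(str(c) for c in sim.get("event_pt_codes", DEFAULT_EVENT_PTS)),
        decoy_pt_codes=tuple(str(c) for c in sim.get("decoy_pt_codes", DEFAULT_DECOY_PTS)),
        multi_drug_prob=float(sim.get("multi_drug_prob", 0.0)),
        seed=int(sim.get("seed", 0) if seed is None else seed),
    )
    return cfg.validate()
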