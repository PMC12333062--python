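"""Reading and integrating case-keyed spontaneous-report tables.

The expected layout mirrors the JADER distribution: four CSV tables linked by
a case identifier — patient demographics, drug mentions (with an involvement
role and an administration route), adverse events coded as MedDRA Preferred
Terms, and medical history.  ``build_universe`` applies the study inclusion
rules (suspected-role, intravenous-route mentions only) and flags each case
for the target event, producing the analysis universe that all
disproportionality statistics are computed against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

__all__ = [
    "ReportTables",
    "AnalysisUniverse",
    "DEFAULT_SCHEMA",
    "ROLES",
    "ROUTES",
    "read_tables",
    "build_universe",
    "normalize_drug_name",
]

logger = logging.getLogger(__name__)

#: canonical table name -> required columns (after schema renaming)
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "demographics": ("case_id", "sex", "age", "weight"),
    "drugs": ("case_id", "drug_name", "role", "route"),
    "reactions": ("case_id", "pt_code", "pt_name", "outcome"),
    "history": ("case_id", "disease"),
}

ROLES = frozenset({"suspected", "concomitant", "interaction"})
ROUTES = frozenset({"intravenous", "oral", "other/unknown"})


class ReportTables(NamedTuple):
    """The four linked raw tables of a spontaneous-report database."""

    demographics: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    history: pd.DataFrame


@dataclass
class AnalysisUniverse:
    """Filtered case universe for disproportionality analysis.

    ``case_drug`` holds one row per retained (case_id, drug_name) pair after
    role/route filtering and deduplication; ``event_cases`` is the set of
    case identifiers with the target event among retained cases.
    """

    case_drug: pd.DataFrame
    event_cases: frozenset[str]
    n_total: int
    n_event: int
    event_pt_codes: tuple[str, ...] = field(default_factory=tuple)

    def drug_counts(self) -> pd.DataFrame:
        """Per-drug case counts: total reports and event-positive reports."""
        if self.case_drug.empty:
            return pd.DataFrame(columns=["drug_name", "event_cases", "report_total"])
        df = self.case_drug.copy()
        df["is_event"] = df["case_id"].isin(self.event_cases)
        out = (
            df.groupby("drug_name", sort=True)
            .agg(event_cases=("is_event", "sum"), report_total=("case_id", "size"))
            .reset_index()
        )
        out["event_cases"] = out["event_cases"].astype(int)
        return out


def normalize_drug_name(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Trim, collapse internal whitespace and case-fold; then apply an
    optional user-supplied synonym map (keys compared after normalization)."""
    key = " ".join(str(name).split()).casefold()
    if synonyms:
        norm_syn = {" ".join(k.split()).casefold(): v for k, v in synonyms.items()}
        return norm_syn.get(key, key)
    return key


def read_tables(
    paths: Mapping[str, str | Path],
    schema: Mapping[str, Mapping[str, str]] | None = None,
    encoding: str = "utf-8",
) -> ReportTables:
    """Read the four report tables from CSV.

    Parameters
    ----------
    paths
        Mapping of table name (``demographics``, ``drugs``, ``reactions``,
        ``history``) to a CSV path.
    schema
        Optional per-table mapping from the file's column names to the
        canonical names of :data:`DEFAULT_SCHEMA` (real JADER ships Japanese
        headers; synthetic output needs none).
    encoding
        Text encoding; the real JADER distribution is Shift-JIS
        (``encoding="cp932"``), the packaged synthetic output is UTF-8.

    Raises
    ------
    ValueError
        If a required table or column is missing, naming the file and column.
    UnicodeDecodeError-wrapping ValueError
        If the file cannot be decoded, naming the encoding tried.
    """
    frames: dict[str, pd.DataFrame] = {}
    for table, required in DEFAULT_SCHEMA.items():
        if table not in paths:
            raise ValueError(f"missing path for table {table!r}")
        path = Path(paths[table])
        try:
            df = pd.read_csv(path, dtype=str, encoding=encoding, keep_default_na=False)
        except UnicodeDecodeError as err:
            raise ValueError(
                f"could not decode {path} with encoding {encoding!r}: {err}"
            ) from err
        if schema and table in schema:
            df = df.rename(columns=dict(schema[table]))
        for col in required:
            if col not in df.columns:
                raise ValueError(f"table {path} is missing required column {col!r}")
        frames[table] = df[list(required)]
        logger.info("read %s: %d rows from %s", table, len(df), path)
    return ReportTables(**frames)


def _map_vocab(series: pd.Series, vocab: frozenset[str], label: str) -> pd.Series:
    """Lower-case and validate a closed-vocabulary column; unknown values are
    mapped to 'other/unknown' with a warning (they then fail every filter)."""
    cleaned = series.str.strip().str.lower()
    unknown = sorted(set(cleaned[~cleaned.isin(vocab)]))
    if unknown:
        logger.warning("unknown %s values mapped to 'other/unknown': %s", label, unknown)
        cleaned = cleaned.where(cleaned.isin(vocab), "other/unknown")
    return cleaned


def build_universe(
    tables: ReportTables,
    event_pt_codes: Iterable[str],
    role_filter: Iterable[str] = ("suspected",),
    route_filter: Iterable[str] = ("intravenous",),
    synonyms: Mapping[str, str] | None = None,
) -> AnalysisUniverse:
    """Apply the inclusion rules and build the analysis universe.

    A case enters the universe iff it carries at least one drug mention
    passing both the role filter (default: suspected only) and the route
    filter (default: intravenous only).  Its event flag is true iff any of
    its reaction rows carries a target PT code; a case with several target
    PTs counts once.  Duplicate (case, drug) pairs are deduplicated so each
    case contributes at most once to any drug's count.
    """
    event_pt_codes = tuple(str(c) for c in event_pt_codes)
    if not event_pt_codes:
        raise ValueError("event_pt_codes must be nonempty")
    roles = {r.lower() for r in role_filter}
    routes = {r.lower() for r in route_filter}

    drugs = tables.drugs.copy()
    drugs["role"] = _map_vocab(drugs["role"], ROLES, "role")
    drugs["route"] = _map_vocab(drugs["route"], ROUTES, "route")
    drugs["drug_name"] = drugs["drug_name"].map(
        lambda s: normalize_drug_name(s, synonyms)
    )

    kept = drugs[drugs["role"].isin(roles) & drugs["route"].isin(routes)]
    case_drug = (
        kept[["case_id", "drug_name"]]
        .drop_duplicates()
        .sort_values(["case_id", "drug_name"])
        .reset_index(drop=True)
    )
    universe_cases = set(case_drug["case_id"])
    if not universe_cases:
        logger.warning("filters produced an empty analysis universe")

    reac = tables.reactions
    hit = reac[reac["pt_code"].astype(str).isin(event_pt_codes)]
    event_cases = frozenset(set(hit["case_id"]) & universe_cases)

    logger.info(
        "universe: %d cases (%d event-positive) from %d drug mentions",
        len(universe_cases), len(event_cases), len(tables.drugs),
    )
    return AnalysisUniverse(
        case_drug=case_drug,
        event_cases=event_cases,
        n_total=len(universe_cases),
        n_event=len(event_cases),
        event_pt_codes=event_pt_codes,
    )
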