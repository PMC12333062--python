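"""Model/Results interface for the disproportionality screen.

``DisproportionalityModel`` holds the analysis universe in reduced form —
per-drug event and report counts plus the universe totals — together with an
optional curated attribute map.  ``fit()`` computes, for every drug, the 2x2
contingency table against the rest of the universe, the reporting odds ratio
with its Woolf 95% CI, the two-sided Fisher exact p (log-space), the
Benjamini–Hochberg adjusted p across the per-drug family, and the signal
flag (CI lower bound > 1 and at least two event cases).  The returned
``DisproportionalityResults`` exposes the tidy per-drug frame, a text
summary, pooled group RORs, signal-detection tables with exact tests, and
volcano-plot coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import stats, stratify
from .ingest import AnalysisUniverse, normalize_drug_name
from .stats import ContingencyTable2x2

__all__ = ["DisproportionalityModel", "DisproportionalityResults", "VolcanoPoint"]


class DisproportionalityModel:
    """Per-drug disproportionality screen of one adverse event.

    Parameters
    ----------
    counts
        Per-drug frame with columns ``drug_name``, ``event_cases`` (cases
        reporting both the drug and the target event) and ``report_total``
        (cases reporting the drug at all).
    n_total, n_event
        Size of the analysis universe and its event-positive subset; the
        comparator for every drug is the rest of this universe.
    attributes
        Optional curated map with ``drug_name`` plus attribute columns
        (e.g. ``adcc_status``, ``antibody_type``).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        n_total: int,
        n_event: int,
        attributes: pd.DataFrame | None = None,
    ):
        required = {"drug_name", "event_cases", "report_total"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"counts is missing columns {sorted(missing)}")
        if n_event > n_total:
            raise ValueError("n_event cannot exceed n_total")
        counts = counts.loc[:, ["drug_name", "event_cases", "report_total"]].copy()
        bad = counts[counts["event_cases"] > counts["report_total"]]
        if not bad.empty:
            raise ValueError(
                f"event_cases exceeds report_total for {bad['drug_name'].tolist()}"
            )
        self.counts = counts.reset_index(drop=True)
        self.n_total = int(n_total)
        self.n_event = int(n_event)
        self.attributes = attributes

    # ------------------------------------------------------------------ #
    @classmethod
    def from_universe(
        cls, universe: AnalysisUniverse, attributes: pd.DataFrame | None = None
    ) -> "DisproportionalityModel":
        """Reduce an ingested case universe to per-drug counts."""
        return cls(
            universe.drug_counts(),
            n_total=universe.n_total,
            n_event=universe.n_event,
            attributes=attributes,
        )

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        n_total: int,
        n_event: int,
        attributes: pd.DataFrame | None = None,
    ) -> "DisproportionalityModel":
        """Build directly from published per-drug counts and universe totals."""
        return cls(counts, n_total, n_event, attributes)

    # ------------------------------------------------------------------ #
    def contingency(self, drug: str) -> ContingencyTable2x2:
        """2x2 table for one drug against the rest of the universe.

        An absent drug yields the degenerate (0, 0, n_event, n_total-n_event)
        table.
        """
        key = normalize_drug_name(drug)
        row = self.counts[self.counts["drug_name"].map(normalize_drug_name) == key]
        if row.empty:
            a, n = 0, 0
        else:
            a = int(row["event_cases"].sum())
            n = int(row["report_total"].sum())
        c = self.n_event - a
        return ContingencyTable2x2(a, n - a, c, self.n_total - n - c).validate()

    def fit(
        self,
        confidence: float = 0.95,
        min_cases: int = 2,
        continuity: bool = False,
    ) -> "DisproportionalityResults":
        """Run the screen over every drug in the counts table."""
        rows = []
        for rec in self.counts.itertuples(index=False):
            t = ContingencyTable2x2(
                int(rec.event_cases),
                int(rec.report_total - rec.event_cases),
                self.n_event - int(rec.event_cases),
                self.n_total - int(rec.report_total) - (self.n_event - int(rec.event_cases)),
            ).validate()
            est = stats.ror_with_ci(t, confidence=confidence, continuity=continuity)
            fisher = stats.fisher_exact_2x2(t)
            rows.append(
                {
                    "drug_name": rec.drug_name,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "ror": est.ror,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "ror_defined": est.defined,
                    "p_value": fisher.p_value,
                    "log10_p": fisher.log10_p,
                    "signal": stats.signal_flag(t, est, min_cases=min_cases),
                }
            )
        columns = [
            "drug_name", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
            "ror_defined", "p_value", "log10_p", "signal",
        ]
        frame = pd.DataFrame(rows, columns=columns)
        if not frame.empty:
            # underflowed p-values enter the BH family at the smallest
            # positive double; their adjusted values stay indistinguishable
            frame["p_adjusted"] = stats.bh_adjust(
                frame["p_value"].clip(lower=np.nextafter(0, 1))
            )
        else:
            frame["p_adjusted"] = pd.Series(dtype=float)
        return DisproportionalityResults(model=self, frame=frame,
                                         confidence=confidence, min_cases=min_cases)


@dataclass(frozen=True)
class VolcanoPoint:
    """One drug's volcano-plot coordinates: x = ln ROR, y = -log10 p."""

    drug_name: str
    x: float
    y: float
    excluded: bool = False
    reason: str = ""


@dataclass
class DisproportionalityResults:
    """Fitted per-drug disproportionality results.

    ``frame`` holds one row per drug: the 2x2 cells, ROR with CI, exact p
    (plus its log10, which survives underflow), BH-adjusted p, and the
    signal flag.
    """

    model: DisproportionalityModel
    frame: pd.DataFrame
    confidence: float = 0.95
    min_cases: int = 2

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        """Human-readable per-drug table, RORs/CIs at 2 dp and p at 4 dp."""
        lines = [
            "Disproportionality screen (reporting odds ratio)",
            f"Universe: {self.model.n_total} cases, {self.model.n_event} with the target event",
            f"Signal rule: {int(self.confidence * 100)}% CI lower bound > 1 "
            f"and >= {self.min_cases} cases",
            "",
            f"{'drug':<24}{'events':>7}{'reports':>9}{'ROR':>8}"
            f"{'95% CI':>16}{'p':>9}{'p(BH)':>9}  signal",
        ]
        for r in self.frame.itertuples(index=False):
            if r.ror_defined:
                ror = f"{r.ror:.2f}"
                ci = f"[{r.ci_low:.2f}, {r.ci_high:.2f}]"
            else:
                ror, ci = "undef", "-"
            lines.append(
                f"{r.drug_name:<24}{r.a:>7}{r.a + r.b:>9}{ror:>8}"
                f"{ci:>16}{_fmt_p(r.p_value):>9}{_fmt_p(r.p_adjusted):>9}"
                f"  {'*' if r.signal else ''}"
            )
        return "\n".join(lines)

    @property
    def n_signals(self) -> int:
        return int(self.frame["signal"].sum())

    # ------------------------------------------------------------------ #
    def pooled(self, drug_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
        """Pooled group RORs: counts summed over member drugs, each group
        compared against the rest of the universe."""
        rows = []
        for label, drugs in drug_sets.items():
            t = stratify.pooled_contingency(
                self.model.counts, drugs, self.model.n_total, self.model.n_event
            )
            est = stats.ror_with_ci(t, confidence=self.confidence)
            fisher = stats.fisher_exact_2x2(t)
            rows.append(
                {
                    "group": label,
                    "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                    "ror": est.ror, "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "p_value": fisher.p_value, "log10_p": fisher.log10_p,
                    "signal": stats.signal_flag(t, est, min_cases=self.min_cases),
                }
            )
        return pd.DataFrame(rows)

    def pooled_by(self, attribute: str) -> pd.DataFrame:
        """Pooled RORs for the groups defined by one attribute column."""
        attrs = self._require_attributes()
        groups = {
            str(level): attrs.loc[attrs[attribute] == level, "drug_name"].tolist()
            for level in stratify.ATTRIBUTE_ORDERS.get(
                attribute, pd.unique(attrs[attribute])
            )
        }
        groups = {k: v for k, v in groups.items() if v}
        return self.pooled(groups)

    def detection_table(self, attribute: str) -> pd.DataFrame:
        """Signal-detected / not-detected counts per attribute level."""
        return stratify.detection_table(self.frame, self._require_attributes(), attribute)

    def compare_detection(self, attribute: str) -> tuple[pd.DataFrame, float]:
        """Detection table plus the exact test of independence on it."""
        tab = self.detection_table(attribute)
        return tab, stratify.fisher_exact_2xk(tab)

    def _require_attributes(self) -> pd.DataFrame:
        if self.model.attributes is None:
            raise ValueError("model was built without an attribute map")
        return self.model.attributes

    # ------------------------------------------------------------------ #
    def volcano_points(self, p_floor: float = 1e-300) -> list[VolcanoPoint]:
        """Volcano coordinates (x = ln ROR, y = -log10 p) for every drug.

        Drugs with an undefined ROR, or whose p-value falls below
        ``p_floor`` (evaluated on the log scale, so underflow to 0.0 is
        detected exactly), are flagged excluded with a reason instead of
        being placed at infinity.
        """
        log10_floor = math.log10(p_floor)
        pts = []
        for r in self.frame.itertuples(index=False):
            if not r.ror_defined:
                pts.append(VolcanoPoint(r.drug_name, math.nan, math.nan,
                                        excluded=True, reason="undefined ROR (zero cell)"))
            elif r.log10_p < log10_floor:
                pts.append(VolcanoPoint(r.drug_name, math.log(r.ror), -r.log10_p,
                                        excluded=True, reason="p underflow"))
            else:
                pts.append(VolcanoPoint(r.drug_name, math.log(r.ror), -r.log10_p))
        return pts

    def volcano_frame(self, p_floor: float = 1e-300) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.volcano_points(p_floor)]).rename(
            columns={"x": "log_ror", "y": "neg_log10_p"}
        )

    def plot_volcano(self, ax=None, p_floor: float = 1e-300, annotate: bool = True):
        """Scatter of ln ROR against -log10 p; excluded drugs are omitted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        pts = [p for p in self.volcano_points(p_floor) if not p.excluded]
        ax.scatter([p.x for p in pts], [p.y for p in pts], s=18)
        if annotate:
            for p in pts:
                ax.annotate(p.drug_name, (p.x, p.y), fontsize=6,
                            xytext=(2, 2), textcoords="offset points")
        ax.axvline(0.0, color="grey", lw=0.6)
        ax.set_xlabel("ln ROR")
        ax.set_ylabel("-log10 p")
        return ax

    # ------------------------------------------------------------------ #
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_total": self.model.n_total,
            "n_event": self.model.n_event,
            "confidence": self.confidence,
            "min_cases": self.min_cases,
            "drugs": json.loads(self.frame.to_json(orient="records")),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "-"
    return f"{p:.4f}" if p >= 5e-5 else f"{p:.1e}"
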