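"""Stratified signal-detection comparisons across curated drug attributes.

Drugs are grouped by curated attributes (ADCC activity: positive/negative;
antibody type: mouse/chimeric/humanized/fully human).  Two comparisons are
supported: pooled group RORs, where the group's event and report counts are
the sums of the member drugs' per-drug counts, and detection tables crossing
the per-drug signal flag with the attribute, tested with an exact test
(Fisher for 2x2, the Freeman–Halton extension for 2xK).
"""

from __future__ import annotations

import itertools
import math
from math import lgamma
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, _REL_TOL

__all__ = [
    "ATTRIBUTE_ORDERS",
    "EnumerationLimitExceeded",
    "pooled_counts",
    "pooled_contingency",
    "detection_table",
    "fisher_exact_2xk",
]

#: canonical column orders for the known attributes
ATTRIBUTE_ORDERS: dict[str, tuple[str, ...]] = {
    "adcc_status": ("positive", "negative"),
    "antibody_type": ("mouse", "chimeric", "humanized", "fully_human"),
}


class EnumerationLimitExceeded(RuntimeError):
    """Raised when a 2xK exact test would exceed the enumeration cap; the
    p-value is explicitly not computed rather than silently approximated."""


def pooled_counts(counts: pd.DataFrame, drug_set: Iterable[str]) -> tuple[int, int]:
    """Sum event and report counts over the member drugs of a group.

    A case suspected of two member drugs contributes once per drug — the
    additive construction under which pooled group counts equal the sums of
    the per-drug table rows.
    """
    drug_set = set(drug_set)
    if not drug_set:
        raise ValueError("drug_set must be nonempty")
    sub = counts[counts["drug_name"].isin(drug_set)]
    return int(sub["event_cases"].sum()), int(sub["report_total"].sum())


def pooled_contingency(
    counts: pd.DataFrame, drug_set: Iterable[str], n_total: int, n_event: int
) -> ContingencyTable2x2:
    """2x2 table for a drug group against the rest of the universe."""
    a, n = pooled_counts(counts, drug_set)
    c = n_event - a
    return ContingencyTable2x2(a, n - a, c, n_total - n - c).validate()


def detection_table(
    results: pd.DataFrame,
    attributes: pd.DataFrame,
    attribute: str,
) -> pd.DataFrame:
    """Cross-tabulate the per-drug signal flag against an attribute.

    Returns a 2xK frame with rows ``detected`` / ``not_detected`` and one
    column per attribute level (canonical order for known attributes,
    appearance order otherwise).  Raises ``KeyError`` naming any drug in
    ``results`` absent from the attribute map.
    """
    if results.empty:
        return pd.DataFrame(index=["detected", "not_detected"])
    attr = attributes.set_index(attributes["drug_name"].str.casefold())[attribute]
    keys = results["drug_name"].str.casefold()
    missing = sorted(set(keys) - set(attr.index))
    if missing:
        raise KeyError(f"drugs missing from attribute map: {missing}")
    levels = list(
        ATTRIBUTE_ORDERS.get(attribute)
        or pd.unique(attributes[attribute])
    )
    tab = pd.DataFrame(0, index=["detected", "not_detected"], columns=levels)
    for flag, level in zip(results["signal"], attr.loc[keys].to_numpy()):
        tab.loc["detected" if flag else "not_detected", level] += 1
    return tab


def fisher_exact_2xk(
    table: pd.DataFrame | Sequence[Sequence[int]],
    max_tables: int = 5_000_000,
) -> float:
    """Exact test of independence for a 2xK table (Freeman–Halton).

    Enumerates every 2xK table with the observed margins and sums the point
    probabilities not exceeding the observed table's (small-p-values rule,
    1e-7 relative tolerance).  For K = 2 this is exactly the two-sided
    Fisher test.  Tables whose margin structure admits more than
    ``max_tables`` candidate tables raise :class:`EnumerationLimitExceeded`.
    """
    arr = np.asarray(table, dtype=object)
    arr = np.array([[int(v) for v in row] for row in arr])
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("expected a 2xK table with K >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    row1 = int(arr[0].sum())
    col = arr.sum(axis=0).astype(int)
    n = int(arr.sum())
    if n == 0 or row1 == 0 or row1 == n:
        return 1.0

    n_candidates = math.prod(int(m) + 1 for m in col)
    if n_candidates > max_tables:
        raise EnumerationLimitExceeded(
            f"margins admit up to {n_candidates} tables (cap {max_tables}); "
            "exact p not computed"
        )

    log_const = (
        lgamma(row1 + 1)
        + lgamma(n - row1 + 1)
        + sum(lgamma(m + 1) for m in col)
        - lgamma(n + 1)
    )

    def log_prob(top: Sequence[int]) -> float:
        return log_const - sum(
            lgamma(x + 1) + lgamma(m - x + 1) for x, m in zip(top, col)
        )

    log_obs = log_prob(arr[0])
    acc = []
    for top in itertools.product(*(range(m + 1) for m in col)):
        if sum(top) != row1:
            continue
        lp = log_prob(top)
        if lp <= log_obs + _REL_TOL:
            acc.append(lp)
    m = max(acc)
    return float(min(math.exp(m) * sum(math.exp(v - m) for v in acc), 1.0))
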