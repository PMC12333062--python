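"""Disproportionality statistics for 2x2 spontaneous-report contingency tables.

The unit of analysis is the case (report).  For one drug against the rest of
the analysis universe the table is::

                    event present   event absent
    target drug          a               b
    all other drugs      c               d

The reporting odds ratio (ROR) is ``(a/b) / (c/d) = ad/bc`` with a Woolf
log-normal confidence interval ``exp(ln ROR +/- z * sqrt(1/a+1/b+1/c+1/d))``.
A drug is flagged as a signal when the CI lower bound exceeds 1 strictly and
at least two event cases were reported.

The two-sided Fisher exact test is evaluated in log space so that p-values
far below double-precision underflow (common at database scale, e.g. a drug
with hundreds of event cases) remain usable on the -log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "RorEstimate",
    "FisherResult",
    "ror_with_ci",
    "signal_flag",
    "fisher_exact_2x2",
    "bh_adjust",
]

# Relative tolerance when comparing point probabilities to the observed
# table's probability (same convention as R's fisher.test).
_REL_TOL = 1e-7


class ContingencyTable2x2(NamedTuple):
    """Counts (a, b, c, d): drug/event, drug/no-event, other/event, other/no-event."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    def validate(self) -> "ContingencyTable2x2":
        for name, v in zip("abcd", self):
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        return ContingencyTable2x2(*(int(v) for v in self))


@dataclass(frozen=True)
class RorEstimate:
    """Point estimate and CI for a reporting odds ratio.

    ``defined`` is False when any cell of the table is zero (the estimate is
    reported as undefined rather than silently corrected; pass
    ``continuity=True`` to ``ror_with_ci`` for the Haldane–Anscombe +0.5
    fallback).
    """

    ror: float
    ci_low: float
    ci_high: float
    defined: bool = True


class FisherResult(NamedTuple):
    """Two-sided exact-test result; ``log10_p`` stays finite when ``p_value`` underflows."""

    p_value: float
    log10_p: float


def ror_with_ci(
    table: ContingencyTable2x2 | Sequence[int],
    confidence: float = 0.95,
    continuity: bool = False,
) -> RorEstimate:
    """Reporting odds ratio with a Woolf log-normal confidence interval.

    Parameters
    ----------
    table
        The (a, b, c, d) contingency counts.
    confidence
        CI level; 0.95 gives z = 1.959964.
    continuity
        Apply the Haldane–Anscombe +0.5 correction to every cell when any
        cell is zero.  Off by default: zero cells yield an undefined estimate.
    """
    t = ContingencyTable2x2(*table).validate()
    a, b, c, d = (float(v) for v in t)
    if min(a, b, c, d) == 0:
        if not continuity:
            return RorEstimate(math.nan, math.nan, math.nan, defined=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = norm.ppf(0.5 + confidence / 2.0)
    log_ror = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(
        ror=math.exp(log_ror),
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        defined=True,
    )


def signal_flag(table: ContingencyTable2x2 | Sequence[int], estimate: RorEstimate,
                min_cases: int = 2) -> bool:
    """Signal rule: CI lower bound strictly greater than 1 and at least
    ``min_cases`` event cases for the drug; an undefined CI never signals."""
    t = ContingencyTable2x2(*table)
    if not estimate.defined or math.isnan(estimate.ci_low):
        return False
    return bool(estimate.ci_low > 1.0 and t.a >= min_cases)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[int]) -> FisherResult:
    """Two-sided Fisher exact test by the small-p-values method.

    Sums the hypergeometric probabilities of every table sharing the observed
    margins whose point probability does not exceed the observed table's
    (within a 1e-7 relative tolerance, as in R's fisher.test).  All
    probabilities are handled as logs, so extremely small p-values are still
    reported exactly on the log10 scale even after ``p_value`` itself
    underflows to 0.0.  Any zero margin gives p = 1.
    """
    t = ContingencyTable2x2(*table).validate()
    a, b, c, d = t
    n = t.n_total
    row1, col1 = a + b, a + c
    if 0 in (row1, col1, n - row1, n - col1):
        return FisherResult(1.0, 0.0)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    logp = hypergeom.logpmf(support, n, col1, row1)
    log_obs = logp[np.searchsorted(support, a)]
    keep = logp <= log_obs + _REL_TOL
    log_p = float(min(logsumexp(logp[keep]), 0.0))
    return FisherResult(math.exp(log_p), log_p / math.log(10.0))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
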