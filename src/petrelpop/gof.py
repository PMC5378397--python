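"""RELEASE-style goodness-of-fit tests for the Cormack-Jolly-Seber model.

The CJS assumptions -- equal survival and equal recapture probability for
all marked animals alive at an occasion -- are screened with the classic
contingency-table decomposition:

* TEST3.SR: per occasion, newly marked vs previously marked animals,
  cross-classified by whether they are ever re-encountered later
  (sensitive to transience).
* TEST3.SM: per occasion, among released animals re-encountered later,
  newly vs previously marked x first re-encounter at the next occasion or
  later.
* TEST2.CT: per occasion, among animals known to be alive around the
  transition (encountered at or before the occasion and again at or after
  the next one), encountered at the occasion or not x encountered at the
  next occasion or not (sensitive to trap-dependence).
* TEST2.CL: per occasion, among animals encountered at or before the
  occasion and re-encountered at least two occasions later but not at the
  immediately following one, encountered at the occasion or not x next
  re-encounter immediately after the gap or later.

Each component pools per-occasion 2x2 tables into a chi-square statistic.
Tables with any expected cell below a threshold (default 2) are dropped
from the pool, in the spirit of U-CARE's low-expected-count pooling; the
global test sums the component statistics and degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .capture import EncounterHistoryTable

__all__ = ["GOFResult", "gof_release"]

COMPONENTS = ("TEST3.SR", "TEST3.SM", "TEST2.CT", "TEST2.CL")


@dataclass
class GOFResult:
    """Pooled chi-square for one test component (or the global sum)."""

    component: str
    chi2: float
    df: int
    p: float  # NaN when df == 0
    tables: list = field(default_factory=list)  # (occasion, 2x2 array) kept for audit

    def __repr__(self):
        p = "undefined" if np.isnan(self.p) else f"{self.p:.4f}"
        return f"GOFResult({self.component}: X2={self.chi2:.3f}, df={self.df}, p={p})"


def _table_chi2(table: np.ndarray, min_expected: float):
    """Pearson chi-square of one 2x2 table, or None if dropped by pooling."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if total == 0 or (rows == 0).any() or (cols == 0).any():
        return None
    expected = np.outer(rows, cols) / total
    if expected.min() < min_expected:
        return None
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2


def gof_release(
    histories: EncounterHistoryTable, min_expected: float = 2.0
) -> list[GOFResult]:
    """Run the TEST2/TEST3 suite on individual encounter histories.

    Returns one :class:`GOFResult` per component plus the global sum.
    Datasets with no recaptures yield df=0 components with ``p = NaN``
    rather than an error.
    """
    T = histories.T
    if T < 3:
        raise ValueError("goodness-of-fit tests need at least 3 occasions")
    H = histories.expand().astype(bool)
    n, _ = H.shape

    first = np.argmax(H, axis=1)
    last = T - 1 - np.argmax(H[:, ::-1], axis=1)

    results = []

    # TEST3.SR / TEST3.SM: release cohorts at occasions 2..T-1
    sr_tables, sm_tables = [], []
    for i in range(1, T - 1):
        at_i = H[:, i]
        new = first == i
        seen_later = H[:, i + 1 :].any(axis=1)
        # SR: new vs old x reseen-or-not
        sr = np.array(
            [
                [(at_i & new & seen_later).sum(), (at_i & new & ~seen_later).sum()],
                [(at_i & ~new & seen_later).sum(), (at_i & ~new & ~seen_later).sum()],
            ]
        )
        sr_tables.append((histories.occasions[i], sr))
        # SM: among reseen, next sighting at i+1 vs later
        reseen = at_i & seen_later
        nxt = H[:, i + 1]
        sm = np.array(
            [
                [(reseen & new & nxt).sum(), (reseen & new & ~nxt).sum()],
                [(reseen & ~new & nxt).sum(), (reseen & ~new & ~nxt).sum()],
            ]
        )
        sm_tables.append((histories.occasions[i], sm))

    # TEST2.CT: transition i -> i+1 for i = 2..T-2 (0-based 1..T-3)
    ct_tables = []
    for i in range(1, T - 2):
        marked = H[:, : i + 1].any(axis=1)
        alive_after = H[:, i + 1 :].any(axis=1)
        pool = marked & alive_after
        at_i = H[:, i]
        at_next = H[:, i + 1]
        ct = np.array(
            [
                [(pool & at_i & at_next).sum(), (pool & at_i & ~at_next).sum()],
                [(pool & ~at_i & at_next).sum(), (pool & ~at_i & ~at_next).sum()],
            ]
        )
        ct_tables.append((histories.occasions[i], ct))

    # TEST2.CL: skippers of occasion i+1, next seen at i+2 vs later
    cl_tables = []
    for i in range(1, T - 3):
        marked = H[:, : i + 1].any(axis=1)
        skip = ~H[:, i + 1]
        seen_after_gap = H[:, i + 2 :].any(axis=1)
        pool = marked & skip & seen_after_gap
        at_i = H[:, i]
        at_gap_end = H[:, i + 2]
        cl = np.array(
            [
                [(pool & at_i & at_gap_end).sum(), (pool & at_i & ~at_gap_end).sum()],
                [(pool & ~at_i & at_gap_end).sum(), (pool & ~at_i & ~at_gap_end).sum()],
            ]
        )
        cl_tables.append((histories.occasions[i], cl))

    for name, tables in zip(
        COMPONENTS, (sr_tables, sm_tables, ct_tables, cl_tables)
    ):
        chi2, df, kept = 0.0, 0, []
        for occ, tab in tables:
            c = _table_chi2(tab, min_expected)
            if c is not None:
                chi2 += c
                df += 1
                kept.append((occ, tab))
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
        results.append(GOFResult(name, chi2, df, p, kept))

    g_chi2 = sum(r.chi2 for r in results)
    g_df = sum(r.df for r in results)
    g_p = float(stats.chi2.sf(g_chi2, g_df)) if g_df > 0 else float("nan")
    results.append(GOFResult("global", g_chi2, g_df, g_p))
    return results
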