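"""Capture-mark-recapture data structures and sufficient statistics.

Encounter histories (one 0/1 detection vector per individual over ordered
annual occasions) are the raw object of a mark-recapture study.  For
open-population likelihoods the sufficient statistics are the reduced
m-array -- per release cohort, the number of individuals first recaptured
at each later occasion -- together with the per-occasion counts of unmarked
(first) captures.  Recaptured individuals are re-released and re-enter the
cohort of their recapture year, so cohort sizes count release *events*.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EncounterHistoryTable",
    "MArray",
    "read_inp",
    "write_inp",
    "histories_to_marray",
    "marray_from_table",
    "read_marray_tsv",
    "write_marray_tsv",
]


class CaptureDataError(ValueError):
    """Malformed or inconsistent capture-mark-recapture input."""


@dataclass
class EncounterHistoryTable:
    """Per-individual binary detection vectors over ordered occasions.

    Parameters
    ----------
    occasions
        Ordered occasion labels (calendar years of the annual sessions).
    histories
        2-D 0/1 integer array, one row per history, ``T`` columns.
    frequency
        Positive count of individuals sharing each history row.
    """

    occasions: list
    histories: np.ndarray
    frequency: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.histories = np.asarray(self.histories, dtype=int)
        if self.histories.ndim != 2:
            raise CaptureDataError("histories must be a 2-D array")
        if self.frequency is None:
            self.frequency = np.ones(len(self.histories), dtype=int)
        self.frequency = np.asarray(self.frequency, dtype=int)
        T = len(self.occasions)
        if self.histories.shape[1] != T:
            raise CaptureDataError(
                f"history length {self.histories.shape[1]} != {T} occasions"
            )
        if not np.isin(self.histories, [0, 1]).all():
            raise CaptureDataError("histories must be binary")
        if len(self.frequency) != len(self.histories):
            raise CaptureDataError("frequency length mismatch")
        if (self.frequency < 1).any():
            raise CaptureDataError("frequencies must be >= 1")
        if len(self.histories) and not self.histories.any(axis=1).all():
            raise CaptureDataError("every history must contain a detection")

    @property
    def T(self) -> int:
        return len(self.occasions)

    @property
    def n_individuals(self) -> int:
        return int(self.frequency.sum())

    def expand(self) -> np.ndarray:
        """One row per individual (frequencies unrolled)."""
        return np.repeat(self.histories, self.frequency, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.histories, columns=self.occasions)
        df["frequency"] = self.frequency
        return df


@dataclass
class MArray:
    """Reduced m-array sufficient statistics for open-population fitting.

    ``released[i]`` counts release events at occasion ``i`` (new captures
    plus re-released recaptures); ``m[i, j]`` counts first recaptures at
    ``j`` of birds released at ``i``; ``unmarked[i]`` counts first-ever
    captures at ``i``.
    """

    occasions: list
    released: np.ndarray
    m: np.ndarray
    unmarked: np.ndarray
    warnings_: list = field(default_factory=list)

    def __post_init__(self):
        self.released = np.asarray(self.released, dtype=int)
        self.m = np.asarray(self.m, dtype=int)
        self.unmarked = np.asarray(self.unmarked, dtype=int)
        T = self.T
        if self.m.shape != (T, T):
            raise CaptureDataError(f"m-array must be {T}x{T}")
        if len(self.released) != T or len(self.unmarked) != T:
            raise CaptureDataError("released/unmarked length mismatch")
        if np.tril(self.m).any():
            raise CaptureDataError("m[i, j] must be zero for j <= i")
        if (self.m.sum(axis=1) > self.released).any():
            raise CaptureDataError("cohort recaptures exceed releases")
        if (self.unmarked > self.released).any() and self.released[:-1].any():
            # final occasion may have unmarked captures without a release row
            bad = np.nonzero(self.unmarked[:-1] > self.released[:-1])[0]
            if bad.size:
                raise CaptureDataError(
                    f"unmarked captures exceed releases at occasion {bad[0] + 1}"
                )

    @property
    def T(self) -> int:
        return len(self.occasions)

    @property
    def never_recaptured(self) -> np.ndarray:
        return self.released - self.m.sum(axis=1)

    @property
    def n_observed(self) -> int:
        """Distinct individuals ever captured."""
        return int(self.unmarked.sum())

    @property
    def total_first_recaptures(self) -> int:
        return int(self.m.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.m, index=self.occasions, columns=self.occasions)
        df.insert(0, "released", self.released)
        df["never_recaptured"] = self.never_recaptured
        df["unmarked"] = self.unmarked
        return df


# ---------------------------------------------------------------------------
# MARK .inp dialect

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.DOTALL)


def read_inp(path) -> EncounterHistoryTable:
    """Read MARK-dialect encounter histories.

    Each record is a 0/1 string, whitespace, an integer frequency and a
    terminating semicolon; ``/* ... */`` block comments are allowed.
    Occasions are labelled 1..T unless the first comment line is
    ``/* occasions: y1 y2 ... */``.
    """
    with open(path) as fh:
        raw = fh.read()

    occasions = None
    m = re.search(r"/\*\s*occasions:([^*]*)\*/", raw)
    if m:
        occasions = [int(tok) for tok in m.group(1).split()]
    text = _COMMENT_RE.sub(" ", raw)

    histories, freqs = [], []
    T = None
    for lineno, record in _iter_records(text):
        parts = record.split()
        if len(parts) != 2:
            raise CaptureDataError(
                f"line {lineno}: expected 'history frequency;', got {record!r}"
            )
        hist, freq_s = parts
        if not set(hist) <= {"0", "1"}:
            raise CaptureDataError(f"line {lineno}: non-binary history {hist!r}")
        if T is None:
            T = len(hist)
        elif len(hist) != T:
            raise CaptureDataError(
                f"line {lineno}: history length {len(hist)} != {T}"
            )
        try:
            freq = int(freq_s)
        except ValueError:
            raise CaptureDataError(f"line {lineno}: bad frequency {freq_s!r}") from None
        if freq < 1:
            raise CaptureDataError(f"line {lineno}: frequency must be positive")
        histories.append([int(c) for c in hist])
        freqs.append(freq)

    if not histories:
        raise CaptureDataError("no encounter histories found")
    if occasions is None:
        occasions = list(range(1, T + 1))
    elif len(occasions) != T:
        raise CaptureDataError("occasions comment length != history length")
    return EncounterHistoryTable(occasions, np.array(histories), np.array(freqs))


def _iter_records(text):
    """Yield (line number, record) for each semicolon-terminated record."""
    line = 1
    buf = []
    start = 1
    for ch in text:
        if ch == "\n":
            line += 1
        if ch == ";":
            rec = "".join(buf).strip()
            if rec:
                yield start, rec
            buf = []
            start = line
        elif buf or not ch.isspace():
            if not buf:
                start = line
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        raise CaptureDataError(f"line {start}: record missing terminating ';'")


def write_inp(table: EncounterHistoryTable, path) -> None:
    """Write encounter histories in the MARK dialect (round-trips read_inp)."""
    with open(path, "w") as fh:
        fh.write("/* occasions: " + " ".join(str(o) for o in table.occasions) + " */\n")
        for hist, freq in zip(table.histories, table.frequency):
            fh.write("".join(str(int(h)) for h in hist) + f" {freq};\n")


# ---------------------------------------------------------------------------
# Sufficient statistics

def histories_to_marray(table: EncounterHistoryTable) -> MArray:
    """Reduce encounter histories to the m-array sufficient statistics.

    Every detection is a release event (all captured birds are re-released);
    ``m[i, j]`` counts first recaptures at ``j`` after release at ``i``.
    """
    if len(table.histories) == 0:
        raise CaptureDataError("empty encounter-history table")
    T = table.T
    released = np.zeros(T, dtype=int)
    m = np.zeros((T, T), dtype=int)
    unmarked = np.zeros(T, dtype=int)
    for hist, freq in zip(table.histories, table.frequency):
        det = np.nonzero(hist)[0]
        unmarked[det[0]] += freq
        for occ in det:
            released[occ] += freq
        for a, b in zip(det[:-1], det[1:]):
            m[a, b] += freq
    # last occasion releases cannot be recaptured; keep them (never recaptured)
    return MArray(list(table.occasions), released, m, unmarked)


def marray_from_table(
    released: Sequence[int],
    first_recapture: Sequence[Sequence[int]],
    total_new: int,
    occasions: Sequence | None = None,
    reported_recapture_events: int | None = None,
) -> MArray:
    """Build a fit-ready m-array from a printed release/first-recapture table.

    The printed layout has release rows for occasions ``1..T-1`` and
    first-recapture columns for occasions ``2..T``.  Unmarked (first)
    captures are derived as ``u_i = R_i - (column sum of m at i)`` for
    observed occasions, with the final occasion's ``u`` taken as
    ``total_new`` minus the rest.

    Parameters
    ----------
    released
        Release counts for occasions 1..T-1.
    first_recapture
        (T-1) x (T-1) matrix; entry [i][j] counts releases of cohort i first
        recaptured at occasion j+2 (columns start at the second occasion).
    total_new
        Total distinct individuals captured over the whole study.
    reported_recapture_events
        Optional independently reported total number of recapture events;
        a mismatch with the table's first-recapture sum raises a warning
        (the table stays authoritative).
    """
    released = np.asarray(released, dtype=int)
    Tm1 = len(released)
    T = Tm1 + 1
    if occasions is None:
        occasions = list(range(1, T + 1))
    if len(occasions) != T:
        raise CaptureDataError("occasions length must be one more than releases")

    fr = np.asarray(first_recapture, dtype=int)
    if fr.shape != (Tm1, Tm1):
        raise CaptureDataError(f"first_recapture must be {Tm1}x{Tm1}")
    m = np.zeros((T, T), dtype=int)
    m[:Tm1, 1:] = fr

    col_sums = m.sum(axis=0)
    unmarked = np.zeros(T, dtype=int)
    unmarked[:Tm1] = released - col_sums[:Tm1]
    if (unmarked[:Tm1] < 0).any():
        i = int(np.nonzero(unmarked[:Tm1] < 0)[0][0])
        raise CaptureDataError(
            f"occasion {occasions[i]}: recaptures exceed releases (negative u)"
        )
    unmarked[Tm1] = total_new - unmarked[:Tm1].sum()
    if unmarked[Tm1] < 0:
        raise CaptureDataError("total_new smaller than derived first captures")

    released_full = np.zeros(T, dtype=int)
    released_full[:Tm1] = released

    notes = []
    if reported_recapture_events is not None and int(m.sum()) != reported_recapture_events:
        msg = (
            f"m-array holds {int(m.sum())} first-recapture events but "
            f"{reported_recapture_events} recapture events were reported; "
            "the table is treated as authoritative (repeat same-occasion "
            "captures cannot be recovered from a reduced m-array)"
        )
        warnings.warn(msg)
        notes.append(msg)
    return MArray(list(occasions), released_full, m, unmarked, warnings_=notes)


# ---------------------------------------------------------------------------
# TSV layout mirroring the printed m-array table

def write_marray_tsv(marr: MArray, path) -> None:
    """Write the m-array in the printed-table TSV layout."""
    T = marr.T
    cols = ["occasion", "released"] + [str(o) for o in marr.occasions[1:]]
    cols += ["total_recaptured"]
    lines = ["\t".join(cols)]
    for i in range(T - 1):
        row = [str(marr.occasions[i]), str(marr.released[i])]
        row += [str(marr.m[i, j]) for j in range(1, T)]
        row += [str(marr.m[i].sum())]
        lines.append("\t".join(row))
    lines.append(f"# total_new\t{marr.n_observed}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_marray_tsv(path) -> MArray:
    """Read the printed-table TSV layout written by :func:`write_marray_tsv`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    total_new = None
    rows = []
    header = lines[0].split("\t")
    occ_cols = header[2:-1]
    for ln in lines[1:]:
        if ln.startswith("#"):
            parts = ln.split("\t")
            if parts[0].strip("# ") == "total_new":
                total_new = int(parts[1])
            continue
        rows.append(ln.split("\t"))
    if total_new is None:
        raise CaptureDataError("missing '# total_new' footer row")
    released = [int(r[1]) for r in rows]
    fr = [[int(v) for v in r[2:-1]] for r in rows]
    occasions = [_maybe_int(rows[0][0])] + [_maybe_int(c) for c in occ_cols]
    return marray_from_table(released, fr, total_new, occasions=occasions)


def _maybe_int(s):
    try:
        return int(s)
    except ValueError:
        return s
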