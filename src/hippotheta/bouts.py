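"""Oscillatory bout extraction and duration statistics.

A bout is a maximal run of consecutive samples during which an oscillation is
present; its length is expressed in cycles (duration times the mean
instantaneous frequency over the run).  Runs shorter than two samples are
dropped as numerically meaningless (a single sample carries no frequency
information); this is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hippotheta.types import OscillatoryTrace

__all__ = [
    "extract_bouts",
    "mean_bout_cycles",
    "average_nearby",
    "compare_bout_groups",
]

BOUT_COLUMNS = ["electrode_id", "label", "start_s", "end_s", "mean_freq_hz", "n_cycles"]


def extract_bouts(trace: OscillatoryTrace, electrode_id: str = "",
                  label: str = "", min_samples: int = 2) -> pd.DataFrame:
    """Table of maximal presence runs with mean frequency and cycle count.

    Duration is measured as ``n_samples / sampling_rate`` (end exclusive), so
    with ``min_samples=1`` the summed durations per trace equal the total
    presence time exactly.
    """
    presence = np.asarray(trace.presence, dtype=bool)
    fs = trace.sampling_rate
    padded = np.concatenate(([False], presence, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    rows = []
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        mean_freq = float(np.mean(trace.inst_freq[s:e]))
        dur = (e - s) / fs
        rows.append(
            {
                "electrode_id": electrode_id,
                "label": label,
                "start_s": s / fs,
                "end_s": e / fs,
                "mean_freq_hz": mean_freq,
                "n_cycles": dur * mean_freq,
            }
        )
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def mean_bout_cycles(bout_table: pd.DataFrame,
                     by: list[str] = ("electrode_id", "label")) -> pd.Series:
    """Arithmetic mean of bout cycle counts per group (electrode x band)."""
    if bout_table.empty:
        return pd.Series(dtype=float)
    return bout_table.groupby(list(by))["n_cycles"].mean()


def average_nearby(values: pd.Series, ap_fractions: pd.Series,
                   radius: float = 0.10) -> pd.Series:
    """Average values of electrodes at nearby A-P positions (one subject).

    Electrodes within ``radius`` of each other along the A-P axis — applied
    transitively, i.e. over connected components of the proximity graph —
    contribute a single averaged value.  The result is indexed by the lowest
    electrode id of each component.
    """
    ids = list(values.index)
    n = len(ids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ap = ap_fractions.reindex(values.index).to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if abs(ap[i] - ap[j]) < radius:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = {}
    for members in comps.values():
        key = min(ids[i] for i in members)
        out[key] = float(np.mean([values.iloc[i] for i in members]))
    return pd.Series(out).sort_index()


def compare_bout_groups(values_a: np.ndarray, values_b: np.ndarray
                        ) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test (two-sided) between bout summaries.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``.  When both groups have
    zero variance and equal means the statistic is 0 and p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), df, 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)
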