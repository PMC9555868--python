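"""Tabular I/O, descriptive statistics and the two group-level inferential
summaries used when comparing the tasks' fitted priors.

The canonical on-disk format is a tidy counts CSV with header
``participant,task,noise,asynchrony_ms,n_trials,n_yes`` — one row per
participant x task x noise x asynchrony cell.  A shim is provided for the
wide layout typical of deposited source-data spreadsheets (one column per
asynchrony level).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ConditionCounts

__all__ = [
    "COUNTS_COLUMNS",
    "counts_to_frame",
    "frame_to_counts",
    "read_counts_csv",
    "write_counts_csv",
    "read_wide_counts",
    "descriptive_proportions",
    "paired_t_test",
    "pearson_correlation",
]

COUNTS_COLUMNS = ("participant", "task", "noise", "asynchrony_ms", "n_trials", "n_yes")
_KEY = ["participant", "task", "noise", "asynchrony_ms"]


def counts_to_frame(rows: Sequence[ConditionCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant for r in rows],
            "task": [r.task for r in rows],
            "noise": [r.noise for r in rows],
            "asynchrony_ms": [r.asynchrony for r in rows],
            "n_trials": [r.n_trials for r in rows],
            "n_yes": [r.n_yes for r in rows],
        }
    )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    df = df.loc[:, list(COUNTS_COLUMNS)].copy()
    for col in ("noise", "asynchrony_ms", "n_trials", "n_yes"):
        df[col] = df[col].astype(int)
    bad = df[(df.n_yes < 0) | (df.n_yes > df.n_trials)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"invalid counts n_yes={row.n_yes} > n_trials={row.n_trials} at "
            f"(participant={row.participant!r}, task={row.task!r}, "
            f"noise={row.noise}, asynchrony_ms={row.asynchrony_ms})"
        )
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate key (participant={row.participant!r}, task={row.task!r}, "
            f"noise={row.noise}, asynchrony_ms={row.asynchrony_ms})"
        )
    return df


def frame_to_counts(df: pd.DataFrame) -> list[ConditionCounts]:
    df = _validate_frame(df)
    return [
        ConditionCounts(
            participant=str(r.participant),
            task=str(r.task),
            noise=int(r.noise),
            asynchrony=int(r.asynchrony_ms),
            n_trials=int(r.n_trials),
            n_yes=int(r.n_yes),
        )
        for r in df.itertuples(index=False)
    ]


def read_counts_csv(path) -> list[ConditionCounts]:
    """Read and validate a tidy counts CSV."""
    return frame_to_counts(pd.read_csv(path))


def write_counts_csv(rows: Sequence[ConditionCounts], path) -> None:
    """Write counts as a tidy CSV (round-trips through ``read_counts_csv``)."""
    _validate_frame(counts_to_frame(rows)).to_csv(path, index=False)


def read_wide_counts(path, n_trials: int = 12) -> list[ConditionCounts]:
    """Shim for wide source-data layouts: one column per asynchrony level.

    Expects columns ``participant``, ``task``, ``noise`` plus one integer
    column per asynchrony (ms), cells holding the number of "yes" answers.
    """
    df = pd.read_csv(path)
    id_cols = {"participant", "task", "noise"}
    missing = id_cols - set(df.columns)
    if missing:
        raise ValueError(f"wide counts table missing columns {sorted(missing)}")
    async_cols = [c for c in df.columns if c not in id_cols]
    rows = []
    for _, rec in df.iterrows():
        for col in async_cols:
            rows.append(
                ConditionCounts(
                    participant=str(rec["participant"]),
                    task=str(rec["task"]),
                    noise=int(rec["noise"]),
                    asynchrony=int(col),
                    n_trials=n_trials,
                    n_yes=int(rec[col]),
                )
            )
    return rows


def descriptive_proportions(rows: Sequence[ConditionCounts]) -> pd.DataFrame:
    """Across-participant mean ± SEM of percent "yes" per (task, noise,
    asynchrony) cell.

    Proportions are computed per participant first, then averaged; SEM is
    SD/sqrt(n participants) (0 for a single participant).
    """
    if not rows:
        raise ValueError("no counts given")
    df = counts_to_frame(rows)
    df["pct_yes"] = 100.0 * df.n_yes / df.n_trials
    grouped = df.groupby(["task", "noise", "asynchrony_ms"])["pct_yes"]
    out = grouped.agg(
        mean_pct_yes="mean",
        sem_pct_yes=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))
        if len(v) > 1
        else 0.0,
        n_participants="count",
    ).reset_index()
    return out


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Paired two-sided t-test; returns ``(t, df, p)``.

    ``t = mean(a-b) / (sd(a-b)/sqrt(n))`` with ``df = n-1``.  Degenerate
    input (zero variance of the differences) raises.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; t is undefined")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = float(n - 1)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation coefficient r."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance; correlation is undefined")
    return float(np.corrcoef(a, b)[0, 1])
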