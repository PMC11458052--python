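"""From trial records to analysis variables.

The scoring pipeline: flag response-time outliers per subject (beyond
mean +/- 2.5 sd, single pass), count hits and false alarms per
subject x stimulus type x orientation filter, compute log-linear-corrected
d', z-normalize sensitivity across all cells, duplicate the 0-deg filter at
180 deg to close the orientation circle, and form the inversion and negation
effect curves by subtraction from the natural condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

RT_SD_CUTOFF = 2.5
ORIENTATION_LEVELS = ("0", "30", "60", "90", "120", "150")


@dataclass(frozen=True)
class ConditionCounts:
    """Same/different trial counts for one condition cell."""

    n_same: int
    n_diff: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.n_same:
            raise ValueError("hits must be within [0, n_same]")
        if not 0 <= self.false_alarms <= self.n_diff:
            raise ValueError("false_alarms must be within [0, n_diff]")


def filter_rt_outliers(trials: pd.DataFrame, cutoff_sd: float = RT_SD_CUTOFF) -> pd.DataFrame:
    """Flag per-subject RT outliers (single pass, not iterated).

    Adds/overwrites an ``excluded`` column: True where rt_ms falls outside
    the subject's mean +/- ``cutoff_sd`` standard deviations.  A subject with
    zero RT variance gets no exclusions.
    """
    out = trials.copy()
    excluded = np.zeros(len(out), dtype=bool)
    for _, idx in out.groupby("subject").groups.items():
        rt = out.loc[idx, "rt_ms"].to_numpy(dtype=float)
        sd = rt.std(ddof=1) if rt.size > 1 else 0.0
        if sd > 0:
            m = rt.mean()
            excluded[out.index.get_indexer(idx)] = (rt < m - cutoff_sd * sd) | (
                rt > m + cutoff_sd * sd
            )
    out["excluded"] = excluded
    return out


def loglinear_dprime(counts: ConditionCounts) -> float:
    """Log-linear-corrected d': add 0.5 to hit/FA counts and 1 to the totals.

    Always finite, even at floor or ceiling performance.
    """
    if counts.n_same <= 0 or counts.n_diff <= 0:
        raise ValueError("both trial counts must be positive")
    h = (counts.hits + 0.5) / (counts.n_same + 1.0)
    f = (counts.false_alarms + 0.5) / (counts.n_diff + 1.0)
    return float(norm.ppf(h) - norm.ppf(f))


def condition_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Hit/false-alarm counts per subject x stimulus type x filter.

    Trials flagged ``excluded`` (if the column exists) are dropped first.
    """
    df = trials
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    grouped = df.groupby(["subject", "stimulus_type", "filter"], sort=True)
    rows = []
    for (subject, st, f), g in grouped:
        same = g[g["is_same"]]
        diff = g[~g["is_same"]]
        rows.append(
            {
                "subject": subject,
                "stimulus_type": st,
                "filter": f,
                "n_same": len(same),
                "n_diff": len(diff),
                "hits": int(same["response_same"].sum()),
                "false_alarms": int(diff["response_same"].sum()),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell log-linear d' from raw (or outlier-filtered) trials."""
    counts = condition_counts(trials)
    counts["dprime"] = [
        loglinear_dprime(ConditionCounts(r.n_same, r.n_diff, r.hits, r.false_alarms))
        for r in counts.itertuples()
    ]
    return counts.drop(columns=["n_same", "n_diff", "hits", "false_alarms"])


def normalize_sensitivity(table: pd.DataFrame, scope: str = "grand") -> pd.DataFrame:
    """Z-transform d' into norm_dprime.

    ``scope='grand'`` (default) standardizes with one mean/sd over every
    subject x stimulus type x filter cell, preserving condition differences.
    ``scope='subject'`` standardizes within subject instead.
    """
    out = table.copy()
    if scope == "grand":
        m, s = out["dprime"].mean(), out["dprime"].std(ddof=0)
        if s == 0 or len(out) < 2:
            raise ValueError("degenerate sensitivity table: zero variance")
        out["norm_dprime"] = (out["dprime"] - m) / s
    elif scope == "subject":
        def _z(x):
            if x.std(ddof=0) == 0:
                raise ValueError("degenerate sensitivity table: zero variance")
            return (x - x.mean()) / x.std(ddof=0)

        out["norm_dprime"] = out.groupby("subject")["dprime"].transform(_z)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out


def duplicate_circular(table: pd.DataFrame) -> pd.DataFrame:
    """Duplicate the 0-deg filter rows at 180 deg (idempotent).

    Closes the orientation circle so tuning fits see the 0/180 identity the
    way the analysis defined it: the 0-deg measurement enters twice.
    """
    if (table["filter"] == "180").any():
        return table.copy()
    zero = table[table["filter"] == "0"]
    if zero.empty:
        raise ValueError("table has no 0-deg filter rows to duplicate")
    dup = zero.copy()
    dup["filter"] = "180"
    return pd.concat([table, dup], ignore_index=True)


def compute_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Inversion and negation effect curves per subject x orientation.

    Expects a normalized table (``norm_dprime`` column) after circular
    duplication; full-spectrum cells are excluded.  Returns a long table with
    columns subject, filter_deg, effect_type, effect.
    """
    if "norm_dprime" not in table.columns:
        raise ValueError("table must be normalized first (norm_dprime column)")
    ori = table[table["filter"] != "fullspectrum"].copy()
    wide = ori.pivot_table(
        index=["subject", "filter"], columns="stimulus_type", values="norm_dprime"
    )
    for st in ("natural", "inverted", "negated"):
        if st not in wide.columns or wide[st].isna().any():
            raise ValueError(f"missing {st} cells in sensitivity table")
    rows = []
    for (subject, f), r in wide.iterrows():
        for effect_type, other in (("inversion", "inverted"), ("negation", "negated")):
            rows.append(
                {
                    "subject": subject,
                    "filter_deg": float(f),
                    "effect_type": effect_type,
                    "effect": float(r["natural"] - r[other]),
                }
            )
    return pd.DataFrame(rows).sort_values(["subject", "effect_type", "filter_deg"]).reset_index(
        drop=True
    )


def score_trials(trials: pd.DataFrame, scope: str = "grand") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline: RT filter -> d' -> z -> duplicate -> effects.

    Returns (sensitivity table with norm_dprime, effect-curve table).
    """
    filtered = filter_rt_outliers(trials)
    table = sensitivity_table(filtered)
    table = normalize_sensitivity(table, scope=scope)
    table = duplicate_circular(table)
    effects = compute_effects(table)
    return table, effects
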