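"""Cohort-level summary statistics for a promoter-trap screen.

Operates on a records table (one row per called line) with columns
``insertion_type``, ``wt_type``, ``wt_fpkm`` and ``level`` and reproduces
the screen-level readouts: insertion-type shares, WT-overlap (i-iv) shares
with activation fractions normalised within the WT-transcribed and
WT-untranscribed strata, transcription-level percentile bins and decade
histograms, the lower (10^1-10^4) vs higher (10^5-10^7) split, the
Spearman correlation of reporter level with WT FPKM, and the Mendelian
recovery expectation for a T2 screen grown from several seeds per line.

Reported percentages are rounded to one decimal, half away from zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import INSERTION_TYPES, WT_TYPES

__all__ = [
    "round1",
    "type_fractions",
    "wt_overlap_fractions",
    "normalized_activation",
    "percentile_bins",
    "decade_histogram",
    "low_high_split",
    "spearman_vs_wt",
    "expected_recovery",
    "summarize",
]

LEVEL_DECADES = tuple(range(1, 8))  # 10^1 .. 10^7
ND = "ND"  # untranscribed (level 0 or omitted)


def round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


def _require_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("empty cohort: no called records")


def type_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentage shares and transcribed fractions per insertion type."""
    _require_records(records)
    out = []
    n = len(records)
    for itype in INSERTION_TYPES:
        sub = records[records["insertion_type"] == itype]
        transcribed = int((sub["level"] > 0).sum())
        out.append(
            {
                "insertion_type": itype,
                "count": len(sub),
                "percent": round1(100.0 * len(sub) / n),
                "transcribed": transcribed,
                "transcribed_fraction": transcribed / len(sub) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("insertion_type")


def normalized_activation(n_active: float, n_inactive: float) -> Optional[float]:
    """Activation share within a stratum, as a 1-decimal percentage.

    Accepts raw counts or percentage shares (the ratio is scale-free).
    Returns None when the stratum is empty.
    """
    total = n_active + n_inactive
    if total == 0:
        return None
    return round1(100.0 * n_active / total)


def wt_overlap_fractions(records: pd.DataFrame) -> dict:
    """Shares of WT-overlap types i-iv plus stratum-normalised activation.

    ``activation_wt_untranscribed`` is the de novo activation frequency
    n_iii / (n_iii + n_iv); ``activation_wt_transcribed`` is
    n_i / (n_i + n_ii).  Both are 1-decimal percentages, or None when the
    stratum is empty.
    """
    _require_records(records)
    counts = {t: int((records["wt_type"] == t).sum()) for t in WT_TYPES}
    n = len(records)
    return {
        "counts": counts,
        "percent": {t: round1(100.0 * c / n) for t, c in counts.items()},
        "activation_wt_untranscribed": normalized_activation(counts["iii"], counts["iv"]),
        "activation_wt_transcribed": normalized_activation(counts["i"], counts["ii"]),
    }


def percentile_bins(levels: Sequence[float]) -> list[str]:
    """Percentile bin (High: 100-67, Mid: 66-34, Low: 33-1) per transcribed line.

    Percentile rank is computed among the given (transcribed) levels only,
    with ties sharing the higher bin; with n distinct levels the three bins
    differ in size by at most one.
    """
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 3:
        raise ValueError("need at least 3 transcribed lines for percentile bins")
    frac = stats.rankdata(levels, method="max") / len(levels)
    return ["High" if f > 2 / 3 else "Mid" if f > 1 / 3 else "Low" for f in frac]


def level_decade(level: float) -> object:
    """Decade bin of a relative transcription level: ND for 0/omitted, else
    floor(log10 level) clamped to [1, 7]."""
    if level is None or not np.isfinite(level) or level <= 0:
        return ND
    return int(min(max(math.floor(math.log10(level)), 1), 7))


def decade_histogram(records: pd.DataFrame) -> pd.DataFrame:
    """Per-insertion-type counts and fractions over bins ND, 10^1..10^7.

    Fractions are normalised within each insertion type (type total = 100%).
    """
    bins = [ND, *LEVEL_DECADES]
    table = pd.DataFrame(0, index=pd.Index(bins, name="decade"), columns=list(INSERTION_TYPES))
    for _, row in records.iterrows():
        table.loc[level_decade(row["level"]), row["insertion_type"]] += 1
    totals = table.sum(axis=0)
    fractions = table.div(totals.where(totals > 0, np.nan), axis=1)
    return pd.concat({"count": table, "fraction": fractions}, axis=1)


def low_high_split(records: pd.DataFrame) -> pd.DataFrame:
    """Per-type shares of transcribed lines in the lower (10^1-10^4) vs
    higher (10^5-10^7) level ranges, normalised per insertion type."""
    transcribed = records[records["level"] > 0]
    out = []
    for itype in INSERTION_TYPES:
        sub = transcribed[transcribed["insertion_type"] == itype]
        n = len(sub)
        lower = int(sum(level_decade(v) != ND and level_decade(v) <= 4 for v in sub["level"]))
        out.append(
            {
                "insertion_type": itype,
                "n_transcribed": n,
                "lower": lower / n if n else np.nan,
                "higher": (n - lower) / n if n else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("insertion_type")


def spearman_vs_wt(records: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of reporter level with WT FPKM over type-i lines.

    Average ranks for ties.  Returns (nan, nan) when either vector is
    constant (correlation undefined).
    """
    sub = records[records["wt_type"] == "i"]
    if len(sub) < 3:
        raise ValueError("need at least 3 type-i lines")
    x = sub["level"].to_numpy(dtype=float)
    y = sub["wt_fpkm"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def expected_recovery(
    n_lines: int, seeds_per_line: int, wt_fraction: float = 0.25
) -> tuple[float, int]:
    """Probability that a segregating T2 line is recovered, and the expected
    number of recovered lines.

    Each seed is wild type (reporter-free) with probability ``wt_fraction``
    (1/4 for a single-locus hemizygous T1); growing ``seeds_per_line`` seeds
    recovers the line unless all of them are wild type.
    """
    if seeds_per_line < 1:
        raise ValueError("seeds_per_line must be >= 1")
    if not 0 <= wt_fraction <= 1:
        raise ValueError("wt_fraction must be within [0, 1]")
    probability = 1.0 - wt_fraction ** seeds_per_line
    expected = int(math.floor(n_lines * probability + 0.5))
    return probability, expected


def summarize(records: pd.DataFrame) -> dict:
    """Full cohort summary as a JSON-serialisable dict."""
    _require_records(records)
    n_called = len(records)
    transcribed_mask = records["level"] > 0
    tf = type_fractions(records)
    wt = wt_overlap_fractions(records)
    hist = decade_histogram(records)
    split = low_high_split(records)
    summary = {
        "n_called": n_called,
        "n_transcribed": int(transcribed_mask.sum()),
        "transcribed_percent": round1(100.0 * transcribed_mask.mean()),
        "insertion_types": {
            t: {
                "count": int(tf.loc[t, "count"]),
                "percent": float(tf.loc[t, "percent"]),
                "transcribed": int(tf.loc[t, "transcribed"]),
                "transcribed_fraction": None
                if pd.isna(tf.loc[t, "transcribed_fraction"])
                else float(tf.loc[t, "transcribed_fraction"]),
            }
            for t in INSERTION_TYPES
        },
        "wt_overlap": wt,
        "decade_histogram": {
            t: {str(b): int(hist[("count", t)].loc[b]) for b in hist.index}
            for t in INSERTION_TYPES
        },
        "low_high_split": {
            t: {
                "n_transcribed": int(split.loc[t, "n_transcribed"]),
                "lower": None if pd.isna(split.loc[t, "lower"]) else float(split.loc[t, "lower"]),
                "higher": None if pd.isna(split.loc[t, "higher"]) else float(split.loc[t, "higher"]),
            }
            for t in INSERTION_TYPES
        },
    }
    n_transcribed = int(transcribed_mask.sum())
    if n_transcribed >= 3:
        bins = percentile_bins(records.loc[transcribed_mask, "level"].tolist())
        summary["percentile_bins"] = {
            b: bins.count(b) for b in ("High", "Mid", "Low")
        }
    type_i = records[records["wt_type"] == "i"]
    if len(type_i) >= 3:
        rho, p = spearman_vs_wt(records)
        summary["spearman_level_vs_wt_fpkm"] = {
            "rho": None if math.isnan(rho) else rho,
            "p": None if math.isnan(p) else p,
            "n": len(type_i),
        }
    return summary
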