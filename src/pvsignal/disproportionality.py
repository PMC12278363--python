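"""Reporting odds ratio (ROR) disproportionality analysis.

For each drug, deduplicated cases are cross-classified against a target
event group:

======================  ============  ==================
                        target cases  all other AE cases
======================  ============  ==================
exposed to the drug          a                b
all other drugs              c                d
======================  ============  ==================

ROR = ad/bc with Woolf 95% CI ``exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d))``.
A drug is a signal when, conjunctively: a ≥ 3, a exceeds the report-count
gate (default: strictly more than 100 target-event reports), the CI lower
bound (ROR_025) exceeds 1, and the Bonferroni-adjusted Pearson chi-square
p-value is below 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, ZeroCellError

__all__ = [
    "ContingencyTable",
    "ScreenThresholds",
    "build_contingency",
    "compute_ror",
    "chi_square",
    "bonferroni_adjust",
    "tabulate_exposure_event",
    "ror_stats_arrays",
    "chi_square_arrays",
    "analyze",
    "screen_signals",
    "volcano_table",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug x target-event counts over deduplicated cases."""

    a: int  # exposed, target event
    b: int  # exposed, other event
    c: int  # not exposed, target event
    d: int  # not exposed, other event

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {cell} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ScreenThresholds:
    """Signal-screen gates; defaults follow the standard screening cascade."""

    min_a: int = 3                # a >= min_a
    min_reports: int = 100        # a > min_reports (strict by default)
    ror_lower_gt: float = 1.0     # ROR_025 > this
    p_adjust_lt: float = 0.01     # Bonferroni-adjusted p < this
    count_rule: str = "gt"        # 'gt' (strictly more than) or 'ge'

    def __post_init__(self) -> None:
        if self.min_a < 0 or self.min_reports < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0 < self.p_adjust_lt <= 1:
            raise ValueError("p_adjust_lt must be in (0, 1]")
        if self.count_rule not in ("gt", "ge"):
            raise ValueError("count_rule must be 'gt' or 'ge'")

    def passes(self, a, ror_lower, p_adjust):
        """Vectorised conjunction of all four gates."""
        a = np.asarray(a, dtype=float)
        rl = np.asarray(ror_lower, dtype=float)
        p = np.asarray(p_adjust, dtype=float)
        count_ok = a > self.min_reports if self.count_rule == "gt" \
            else a >= self.min_reports
        with np.errstate(invalid="ignore"):
            return ((a >= self.min_a) & count_ok
                    & (rl > self.ror_lower_gt) & (p < self.p_adjust_lt))


def build_contingency(exposed: Sequence[bool],
                      event: Sequence[bool]) -> ContingencyTable:
    """Tally the 2x2 table from per-case (exposed, target-event) flags."""
    exposed = np.asarray(exposed, dtype=bool)
    event = np.asarray(event, dtype=bool)
    if exposed.size == 0 or exposed.shape != event.shape:
        raise ValueError("need one (exposed, event) flag pair per case")
    a = int(np.sum(exposed & event))
    b = int(np.sum(exposed & ~event))
    c = int(np.sum(~exposed & event))
    d = int(np.sum(~exposed & ~event))
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable, haldane: bool = False
                ) -> tuple[float, float, float]:
    """ROR point estimate with Woolf 95% CI.

    With ``haldane=True``, 0.5 is added to every cell (Haldane–Anscombe)
    so zero cells remain defined; otherwise a zero cell raises
    :class:`ZeroCellError` naming the offending cell.
    """
    cells = {"a": float(table.a), "b": float(table.b),
             "c": float(table.c), "d": float(table.d)}
    if haldane:
        cells = {k: v + 0.5 for k, v in cells.items()}
    for name, v in cells.items():
        if v == 0:
            raise ZeroCellError(
                f"cell {name} is zero; ROR undefined without continuity "
                "correction")
    a, b, c, d = cells["a"], cells["b"], cells["c"], cells["d"]
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = _Z975 * se
    return ror, ror * math.exp(-half), ror * math.exp(half)


def chi_square(table: ContingencyTable, yates: bool = False
               ) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2; Yates correction optional."""
    arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "2x2 table has an all-zero margin; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), float(p)


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """p_adj = min(1, m·p); order-preserving.  Requires m >= len(p) >= 0."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# vectorised kernels shared by analyze() and large simulation studies
# ---------------------------------------------------------------------------

def tabulate_exposure_event(exposed: np.ndarray, event: np.ndarray
                            ) -> tuple[np.ndarray, ...]:
    """Per-drug (a, b, c, d) from a case x drug boolean exposure matrix."""
    exposed = np.asarray(exposed, dtype=bool)
    event = np.asarray(event, dtype=bool)
    n = event.size
    n_event = int(event.sum())
    a = event.astype(np.int64) @ exposed.astype(np.int64)
    n_exposed = exposed.sum(axis=0)
    b = n_exposed - a
    c = n_event - a
    d = n - n_exposed - c
    return a, b, c, d


def ror_stats_arrays(a, b, c, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ROR and Woolf CI; NaN where any cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where(ok, (a * d) / (b * c), np.nan)
        se = np.where(ok, np.sqrt(1 / np.where(a > 0, a, 1)
                                  + 1 / np.where(b > 0, b, 1)
                                  + 1 / np.where(c > 0, c, 1)
                                  + 1 / np.where(d > 0, d, 1)), np.nan)
        lower = ror * np.exp(-_Z975 * se)
        upper = ror * np.exp(_Z975 * se)
    return ror, lower, upper


def chi_square_arrays(a, b, c, d, yates: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-square on 2x2 tables; NaN on degenerate margins."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    ok = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(ok, n * diff ** 2 / (r1 * r2 * c1 * c2), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def analyze(event_by_case: pd.Series, pairs: pd.DataFrame,
            thresholds: ScreenThresholds | None = None,
            yates: bool = False, family_size: int | None = None
            ) -> pd.DataFrame:
    """Per-drug signal table over all drugs with at least one target-event
    case report.

    ``event_by_case``: boolean Series indexed by caseid (all deduplicated
    cases).  ``pairs``: unique (caseid, drugname) suspect-exposure pairs
    (see :func:`pvsignal.io.suspect_pairs`).  The Bonferroni family size
    defaults to the number of drugs tested (a >= 1) for this event.
    """
    thresholds = thresholds or ScreenThresholds()
    n_total = len(event_by_case)
    n_event = int(event_by_case.sum())
    merged = pairs.merge(event_by_case.rename("event"),
                         left_on="caseid", right_index=True, how="inner")
    grp = merged.groupby("drugname")["event"]
    stats_df = grp.agg(n_exposed="size", a="sum").reset_index() \
        .rename(columns={"drugname": "drug"})
    stats_df["a"] = stats_df["a"].astype(int)
    stats_df = stats_df[stats_df["a"] >= 1].reset_index(drop=True)
    a = stats_df["a"].to_numpy()
    b = stats_df["n_exposed"].to_numpy() - a
    c = n_event - a
    d = n_total - stats_df["n_exposed"].to_numpy() - c
    ror, lower, upper = ror_stats_arrays(a, b, c, d)
    chi2, p_raw = chi_square_arrays(a, b, c, d, yates=yates)
    m = family_size if family_size is not None else max(len(stats_df), 1)
    p_adj = bonferroni_adjust(np.nan_to_num(p_raw, nan=1.0), m)
    p_adj = np.where(np.isnan(p_raw), np.nan, p_adj)
    out = pd.DataFrame({
        "drug": stats_df["drug"],
        "a": a, "b": b, "c": c, "d": d,
        "ror": ror, "ror_lower": lower, "ror_upper": upper,
        "chi2": chi2, "p_raw": p_raw, "p_adjust": p_adj,
        "n_reports": a,
        "zero_cell": (a == 0) | (b == 0) | (c == 0) | (d == 0),
    })
    out["is_signal"] = thresholds.passes(a, lower, p_adj)
    out.attrs["family_size"] = m
    out.attrs["n_cases"] = n_total
    out.attrs["n_event_cases"] = n_event
    return out.sort_values("drug", kind="mergesort").reset_index(drop=True)


def screen_signals(results: pd.DataFrame,
                   thresholds: ScreenThresholds | None = None
                   ) -> pd.DataFrame:
    """Apply the four-gate screen; return signal rows sorted by descending
    ROR (ties broken alphabetically by drug name)."""
    thresholds = thresholds or ScreenThresholds()
    out = results.copy()
    out["is_signal"] = thresholds.passes(
        out["a"], out["ror_lower"], out["p_adjust"])
    out = out[out["is_signal"]]
    return out.sort_values(["ror", "drug"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """(drug, ror, -log10 p_adjust, is_signal) rows, one per tested drug.

    p is clamped to the smallest positive normal double so the ordinate is
    always finite.
    """
    tiny = np.finfo(float).tiny
    p = np.clip(results["p_adjust"].to_numpy(dtype=float), tiny, 1.0)
    return pd.DataFrame({
        "drug": results["drug"],
        "ror": results["ror"],
        "neg_log10_p_adjust": -np.log10(p),
        "is_signal": results["is_signal"],
    })
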