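"""Time from therapy start to adverse-event onset.

One onset record is produced per (case, suspect drug) pair for target-event
cases where both the therapy start date and the event date resolve to at
least year+month precision; month-precision dates are imputed to the first
of the month (and flagged).  Pairs with missing dates, year-only dates, or a
negative start-to-event difference are excluded, with exclusion counts
reported by reason.  Summaries use the linear-interpolation quantile
convention (numpy's default).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import ReportSet, SUSPECT_ROLES

__all__ = ["compute_onset", "summarize_onset"]

_USABLE_PREC = ("day", "month")


def compute_onset(reports: ReportSet, event_flags: pd.Series,
                  roles: Sequence[str] = SUSPECT_ROLES
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Onset records for flagged cases.

    Returns ``(records, counters)`` where records has columns case_id,
    drug_name, onset_days, start_date, imputed (either date was
    month-precision) and counters tallies exclusions by reason
    (``missing_date``, ``year_precision``, ``negative_onset``).
    """
    flagged = event_flags[event_flags].index
    demo = reports.demo[reports.demo["caseid"].isin(flagged)]
    event_dates = demo.set_index("caseid")[["event_date", "event_date_prec"]]

    d = reports.drugs
    mask = d["role_cod"].fillna("").str.strip().str.upper().isin(
        [r.upper() for r in roles]) & d["caseid"].isin(flagged)
    pairs = d.loc[mask, ["caseid", "drugname", "start_date",
                         "start_date_prec"]]
    # several rows of the same drug in a case: earliest recorded start wins
    pairs = pairs.sort_values(["caseid", "drugname", "start_date"],
                              kind="mergesort")
    pairs = pairs.drop_duplicates(["caseid", "drugname"], keep="first")
    pairs = pairs.merge(event_dates, left_on="caseid", right_index=True,
                        how="left")

    counters = {"missing_date": 0, "year_precision": 0, "negative_onset": 0}
    missing = (pairs["start_date"].isna() | pairs["event_date"].isna()
               | (pairs["start_date_prec"] == "missing")
               | (pairs["event_date_prec"] == "missing"))
    counters["missing_date"] = int(missing.sum())
    pairs = pairs[~missing]
    year_only = ((pairs["start_date_prec"] == "year")
                 | (pairs["event_date_prec"] == "year"))
    counters["year_precision"] = int(year_only.sum())
    pairs = pairs[~year_only]
    days = (pairs["event_date"] - pairs["start_date"]).dt.days
    negative = days < 0
    counters["negative_onset"] = int(negative.sum())
    pairs = pairs[~negative]
    records = pd.DataFrame({
        "case_id": pairs["caseid"].to_numpy(),
        "drug_name": pairs["drugname"].to_numpy(),
        "onset_days": days[~negative].to_numpy(dtype=np.int64),
        "start_date": pairs["start_date"].to_numpy(),
        "imputed": ((pairs["start_date_prec"] == "month")
                    | (pairs["event_date_prec"] == "month")).to_numpy(),
    })
    return records.reset_index(drop=True), counters


def _quartiles(days: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(days, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


def summarize_onset(records: pd.DataFrame, by: str = "event",
                    group_name: str = "all") -> pd.DataFrame:
    """Median and IQR of onset days.

    ``by='event'`` gives a single row for the whole event group, first
    deduplicating to one record per case (the one with the earliest therapy
    start).  ``by='drug'`` gives one row per drug over (case, drug) records.
    Empty groups are omitted.  Raw day vectors for violin rendering are the
    ``records`` themselves.
    """
    if by not in ("event", "drug"):
        raise ValueError("by must be 'event' or 'drug'")
    rows = []
    if by == "event":
        if len(records):
            dedup = records.sort_values(
                ["case_id", "start_date", "drug_name"], kind="mergesort")
            dedup = dedup.drop_duplicates("case_id", keep="first")
            med, q1, q3 = _quartiles(dedup["onset_days"].to_numpy())
            rows.append((group_name, len(dedup), med, q1, q3))
    else:
        for drug, grp in records.groupby("drug_name", sort=True):
            med, q1, q3 = _quartiles(grp["onset_days"].to_numpy())
            rows.append((drug, len(grp), med, q1, q3))
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])
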