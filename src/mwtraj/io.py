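"""Probe-table input/output, validation, exclusion rules, and cohort summaries.

A probe table holds one row per experience-sampling probe.  The on-disk
dialect is a UTF-8, comma-separated CSV with a fixed header::

    participant_id,timestamp,state,not_report,rating,alcohol_flag,display_problem_flag,window_start_hour

* ``timestamp`` — ISO-8601 date-time at minute resolution (response stamp).
* ``state`` — one of ``focused``, ``mw_with_task``, ``mw_without_task``,
  ``declined``, ``invalid``.
* ``not_report`` — number of thoughts on the mind, an integer 0–10; the
  questionnaire's open-top "10+" menu item is accepted and encoded as 10.
  Empty for declined/invalid probes.
* ``rating`` — five-level scene-closeness label (``much_closer``,
  ``little_closer``, ``same``, ``little_farther``, ``much_farther``) or empty.
* ``alcohol_flag`` / ``display_problem_flag`` — ``true``/``false``.
* ``window_start_hour`` — the participant's chosen 12-h daily probing window
  start (9, 10, 11, or 12); constant within a participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    NoAnalyzableDataError,
    NotReportRangeError,
    SchemaError,
    TimestampParseError,
    ValidationError,
)

STATES = ("focused", "mw_with_task", "mw_without_task", "declined", "invalid")
ANSWERED_STATES = ("focused", "mw_with_task", "mw_without_task")
MW_STATES = ("mw_with_task", "mw_without_task")
RATINGS = ("much_closer", "little_closer", "same", "little_farther", "much_farther")
WINDOW_START_HOURS = (9, 10, 11, 12)
WINDOW_HOURS = 12

COLUMNS = [
    "participant_id",
    "timestamp",
    "state",
    "not_report",
    "rating",
    "alcohol_flag",
    "display_problem_flag",
    "window_start_hour",
]


@dataclass
class ProbeTable:
    """Validated collection of probe records plus per-participant windows.

    ``records`` is a DataFrame with the dialect's columns (typed: datetime
    timestamps, nullable-integer ``not_report``, boolean flags) sorted by
    (participant_id, timestamp).  ``windows`` maps participant id to the
    window start hour.
    """

    records: pd.DataFrame
    windows: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.windows:
            self.windows = (
                self.records.groupby("participant_id", sort=True)["window_start_hour"]
                .first()
                .astype(int)
                .to_dict()
            )
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        key = df[["participant_id", "timestamp"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate probe for participant {dup['participant_id']} at {dup['timestamp']}"
            )
        if not df.sort_values(["participant_id", "timestamp"]).index.equals(df.index):
            raise ValidationError("records not sorted by (participant_id, timestamp)")
        bad_state = ~df["state"].isin(STATES)
        if bad_state.any():
            raise SchemaError(f"unknown state label(s): {sorted(df.loc[bad_state, 'state'].unique())}")
        rated = df["rating"].notna()
        bad_rating = rated & ~df["rating"].isin(RATINGS)
        if bad_rating.any():
            raise SchemaError(f"unknown rating label(s): {sorted(df.loc[bad_rating, 'rating'].unique())}")
        nr = df["not_report"]
        out = nr.notna() & ((nr < 0) | (nr > 10))
        if out.any():
            raise NotReportRangeError(f"not_report outside 0..10 in {int(out.sum())} row(s)")
        unanswered = df["state"].isin(("declined", "invalid"))
        if (unanswered & (df["not_report"].notna() | df["rating"].notna())).any():
            raise ValidationError("declined/invalid probes must not carry not_report or rating")
        for pid, start in self.windows.items():
            if start not in WINDOW_START_HOURS:
                raise ValidationError(f"window_start_hour {start} for {pid} not in {WINDOW_START_HOURS}")
        # timestamps must fall inside the declared daily window unless declined
        sub = df[df["state"] != "declined"]
        if len(sub):
            starts = sub["participant_id"].map(self.windows)
            hours = sub["timestamp"].dt.hour + sub["timestamp"].dt.minute / 60.0
            inside = (hours >= starts) & (hours < starts + WINDOW_HOURS)
            if not inside.all():
                row = sub[~inside].iloc[0]
                raise ValidationError(
                    f"probe at {row['timestamp']} outside the daily window of {row['participant_id']}"
                )

    # ------------------------------------------------------------------
    @property
    def answered(self) -> pd.Series:
        """Boolean mask: probe was fully answered (one of the three mental states)."""
        return self.records["state"].isin(ANSWERED_STATES)

    @property
    def usable(self) -> pd.Series:
        """Answered and free of alcohol/display-problem flags."""
        return (
            self.answered
            & ~self.records["alcohol_flag"]
            & ~self.records["display_problem_flag"]
        )

    @property
    def is_mw(self) -> pd.Series:
        """Mind-wandering report, pooled over with-task/without-task."""
        return self.records["state"].isin(MW_STATES)

    def participants(self) -> list[str]:
        return sorted(self.records["participant_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


# ----------------------------------------------------------------------
# reading / writing


def _parse_not_report(raw: pd.Series) -> pd.Series:
    s = raw.astype("string").str.strip()
    s = s.replace({"": pd.NA})
    s = s.str.replace(r"^10\+$", "10", regex=True)
    bad = s.notna() & ~s.str.fullmatch(r"\d+")
    if bad.any():
        raise NotReportRangeError(
            f"unparseable not_report value(s): {sorted(s[bad].unique())}"
        )
    out = s.astype("Int64")
    oob = out.notna() & ((out < 0) | (out > 10))
    if oob.any():
        rows = list(out.index[oob][:5])
        raise NotReportRangeError(f"not_report outside 0..10 at row(s) {rows}")
    return out


def _parse_bool(raw: pd.Series, name: str) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower().replace({"": "false"})
    mapping = {"true": True, "false": False, "1": True, "0": False}
    bad = ~s.isin(mapping)
    if bad.any():
        raise SchemaError(f"unparseable boolean in column {name}: {sorted(s[bad].unique())}")
    return s.map(mapping).astype(bool)


def read_probe_table(path: str | Path) -> ProbeTable:
    """Read a probe-table CSV in the documented dialect.

    Raises :class:`FileNotFoundError`, :class:`SchemaError` (bad header or
    enum label, with the offending row), :class:`TimestampParseError`, or
    :class:`NotReportRangeError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COLUMNS:
        raise SchemaError(f"header {list(df.columns)} does not match {COLUMNS}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TimestampParseError(str(exc)) from None

    state = df["state"].str.strip()
    bad = ~state.isin(STATES)
    if bad.any():
        raise SchemaError(f"unknown state label at row(s) {list(df.index[bad][:5])}: {sorted(state[bad].unique())}")
    rating = df["rating"].str.strip().replace({"": pd.NA})
    badr = rating.notna() & ~rating.isin(RATINGS)
    if badr.any():
        raise SchemaError(
            f"unknown rating label at row(s) {list(df.index[badr][:5])}: {sorted(rating[badr].unique())}"
        )
    try:
        window = df["window_start_hour"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"unparseable window_start_hour: {exc}") from None

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].str.strip(),
            "timestamp": ts,
            "state": state,
            "not_report": _parse_not_report(df["not_report"]),
            "rating": rating,
            "alcohol_flag": _parse_bool(df["alcohol_flag"], "alcohol_flag"),
            "display_problem_flag": _parse_bool(df["display_problem_flag"], "display_problem_flag"),
            "window_start_hour": window,
        }
    )
    out = out.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    return ProbeTable(out)


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    """Write a probe table back to the documented CSV dialect (round-trip safe)."""
    df = table.records.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    df["not_report"] = df["not_report"].astype("string").fillna("")
    df["rating"] = df["rating"].astype("string").fillna("")
    for col in ("alcohol_flag", "display_problem_flag"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionReport:
    """Every removal made by :func:`apply_exclusions`, with its reason."""

    min_probes: int
    excluded_participants: list[dict] = field(default_factory=list)
    excluded_records: list[dict] = field(default_factory=list)
    n_records_before: int = 0
    n_records_after: int = 0

    def to_dict(self) -> dict:
        return {
            "min_probes": self.min_probes,
            "threshold_counts_only_answered_probes": True,
            "excluded_participants": self.excluded_participants,
            "excluded_records": self.excluded_records,
            "n_records_before": self.n_records_before,
            "n_records_after": self.n_records_after,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))

    @property
    def empty(self) -> bool:
        return not self.excluded_participants and not self.excluded_records


def apply_exclusions(table: ProbeTable, min_probes: int = 40) -> tuple[ProbeTable, ExclusionReport]:
    """Apply the cohort's exclusion rules.

    1. Participants who answered fewer than ``min_probes`` probes are removed
       entirely (only fully answered probes count toward the threshold —
       declined and invalid ones do not).
    2. ``invalid`` records (improperly received/answered probes) are dropped.
    3. Remaining records flagged for alcohol or display problems are dropped
       individually.

    Declined probes are retained; they are simply never ``usable``.  The
    returned report lists every removal with its reason.  Idempotent.
    """
    report = ExclusionReport(min_probes=min_probes, n_records_before=len(table))
    df = table.records

    answered_counts = (
        df[df["state"].isin(ANSWERED_STATES)].groupby("participant_id").size()
    )
    keep_participants = set()
    for pid in df["participant_id"].unique():
        n = int(answered_counts.get(pid, 0))
        if n < min_probes:
            report.excluded_participants.append(
                {"participant_id": pid, "answered_probes": n, "reason": f"fewer than {min_probes} answered probes"}
            )
        else:
            keep_participants.add(pid)

    df = df[df["participant_id"].isin(keep_participants)]

    for maskfn, reason in (
        (lambda d: d["state"] == "invalid", "invalid response"),
        (lambda d: d["alcohol_flag"], "alcohol or substance influence"),
        (lambda d: d["display_problem_flag"], "display problem during the rating task"),
    ):
        mask = maskfn(df)
        for _, row in df[mask].iterrows():
            report.excluded_records.append(
                {
                    "participant_id": row["participant_id"],
                    "timestamp": str(row["timestamp"]),
                    "reason": reason,
                }
            )
        df = df[~mask]

    df = df.reset_index(drop=True)
    report.n_records_after = len(df)
    if not df["state"].isin(ANSWERED_STATES).any():
        raise NoAnalyzableDataError("no analyzable data remain after exclusions")
    windows = {p: w for p, w in table.windows.items() if p in keep_participants}
    return ProbeTable(df, windows), report


# ----------------------------------------------------------------------
# cohort summary


@dataclass
class CohortSummary:
    n_participants: int
    valid_probes: int
    per_participant_counts: dict[str, int]
    proportions: dict[str, float]  # grand averages over participants

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "valid_probes": self.valid_probes,
            "per_participant_counts": self.per_participant_counts,
            "proportions": self.proportions,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = [{"participant_id": p, "valid_probes": n} for p, n in self.per_participant_counts.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def summarize_cohort(table: ProbeTable) -> CohortSummary:
    """State proportions per participant, then grand-averaged across participants.

    Proportions are computed over each participant's usable (answered,
    unflagged) probes; declined probes enter neither numerator nor
    denominator.  The cohort figure is the unweighted mean of the
    per-participant fractions, so participants — not probes — carry equal
    weight.
    """
    df = table.records[table.usable]
    counts = df.groupby("participant_id").size()
    for pid in table.records["participant_id"].unique():
        if int(counts.get(pid, 0)) == 0:
            raise NoAnalyzableDataError(
                f"participant {pid} has zero answered probes (should have been excluded)"
            )
    per_state = (
        df.groupby(["participant_id", "state"]).size().unstack(fill_value=0).reindex(columns=ANSWERED_STATES, fill_value=0)
    )
    frac = per_state.div(per_state.sum(axis=1), axis=0)
    grand = frac.mean(axis=0)
    proportions = {
        "focused": float(grand["focused"]),
        "mw_with_task": float(grand["mw_with_task"]),
        "mw_without_task": float(grand["mw_without_task"]),
        "mw_pooled": float(grand["mw_with_task"] + grand["mw_without_task"]),
    }
    return CohortSummary(
        n_participants=int(per_state.shape[0]),
        valid_probes=int(len(df)),
        per_participant_counts={str(p): int(n) for p, n in counts.items()},
        proportions=proportions,
    )
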