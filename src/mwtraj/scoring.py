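"""R-score encoding, per-participant summaries, d-standardization, and
state comparisons.

The five-level scene-closeness rating is encoded as an integer R score:
``much_closer`` -> -2, ``little_closer`` -> -1, ``same`` -> 0,
``little_farther`` -> 1, ``much_farther`` -> 2.  Zero is the veridical
default; non-zero values indicate a top-down response bias read as
deliberate-constraint (cognitive-control) strength.  Because non-same
responses are rare, state contrasts focus on the per-participant extreme
values (minimum and maximum) of the R-score distribution, compared with the
Brunner–Munzel rank test; numbers of thoughts (NoT) are compared with a
paired t-test on per-participant state means.

d-standardization subtracts a per-participant reference statistic (their
own minimum, mean, or maximum) from each raw value, yielding dMin, dMean,
and dMax variants of both measures.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, NoAnalyzableDataError, ParameterError
from .io import MW_STATES, ProbeTable

RATING_TO_SCORE = {
    "much_closer": -2,
    "little_closer": -1,
    "same": 0,
    "little_farther": 1,
    "much_farther": 2,
}

REFERENCES = ("min", "mean", "max")


def rating_to_score(rating: str | None) -> int | None:
    """Encode one closeness label; a missing rating stays missing."""
    if rating is None or (isinstance(rating, float) and np.isnan(rating)) or rating is pd.NA:
        return None
    try:
        return RATING_TO_SCORE[rating]
    except KeyError:
        raise ParameterError(f"unknown rating label: {rating!r}") from None


def score_ratings(table: ProbeTable) -> pd.Series:
    """R scores aligned to ``table.records``; unusable/unrated probes are NaN."""
    scores = table.records["rating"].map(RATING_TO_SCORE).astype("Float64")
    return scores.where(table.usable).astype(float)


def not_values(table: ProbeTable) -> pd.Series:
    """NoT reports aligned to ``table.records``; unusable probes are NaN."""
    return table.records["not_report"].astype("Float64").where(table.usable).astype(float)


# ----------------------------------------------------------------------
# per-participant summaries and standardization


def participant_summaries(table: ProbeTable) -> pd.DataFrame:
    """Min/mean/max of R scores and NoTs over each participant's usable probes.

    Indexed by participant_id with columns ``r_min, r_mean, r_max, not_min,
    not_mean, not_max, n_probes``.
    """
    df = pd.DataFrame(
        {
            "participant_id": table.records["participant_id"],
            "r": score_ratings(table),
            "nt": not_values(table),
        }
    ).dropna(subset=["r", "nt"], how="all")
    if df.empty:
        raise NoAnalyzableDataError("no scored probes to summarize")
    g = df.groupby("participant_id")
    out = pd.DataFrame(
        {
            "r_min": g["r"].min(),
            "r_mean": g["r"].mean(),
            "r_max": g["r"].max(),
            "not_min": g["nt"].min(),
            "not_mean": g["nt"].mean(),
            "not_max": g["nt"].max(),
            "n_probes": g.size(),
        }
    )
    bad = out[["r_min", "not_min"]].isna().any(axis=1)
    if bad.any():
        raise NoAnalyzableDataError(
            f"participant(s) without scored probes: {list(out.index[bad])}"
        )
    return out


def standardize(values: pd.Series, participant_ids: pd.Series,
                summaries: pd.DataFrame, measure: str, reference: str) -> pd.Series:
    """d-standardize per-probe values: raw minus the participant's own
    reference statistic (``min``, ``mean``, or ``max``) of that measure.

    ``measure`` is ``"r"`` or ``"not"``; missing raw values stay missing.
    """
    if reference not in REFERENCES:
        raise ParameterError(f"reference must be one of {REFERENCES}")
    col = f"{measure}_{reference}"
    if col not in summaries.columns:
        raise ParameterError(f"summary column {col!r} missing")
    ref = participant_ids.map(summaries[col])
    if (values.notna() & ref.isna()).any():
        raise ParameterError("values present for a participant missing from the summaries")
    return values - ref


# ----------------------------------------------------------------------
# Brunner–Munzel


@dataclass
class TestResult:
    """Two-sample test outcome in the reporting form 'stat (df) , p'."""

    statistic: float
    df: float
    p_value: float
    relative_effect: float | None = None  # P(X < Y) + 0.5 P(X = Y)

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}
        if self.relative_effect is not None:
            d["relative_effect"] = self.relative_effect
        return d


def brunner_munzel(x, y) -> TestResult:
    """Brunner–Munzel test for the relative effect p = P(X < Y) + 0.5 P(X = Y).

    Midranks handle ties; the statistic is studentized with separate rank
    variances and referred to a t distribution with Welch-type estimated
    degrees of freedom.  Positive statistics mean ``y`` tends to be larger.
    Raises :class:`DegenerateDataError` when both rank variances vanish
    (all values identical across the two samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("each sample needs at least two values")
    N = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1, r2 = ranks[:n1], ranks[n1:]
    r1_int = sps.rankdata(x)
    r2_int = sps.rankdata(y)
    m1, m2 = r1.mean(), r2.mean()
    p_hat = (m2 - (n2 + 1) / 2) / n1

    v1 = np.sum((r1 - r1_int - m1 + (n1 + 1) / 2) ** 2) / (n1 - 1)
    v2 = np.sum((r2 - r2_int - m2 + (n2 + 1) / 2) ** 2) / (n2 - 1)
    denom = n1 * v1 + n2 * v2
    if denom <= 0:
        if np.unique(np.concatenate([x, y])).size == 1:
            raise DegenerateDataError("all values identical across both samples")
        # complete separation: the relative effect is exactly 0 or 1 and the
        # studentized statistic diverges
        sign = np.sign(m2 - m1)
        return TestResult(statistic=float(sign * np.inf), df=float("nan"),
                          p_value=0.0, relative_effect=float(p_hat))
    statistic = n1 * n2 * (m2 - m1) / (N * np.sqrt(denom))
    df = denom ** 2 / ((n1 * v1) ** 2 / (n1 - 1) + (n2 * v2) ** 2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(statistic), df)
    return TestResult(statistic=float(statistic), df=float(df),
                      p_value=float(p), relative_effect=float(p_hat))


def relative_effect_bruteforce(x, y) -> float:
    """O(n*m) pair-count oracle for the Brunner–Munzel relative effect."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(((x < y).sum() + 0.5 * (x == y).sum()) / (x.size * y.size))


# ----------------------------------------------------------------------
# state comparison


@dataclass
class StateComparison:
    """Mind-wandering vs focused contrast: paired t on NoT means, and
    Brunner–Munzel on per-participant per-state R extremes."""

    not_t: TestResult
    not_mean_mw: float
    not_mean_focused: float
    n_pairs: int
    dropped_from_t: list[str]
    r_extremes: dict[str, TestResult]  # keys: min, mean, max
    n_mw: int
    n_focused: int

    def to_dict(self) -> dict:
        return {
            "not_paired_t": {
                **self.not_t.to_dict(),
                "mean_not_mw": self.not_mean_mw,
                "mean_not_focused": self.not_mean_focused,
                "n_pairs": self.n_pairs,
                "dropped_participants": self.dropped_from_t,
            },
            "r_extremes_brunner_munzel": {k: v.to_dict() for k, v in self.r_extremes.items()},
            "n_participants_mw": self.n_mw,
            "n_participants_focused": self.n_focused,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compare_states(table: ProbeTable) -> StateComparison:
    """Compare mind-wandering (pooled with/without task) and focused states.

    NoT: each participant's mean NoT per state; paired t-test across
    participants having both states (those lacking one are dropped and
    reported).  R scores: each participant's min/mean/max within each state;
    for each statistic the two participant-level distributions are compared
    with the Brunner–Munzel test, ordered (focused, mind-wandering) so a
    positive statistic means larger values while mind wandering.
    """
    rec = table.records[table.usable]
    df = pd.DataFrame(
        {
            "participant_id": rec["participant_id"],
            "mw": rec["state"].isin(MW_STATES),
            "nt": rec["not_report"].astype(float),
            "r": rec["rating"].map(RATING_TO_SCORE).astype(float),
        }
    )
    if df.empty:
        raise NoAnalyzableDataError("no usable probes")

    nt = df.pivot_table(index="participant_id", columns="mw", values="nt", aggfunc="mean")
    nt = nt.reindex(columns=[False, True])
    complete = nt.dropna()
    if len(complete) < 2:
        raise DegenerateDataError("fewer than two participants with both states")
    dropped = sorted(set(nt.index) - set(complete.index))
    diffs = (complete[True] - complete[False]).to_numpy()
    if np.allclose(diffs.std(ddof=1), 0.0):
        # zero-variance differences: t is 0 when the means agree exactly
        t_stat = 0.0 if np.allclose(diffs.mean(), 0.0) else np.inf * np.sign(diffs.mean())
        t_p = 1.0 if t_stat == 0.0 else 0.0
    else:
        t_stat, t_p = sps.ttest_rel(complete[True], complete[False])
    not_t = TestResult(statistic=float(t_stat), df=float(len(complete) - 1), p_value=float(t_p))

    g = df.groupby(["participant_id", "mw"])["r"]
    per_state = pd.DataFrame({"min": g.min(), "mean": g.mean(), "max": g.max()}).reset_index()
    fc = per_state[~per_state["mw"]]
    mw = per_state[per_state["mw"]]
    extremes = {
        stat: brunner_munzel(fc[stat].dropna(), mw[stat].dropna())
        for stat in ("min", "mean", "max")
    }
    return StateComparison(
        not_t=not_t,
        not_mean_mw=float(complete[True].mean()),
        not_mean_focused=float(complete[False].mean()),
        n_pairs=int(len(complete)),
        dropped_from_t=[str(p) for p in dropped],
        r_extremes=extremes,
        n_mw=int(mw["min"].notna().sum()),
        n_focused=int(fc["min"].notna().sum()),
    )
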