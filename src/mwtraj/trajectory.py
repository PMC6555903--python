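"""Event-locked segmentation, hourly binning, cluster-bootstrap percentile
normalization, and 2D trajectory assembly.

Each mind-wandering probe anchors a segment spanning a 17-hour window from
8 hours before to 9 hours after the report.  Probes are assigned to
half-open one-hour bins: a probe at offset ``delta`` hours from the
reference falls in bin ``k`` iff ``k <= delta < k + 1``, for
``k in {-8..8}``; the reference itself sits in bin 0.  Segments never
bridge calendar days — only probes from the reference probe's own probing
day are members — and the same probe may appear in several segments when
mind wandering recurs within a day.

Within each participant, values landing in a bin (across all of their
segments) are averaged first; the grand average per bin is the unweighted
mean over participants contributing to that bin.  Because participants
contribute unevenly across bins and their probes are temporally dependent,
uncertainty is quantified with a cluster bootstrap: whole participants are
resampled with replacement and every bin's grand average is recomputed from
the resampled participants' bin means.  Each observed grand average is then
converted to a percentile (midrank convention) within the distribution
pooled over all 17 bins' resampled grand averages, placing every bin on a
common 0–100 scale so bins can be compared — the event-locked signal shows
up as bins in the tails of that pooled distribution.

The trajectory pairs the NoT percentile series (vertical axis, dMean by
default) with the R-score percentile series (horizontal axis, dMin by
default); inter-individual variability around each trajectory point is a
leave-one-participant-out jackknife radius in percentile coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySegmentsError, ParameterError
from .io import ProbeTable

DEFAULT_PRE_HOURS = 8
DEFAULT_POST_HOURS = 9


def default_bins(pre_hours: int = DEFAULT_PRE_HOURS, post_hours: int = DEFAULT_POST_HOURS) -> list[int]:
    return list(range(-pre_hours, post_hours))


# ----------------------------------------------------------------------
# segmentation


@dataclass
class Segments:
    """Long-format membership table: one row per (segment, member probe).

    ``frame`` columns: participant_id, segment_id, ref_time, probe_time,
    bin, is_mw, plus one column per attached value measure.
    """

    frame: pd.DataFrame
    pre_hours: int = DEFAULT_PRE_HOURS
    post_hours: int = DEFAULT_POST_HOURS
    value_columns: list[str] = field(default_factory=list)

    @property
    def bins(self) -> list[int]:
        return default_bins(self.pre_hours, self.post_hours)

    @property
    def n_segments(self) -> int:
        return self.frame["segment_id"].nunique()


def segment_events(table: ProbeTable, values: pd.DataFrame | pd.Series | None = None,
                   pre_hours: int = DEFAULT_PRE_HOURS,
                   post_hours: int = DEFAULT_POST_HOURS) -> Segments:
    """Cut one segment per usable mind-wandering probe (pooled with/without
    task) and attach ``values`` (aligned to ``table.records``) to members.

    Members are the participant's usable probes on the same calendar probing
    day whose offset lies in ``[-pre_hours, post_hours)``.  Raises
    :class:`EmptySegmentsError` when no mind-wandering probe exists.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame("value")
    rec = table.records
    usable = table.usable
    probes = pd.DataFrame(
        {
            "participant_id": rec["participant_id"],
            "probe_time": rec["timestamp"],
            "day": rec["timestamp"].dt.normalize(),
            "is_mw": table.is_mw,
        }
    )[usable]
    if values is not None:
        if not values.index.equals(rec.index):
            raise ParameterError("values must be aligned to table.records")
        for col in values.columns:
            probes[col] = values[col]

    refs = probes[probes["is_mw"]][["participant_id", "probe_time", "day"]].rename(
        columns={"probe_time": "ref_time"}
    )
    if refs.empty:
        raise EmptySegmentsError(
            "no mind-wandering probes to anchor segments; "
            "check state labels and exclusion settings"
        )
    refs = refs.reset_index(drop=True)
    refs["segment_id"] = refs.index

    merged = refs.merge(probes, on=["participant_id", "day"])
    delta = (merged["probe_time"] - merged["ref_time"]).dt.total_seconds() / 3600.0
    merged["bin"] = np.floor(delta).astype(int)
    merged = merged[(merged["bin"] >= -pre_hours) & (merged["bin"] <= post_hours - 1)]
    cols = ["participant_id", "segment_id", "ref_time", "probe_time", "bin", "is_mw"]
    vcols = list(values.columns) if values is not None else []
    return Segments(
        frame=merged[cols + vcols].reset_index(drop=True),
        pre_hours=pre_hours,
        post_hours=post_hours,
        value_columns=vcols,
    )


# ----------------------------------------------------------------------
# binning and grand averages


@dataclass
class BinnedSeries:
    """Per-participant bin means plus the cross-participant grand average."""

    participant_bin_means: pd.DataFrame  # index participant, columns bins
    grand_average: pd.Series
    n_participants: pd.Series

    @property
    def bins(self) -> list[int]:
        return list(self.participant_bin_means.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grand_average": self.grand_average, "n_participants": self.n_participants}
        ).rename_axis("bin")


def bin_and_average(segments: Segments, column: str = "value") -> BinnedSeries:
    """Pool each participant's values per bin (across all their segments),
    then grand-average over contributing participants, unweighted."""
    df = segments.frame.dropna(subset=[column])
    means = (
        df.groupby(["participant_id", "bin"])[column]
        .mean()
        .unstack("bin")
        .reindex(columns=segments.bins)
    )
    grand = means.mean(axis=0)
    counts = means.notna().sum(axis=0).astype(int)
    return BinnedSeries(participant_bin_means=means, grand_average=grand, n_participants=counts)


# ----------------------------------------------------------------------
# homogeneity of mind-wandering placement


@dataclass
class MWProbabilityResult:
    """Per-bin mind-wandering probability and its homogeneity check."""

    participant_probabilities: pd.DataFrame
    grand_average: pd.Series
    sd: pd.Series
    anova: dict | None  # F, df_num, df_den, p_value, n_participants (complete cases)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grand_average": self.grand_average,
                "sd": self.sd,
                "n_participants": self.participant_probabilities.notna().sum(axis=0).astype(int),
            }
        ).rename_axis("bin")


def mw_probability_series(segments: Segments) -> MWProbabilityResult:
    """Average probability of a mind-wandering report per bin, and a
    repeated-measures one-way ANOVA over the 16 non-reference bins.

    Bin 0 holds the reference probes and is excluded from the test.  Only
    participants with a probability in every non-reference bin (complete
    cases) enter the ANOVA; with fewer than two such participants the test
    is skipped with a warning.  Because per-bin proportions have unequal
    precision and shared probes correlate neighbouring bins, sphericity is
    not tenable and the Greenhouse–Geisser corrected p-value is reported
    (the uncorrected one is kept alongside).
    """
    df = segments.frame
    probs = (
        df.groupby(["participant_id", "bin"])["is_mw"]
        .mean()
        .unstack("bin")
        .reindex(columns=segments.bins)
    )
    grand = probs.mean(axis=0)
    sd = probs.std(axis=0, ddof=1)

    nonzero = [b for b in segments.bins if b != 0]
    complete = probs[nonzero].dropna()
    anova = None
    if len(complete) < 2:
        warnings.warn("homogeneity ANOVA skipped: fewer than 2 complete-case participants")
    else:
        long = complete.stack().rename("p").reset_index()
        long.columns = ["participant_id", "bin", "p"]
        # exact zero between-bin variance -> F is 0 by definition, even when
        # the interaction term also vanishes
        bin_means = complete.mean(axis=0)
        ss_bins = float(len(complete) * ((bin_means - bin_means.mean()) ** 2).sum())
        if ss_bins < 1e-24:
            anova = {
                "F": 0.0,
                "df_num": float(len(nonzero) - 1),
                "df_den": float((len(nonzero) - 1) * (len(complete) - 1)),
                "p_value": 1.0,
                "p_uncorrected": 1.0,
                "gg_epsilon": float("nan"),
                "n_participants": int(len(complete)),
            }
        else:
            import pingouin as pg  # deferred: slow import

            res = pg.rm_anova(data=long, dv="p", within="bin",
                              subject="participant_id", correction=True)
            row = res.iloc[0]
            p_gg = row.get("p_GG_corr", np.nan)
            anova = {
                "F": float(row["F"]),
                "df_num": float(row["ddof1"]),
                "df_den": float(row["ddof2"]),
                "p_value": float(p_gg) if np.isfinite(p_gg) else float(row["p_unc"]),
                "p_uncorrected": float(row["p_unc"]),
                "gg_epsilon": float(row.get("eps", np.nan)),
                "n_participants": int(len(complete)),
            }
    return MWProbabilityResult(
        participant_probabilities=probs, grand_average=grand, sd=sd, anova=anova
    )


# ----------------------------------------------------------------------
# cluster bootstrap percentiles


@dataclass
class BootstrapDist:
    """Resampled grand averages: one column per bin, one row per replicate."""

    samples: pd.DataFrame
    B: int
    seed: int | np.random.SeedSequence

    def pooled(self) -> np.ndarray:
        vals = self.samples.to_numpy().ravel()
        return vals[~np.isnan(vals)]


def _resampled_grand_averages(M: np.ndarray, B: int,
                              rng: np.random.Generator) -> np.ndarray:
    """B cluster resamples of the per-bin grand average (participants drawn
    with replacement; a resampled participant lacking a bin contributes
    nothing to it)."""
    n = M.shape[0]
    S = np.nan_to_num(M, nan=0.0)
    C = ~np.isnan(M)
    idx = rng.integers(0, n, size=(B, n))
    sums = S[idx].sum(axis=1)
    counts = C[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = sums / counts
    G[counts == 0] = np.nan
    return G


def bootstrap_percentiles(binned: BinnedSeries, B: int = 2000,
                          seed: int | np.random.SeedSequence = 0) -> tuple[pd.Series, BootstrapDist]:
    """Percentile-normalize a binned series against its cluster bootstrap.

    Draws ``B`` resamples of the cohort (participants with replacement) and
    recomputes every bin's grand average per resample.  The observed grand
    average of each bin is assigned its midrank percentile,
    ``100 * (#below + 0.5 * #ties) / #resampled values``, within the
    distribution pooled across all bins' resampled grand averages, so the
    percentiles of different bins share one reference scale.  Bins with no
    contributing participant get a missing percentile.  Bitwise reproducible
    from ``(input, B, seed)``.
    """
    M = binned.participant_bin_means.to_numpy(dtype=float)
    if M.shape[0] == 0:
        raise ParameterError("binned series has no participants")
    rng = np.random.default_rng(seed)
    G = _resampled_grand_averages(M, B, rng)
    ref = np.sort(G[~np.isnan(G)])
    obs = binned.grand_average.to_numpy(dtype=float)
    lo = np.searchsorted(ref, obs, side="left")
    hi = np.searchsorted(ref, obs, side="right")
    pct = 100.0 * (lo + 0.5 * (hi - lo)) / len(ref)
    pct = np.where(np.isnan(obs), np.nan, pct)
    percentiles = pd.Series(pct, index=binned.grand_average.index, name="percentile")
    dist = BootstrapDist(
        samples=pd.DataFrame(G, columns=binned.grand_average.index), B=B, seed=seed
    )
    return percentiles, dist


# ----------------------------------------------------------------------
# trajectory and inter-individual variability


@dataclass
class Trajectory:
    """Ordered 17-point trajectory in (R percentile, NoT percentile) space."""

    points: pd.DataFrame  # index bin; columns r_pct, not_pct, radius, complete, counts
    r_measure: str = "dmin_r"
    not_measure: str = "dmean_not"

    def to_csv(self, path: str | Path) -> None:
        self.points.to_csv(path)

    @property
    def complete_points(self) -> pd.DataFrame:
        return self.points[self.points["complete"]]


def build_trajectory(not_pct: pd.Series, r_pct: pd.Series,
                     radii: pd.Series | None = None,
                     n_participants_not: pd.Series | None = None,
                     n_participants_r: pd.Series | None = None,
                     r_measure: str = "dmin_r",
                     not_measure: str = "dmean_not") -> Trajectory:
    """Pair the two percentile series into trajectory points.

    Points with either axis missing are flagged (``complete = False``),
    never interpolated.  Raises on mismatched bin axes.
    """
    if not not_pct.index.equals(r_pct.index):
        raise ParameterError("percentile series are on different bin axes")
    pts = pd.DataFrame({"r_pct": r_pct, "not_pct": not_pct}).rename_axis("bin")
    pts["radius"] = radii if radii is not None else np.nan
    pts["n_participants_not"] = (
        n_participants_not if n_participants_not is not None else pd.Series(dtype=int)
    )
    pts["n_participants_r"] = (
        n_participants_r if n_participants_r is not None else pd.Series(dtype=int)
    )
    pts["complete"] = pts["r_pct"].notna() & pts["not_pct"].notna()
    return Trajectory(points=pts, r_measure=r_measure, not_measure=not_measure)


def interindividual_variability(binned_not: BinnedSeries, binned_r: BinnedSeries,
                                B: int = 2000, seed: int = 0,
                                min_participants: int = 3) -> pd.Series:
    """Leave-one-participant-out jackknife radius per bin.

    For each participant, both percentile series are recomputed without
    them; the radius of a bin is the root-mean-square Euclidean distance,
    in percentile coordinates, between the full-cohort trajectory point and
    the leave-one-out points.  Bins where fewer than ``min_participants``
    participants contribute (to either measure) get a missing radius.
    """
    if not binned_not.grand_average.index.equals(binned_r.grand_average.index):
        raise ParameterError("binned series are on different bin axes")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + 1)  # full run + a stream to split for LOO runs
    full_not, _ = bootstrap_percentiles(binned_not, B, children[0])
    full_r, _ = bootstrap_percentiles(binned_r, B, children[0])

    participants = sorted(
        set(binned_not.participant_bin_means.index) | set(binned_r.participant_bin_means.index)
    )
    loo_seeds = children[1].spawn(len(participants))

    def drop(binned: BinnedSeries, pid) -> BinnedSeries:
        m = binned.participant_bin_means.drop(index=pid, errors="ignore")
        return BinnedSeries(
            participant_bin_means=m,
            grand_average=m.mean(axis=0),
            n_participants=m.notna().sum(axis=0).astype(int),
        )

    sq = np.zeros(len(full_not))
    cnt = np.zeros(len(full_not))
    for pid, child in zip(participants, loo_seeds):
        p_not, _ = bootstrap_percentiles(drop(binned_not, pid), B, child)
        p_r, _ = bootstrap_percentiles(drop(binned_r, pid), B, child)
        d2 = (p_not - full_not) ** 2 + (p_r - full_r) ** 2
        ok = d2.notna().to_numpy()
        sq[ok] += d2.to_numpy()[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        radii = np.sqrt(sq / cnt)
    contributing = np.minimum(
        binned_not.n_participants.to_numpy(), binned_r.n_participants.to_numpy()
    )
    radii = np.where((contributing < min_participants) | (cnt == 0), np.nan, radii)
    return pd.Series(radii, index=full_not.index, name="radius")


def binned_d_series(table: ProbeTable, measure: str, reference: str,
                    pre_hours: int = DEFAULT_PRE_HOURS,
                    post_hours: int = DEFAULT_POST_HOURS) -> BinnedSeries:
    """Convenience path from a cleaned probe table to one binned d-series.

    ``measure`` is ``"r"`` or ``"not"``; ``reference`` is the d-variant
    (``min``/``mean``/``max``).  Standardizes per participant, segments
    around mind-wandering probes, and bins.
    """
    from . import scoring

    summaries = scoring.participant_summaries(table)
    values = scoring.score_ratings(table) if measure == "r" else scoring.not_values(table)
    d = scoring.standardize(values, table.records["participant_id"],
                            summaries, measure, reference)
    segments = segment_events(table, d.to_frame("d"), pre_hours, post_hours)
    return bin_and_average(segments, "d")


# ----------------------------------------------------------------------
# period diagnostics


def autocorrelation(values: pd.Series | np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Missing-data-aware sample autocorrelation at lags 0..max_lag."""
    x = np.asarray(values, dtype=float)
    x = x - np.nanmean(x)
    n = len(x)
    if max_lag is None:
        max_lag = n - 2
    var = np.nanmean(x * x)
    out = np.full(max_lag + 1, np.nan)
    for h in range(max_lag + 1):
        prod = x[: n - h] * x[h:]
        if np.isfinite(prod).any() and var > 0:
            out[h] = np.nanmean(prod) / var
    return out


def first_autocorr_peak_lag(values: pd.Series | np.ndarray,
                            max_lag: int | None = None) -> int | None:
    """Lag of the first positive-lag local maximum of the autocorrelation.

    Used to read an oscillation period off a regularly sampled series (one
    sample per hour for binned series).  Falls back to the argmax over
    lags >= 2 when no interior local peak exists; returns None for flat or
    too-short series.
    """
    ac = autocorrelation(values, max_lag)
    if len(ac) < 4 or not np.isfinite(ac[1:]).any():
        return None
    for h in range(2, len(ac) - 1):
        if np.isfinite(ac[h - 1 : h + 2]).all() and ac[h - 1] < ac[h] >= ac[h + 1]:
            return h
    interior = ac.copy()
    interior[:2] = -np.inf
    if np.isfinite(interior[2:]).any():
        return int(np.nanargmax(interior))
    return None
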