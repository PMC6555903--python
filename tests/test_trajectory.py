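"""Event-locked segmentation, binning, bootstrap percentiles, trajectory."""

import numpy as np
import pandas as pd
import pytest

import mwtraj as m
from mwtraj.errors import EmptySegmentsError, ParameterError
from mwtraj.trajectory import (
    BinnedSeries,
    Segments,
    bin_and_average,
    bootstrap_percentiles,
    build_trajectory,
    default_bins,
    first_autocorr_peak_lag,
    interindividual_variability,
    mw_probability_series,
    segment_events,
)
from mwtraj import scoring
from mwtraj import trajectory as traj

from conftest import make_table


def _values(table):
    """Attach the raw R score as the segmented value."""
    return scoring.score_ratings(table).to_frame("value")


def test_half_open_hour_bin_assignment():
    table = make_table(
        [
            ("A", "2017-02-06T12:30", "focused", 1, "same"),      # -0.5 h -> bin -1
            ("A", "2017-02-06T13:00", "mw_with_task", 5, "same"),  # reference
            ("A", "2017-02-06T13:30", "focused", 1, "same"),      # +0.5 h -> bin 0
            ("A", "2017-02-06T21:59", "focused", 1, "same"),      # +8h59 -> bin 8
            ("A", "2017-02-06T22:01", "focused", 1, "same"),      # +9h01 -> excluded
        ],
        window=12,
    )
    segs = segment_events(table, _values(table))
    one = segs.frame[segs.frame["segment_id"] == 0]
    got = dict(zip(one["probe_time"].dt.strftime("%H:%M"), one["bin"]))
    assert got == {"12:30": -1, "13:00": 0, "13:30": 0, "21:59": 8}


def test_segment_window_spans_17_bins():
    assert default_bins() == list(range(-8, 9))
    assert len(default_bins()) == 17


def test_recurring_mw_yields_overlapping_segments():
    table = make_table(
        [
            ("A", "2017-02-06T12:00", "mw_with_task", 4, "same"),
            ("A", "2017-02-06T14:30", "mw_without_task", 5, "same"),
        ],
        window=12,
    )
    segs = segment_events(table, _values(table))
    assert segs.n_segments == 2
    first = segs.frame[segs.frame["ref_time"].dt.hour == 12]
    second = segs.frame[segs.frame["ref_time"].dt.hour == 14]
    late = first[first["probe_time"].dt.strftime("%H:%M") == "14:30"]
    assert late["bin"].tolist() == [2]
    assert second.set_index(second["probe_time"].dt.strftime("%H:%M"))["bin"].to_dict() == {
        "12:00": -3,
        "14:30": 0,
    }


def test_segments_never_bridge_calendar_days():
    table = make_table(
        [
            ("A", "2017-02-06T20:00", "mw_with_task", 4, "same"),
            ("A", "2017-02-07T12:10", "focused", 1, "same"),  # next day: excluded
        ],
        window=12,
    )
    segs = segment_events(table, _values(table))
    assert len(segs.frame) == 1
    assert segs.frame["bin"].tolist() == [0]


def test_no_mw_probes_raises():
    table = make_table([("A", "2017-02-06T12:30", "focused", 1, "same")], window=12)
    with pytest.raises(EmptySegmentsError):
        segment_events(table, _values(table))


# ----------------------------------------------------------------------
# binning


def _segments_from(rows, window=12):
    table = make_table(rows, window=window)
    return segment_events(table, _values(table))


def test_binning_single_datum():
    segs = _segments_from(
        [
            ("A", "2017-02-06T13:00", "mw_with_task", 4, "much_closer"),
            ("A", "2017-02-06T16:30", "focused", 1, "little_farther"),  # bin 3, value 1
        ]
    )
    binned = bin_and_average(segs)
    assert binned.grand_average[3] == pytest.approx(1.0)
    assert binned.n_participants[3] == 1
    assert np.isnan(binned.grand_average[5])


def test_grand_average_is_unweighted_over_participants():
    segs = _segments_from(
        [
            ("A", "2017-02-06T13:00", "mw_with_task", 4, "little_farther"),
            ("B", "2017-02-06T13:00", "mw_with_task", 4, "much_farther"),
            ("B", "2017-02-06T13:20", "mw_without_task", 4, "much_farther"),
        ]
    )
    binned = bin_and_average(segs)
    # A: bin-0 mean 1; B pools three bin-0 values (two segments) to 2
    assert binned.grand_average[0] == pytest.approx((1 + 2) / 2)
    assert binned.n_participants[0] == 2


def test_within_participant_pooling_before_grand_average():
    segs = _segments_from(
        [
            ("A", "2017-02-06T13:00", "mw_with_task", 4, "same"),
            ("A", "2017-02-06T14:10", "focused", 1, "little_farther"),   # bin 1 of seg 1
            ("A", "2017-02-07T13:00", "mw_with_task", 4, "same"),
            ("A", "2017-02-07T14:50", "focused", 1, "much_farther"),     # bin 1 of seg 2
        ]
    )
    binned = bin_and_average(segs)
    assert binned.grand_average[1] == pytest.approx((1 + 2) / 2)
    assert binned.n_participants[1] == 1


# ----------------------------------------------------------------------
# homogeneity


def _flat_probability_segments(n_pid=4):
    """Every (participant, bin) cell holds one MW and one non-MW probe."""
    rows = []
    for p in range(n_pid):
        for b in default_bins():
            for j, mw in enumerate((True, False)):
                rows.append(
                    {
                        "participant_id": f"P{p}",
                        "segment_id": 0,
                        "ref_time": pd.Timestamp("2017-02-06T12:00"),
                        "probe_time": pd.Timestamp("2017-02-06T12:00"),
                        "bin": b,
                        "is_mw": mw,
                    }
                )
    return Segments(frame=pd.DataFrame(rows))


def test_identical_bin_probabilities_give_zero_f():
    res = mw_probability_series(_flat_probability_segments())
    assert res.anova["F"] == 0.0
    assert res.anova["p_value"] == 1.0
    assert (res.grand_average == 0.5).all()


def test_bin_zero_excluded_from_homogeneity_test():
    segs = _flat_probability_segments()
    frame = segs.frame.copy()
    # make bin 0 wildly different: it must not affect the ANOVA
    frame.loc[frame["bin"] == 0, "is_mw"] = True
    res = mw_probability_series(Segments(frame=frame))
    assert res.grand_average[0] == 1.0
    assert res.anova["F"] == 0.0


def test_homogeneity_skipped_with_one_participant():
    segs = _flat_probability_segments(n_pid=1)
    with pytest.warns(UserWarning, match="skipped"):
        res = mw_probability_series(segs)
    assert res.anova is None


# ----------------------------------------------------------------------
# bootstrap percentiles


def _binned(matrix, participants=None):
    df = pd.DataFrame(matrix, index=participants or [f"P{i}" for i in range(len(matrix))])
    return BinnedSeries(
        participant_bin_means=df,
        grand_average=df.mean(axis=0),
        n_participants=df.notna().sum(axis=0).astype(int),
    )


def test_single_participant_all_ties_gives_midrank_50():
    binned = _binned([[2.0]])
    pct, dist = bootstrap_percentiles(binned, B=100, seed=0)
    assert pct.iloc[0] == pytest.approx(50.0)
    assert (dist.samples.to_numpy() == 2.0).all()


def test_percentiles_reproducible_bitwise():
    rng = np.random.default_rng(3)
    binned = _binned(rng.normal(size=(6, 17)))
    a, _ = bootstrap_percentiles(binned, B=500, seed=42)
    b, _ = bootstrap_percentiles(binned, B=500, seed=42)
    assert (a.to_numpy() == b.to_numpy()).all()
    c, _ = bootstrap_percentiles(binned, B=500, seed=43)
    assert not (a.to_numpy() == c.to_numpy()).all()


def test_percentile_monotone_in_observed_value():
    rng = np.random.default_rng(4)
    M = rng.normal(size=(8, 17))
    base, _ = bootstrap_percentiles(_binned(M), B=1000, seed=7)
    M2 = M.copy()
    M2[3, 5] += 5.0
    raised, _ = bootstrap_percentiles(_binned(M2), B=1000, seed=7)
    assert raised.iloc[5] >= base.iloc[5]


def test_empty_bin_has_missing_percentile():
    M = np.full((3, 2), np.nan)
    M[:, 0] = [1.0, 2.0, 3.0]
    binned = _binned(M)
    pct, _ = bootstrap_percentiles(binned, B=200, seed=0)
    assert np.isnan(pct.iloc[1]) and np.isfinite(pct.iloc[0])


def test_exchangeable_cohort_percentiles_center_at_50():
    rng = np.random.default_rng(11)
    binned = _binned(rng.normal(size=(20, 17)))
    pct, _ = bootstrap_percentiles(binned, B=2000, seed=1)
    assert abs(pct.mean() - 50) < 5


# ----------------------------------------------------------------------
# trajectory assembly and variability


def test_constant_inputs_give_identity_layout():
    bins = pd.Index(default_bins(), name="bin")
    fifty = pd.Series(50.0, index=bins)
    t = build_trajectory(fifty, fifty)
    assert len(t.points) == 17
    assert (t.points["r_pct"] == 50).all() and (t.points["not_pct"] == 50).all()
    assert t.points["complete"].all()


def test_missing_axis_flags_point_without_interpolation():
    bins = pd.Index(default_bins(), name="bin")
    not_pct = pd.Series(50.0, index=bins)
    r_pct = pd.Series(50.0, index=bins)
    r_pct[-8] = np.nan
    t = build_trajectory(not_pct, r_pct)
    assert t.points["complete"].sum() == 16
    assert not t.points.loc[-8, "complete"]
    assert np.isnan(t.points.loc[-8, "r_pct"])


def test_mismatched_axes_rejected():
    a = pd.Series(50.0, index=pd.Index(default_bins(), name="bin"))
    b = pd.Series(50.0, index=pd.Index(range(-3, 4), name="bin"))
    with pytest.raises(ParameterError):
        build_trajectory(a, b)


def test_identical_participants_give_zero_radius():
    row = np.linspace(-1, 1, 17)
    M = np.tile(row, (5, 1))
    radii = interindividual_variability(_binned(M), _binned(M + 0.3), B=200, seed=0)
    assert np.allclose(radii.dropna(), 0.0)
    assert radii.notna().all()


def test_radius_nonnegative_and_small_bins_missing():
    rng = np.random.default_rng(5)
    M = rng.normal(size=(6, 17))
    Mn = M.copy()
    Mn[1:, 0] = np.nan  # bin -8: single contributing participant
    radii = interindividual_variability(_binned(Mn), _binned(M), B=200, seed=0)
    assert np.isnan(radii.iloc[0])
    assert (radii.dropna() >= 0).all()


def test_two_participant_jackknife_matches_manual_enumeration():
    """Radius equals the RMS of the two manually computed leave-one-out
    displacement vectors in percentile space."""
    rng = np.random.default_rng(6)
    Mn, Mr = rng.normal(size=(2, 17)), rng.normal(size=(2, 17))
    bn, br = _binned(Mn), _binned(Mr)
    B, seed = 300, 9
    radii = interindividual_variability(bn, br, B=B, seed=seed, min_participants=2)

    ss = np.random.SeedSequence(seed)
    full_child, loo_parent = ss.spawn(2)
    full_not, _ = bootstrap_percentiles(bn, B, full_child)
    full_r, _ = bootstrap_percentiles(br, B, full_child)
    loo_children = loo_parent.spawn(2)
    d2 = []
    for j, child in enumerate(loo_children):
        keep = [1 - j]
        bn_j = _binned(Mn[keep], participants=[f"P{keep[0]}"])
        br_j = _binned(Mr[keep], participants=[f"P{keep[0]}"])
        p_not, _ = bootstrap_percentiles(bn_j, B, child)
        p_r, _ = bootstrap_percentiles(br_j, B, child)
        d2.append((p_not - full_not) ** 2 + (p_r - full_r) ** 2)
    expected = np.sqrt((d2[0] + d2[1]) / 2)
    assert np.allclose(radii.to_numpy(), expected.to_numpy())


# ----------------------------------------------------------------------
# period diagnostics and cohort-level shape


def test_autocorr_peak_on_pure_cosine():
    for period in (4, 5, 6):
        x = np.cos(2 * np.pi * np.arange(17) / period)
        assert first_autocorr_peak_lag(x, max_lag=8) == period


def test_edge_bins_thinner_than_reference_bin(default_cohort):
    table, _ = default_cohort
    summ = scoring.participant_summaries(table)
    d_not = scoring.standardize(
        scoring.not_values(table), table.records["participant_id"], summ, "not", "mean"
    )
    segs = segment_events(table, d_not.to_frame("d_not"))
    binned = bin_and_average(segs, "d_not")
    assert binned.n_participants[-8] < binned.n_participants[0]
    assert binned.n_participants[8] < binned.n_participants[0]


def test_period_recovery_single_cohort():
    table, _ = m.simulate_cohort(m.SimParams(master_seed=21, period_hours=5.0))
    clean, _ = m.apply_exclusions(table)
    summ = scoring.participant_summaries(clean)
    d_not = scoring.standardize(
        scoring.not_values(clean), clean.records["participant_id"], summ, "not", "mean"
    )
    segs = segment_events(clean, d_not.to_frame("d_not"))
    binned = bin_and_average(segs, "d_not")
    lag = first_autocorr_peak_lag(binned.grand_average, max_lag=8)
    assert lag is not None and abs(lag - 5) <= 1
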