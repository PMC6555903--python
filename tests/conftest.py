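import numpy as np
import pandas as pd
import pytest

import mwtraj as m
from mwtraj.io import COLUMNS, ProbeTable
from mwtraj.simulate import SimParams, simulate_cohort


def make_table(rows, window=9):
    """Build a ProbeTable from (pid, 'YYYY-MM-DDTHH:MM', state, not, rating) tuples.

    ``not`` / ``rating`` may be None; flags default to False.
    """
    recs = []
    for r in rows:
        pid, ts, state, nt, rating = r[:5]
        alcohol = r[5] if len(r) > 5 else False
        display = r[6] if len(r) > 6 else False
        recs.append(
            {
                "participant_id": pid,
                "timestamp": pd.Timestamp(ts),
                "state": state,
                "not_report": nt,
                "rating": rating,
                "alcohol_flag": alcohol,
                "display_problem_flag": display,
                "window_start_hour": window,
            }
        )
    df = pd.DataFrame(recs, columns=COLUMNS)
    df["not_report"] = df["not_report"].astype("Int64")
    df["rating"] = df["rating"].astype(object).where(df["rating"].notna(), pd.NA)
    df = df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    return ProbeTable(df)


def bulk_rows(pid, day, n, state="focused", nt=1, rating="same", start_hour=9, window=9):
    """n answered probes on one day, two hours apart."""
    return [
        (pid, f"2017-02-{day:02d}T{start_hour + 2 * (i % 6):02d}:{(i // 6) * 7:02d}",
         state, nt, rating)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (28 participants) after exclusions."""
    table, truth = simulate_cohort(SimParams(master_seed=11))
    clean, _report = m.apply_exclusions(table)
    return clean, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 8-participant cohort after exclusions."""
    table, truth = simulate_cohort(SimParams(n_participants=8, master_seed=5))
    clean, _report = m.apply_exclusions(table)
    return clean, truth
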