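"""End-to-end orchestration: simulate or load, exclude, score, segment,
bootstrap, and assemble the trajectory, writing a machine-readable bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from . import scoring, trajectory as traj, plotting
from .errors import ParameterError, PipelineError
from .simulate import SimParams, simulate_cohort

log = logging.getLogger("mwtraj")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_path`` (a probe-table CSV) or ``sim`` (generator
    parameters) must be set.
    """

    input_path: str | None = None
    sim: SimParams | None = None
    min_probes: int = 40
    not_reference: str = "mean"   # d-variant for the NoT axis
    r_reference: str = "min"      # d-variant for the R axis
    B: int = 2000
    bootstrap_seed: int = 0
    outdir: str = "mwtraj_out"
    make_plots: bool = True
    variability: bool = True

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ParameterError("exactly one of input_path / sim must be set")
        if self.not_reference not in scoring.REFERENCES or self.r_reference not in scoring.REFERENCES:
            raise ParameterError(f"references must be one of {scoring.REFERENCES}")
        if self.B < 1:
            raise ParameterError("B must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimParams.from_dict(d["sim"])
        return cls(**d)


@dataclass
class RunResult:
    outdir: Path
    files: list[Path] = field(default_factory=list)
    cohort: pio.CohortSummary | None = None
    states: scoring.StateComparison | None = None
    trajectory: traj.Trajectory | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage; on any failure, partial outputs are removed and a
    :class:`PipelineError` naming the stage propagates."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(outdir=outdir)

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        result.files.append(path)
        log.info("wrote %s", path)
        return path

    try:
        # ---- acquire ------------------------------------------------
        if config.sim is not None:
            table, truth = _stage("simulate")(simulate_cohort)(config.sim)
            emit("probes.csv", lambda p: pio.write_probe_table(table, p))
            emit("truth.json", truth.to_json)
        else:
            table = _stage("read")(pio.read_probe_table)(config.input_path)
        log.info("loaded %d probes from %d participants", len(table), len(table.participants()))

        # ---- exclusions and cohort summary --------------------------
        table, report = _stage("exclusions")(pio.apply_exclusions)(table, config.min_probes)
        for entry in report.excluded_participants + report.excluded_records:
            log.info("excluded: %s", entry)
        emit("exclusion_report.json", report.to_json)
        summary = _stage("cohort_summary")(pio.summarize_cohort)(table)
        result.cohort = summary
        emit("cohort_summary.json", summary.to_json)
        emit("cohort_summary.csv", summary.to_csv)
        log.info("valid probes: %d; MW incidence: %.1f%%", summary.valid_probes,
                 100 * summary.proportions["mw_pooled"])

        # ---- state comparison ---------------------------------------
        states = _stage("compare_states")(scoring.compare_states)(table)
        result.states = states
        emit("state_comparison.json", states.to_json)

        # ---- d-standardization and segmentation ---------------------
        summaries = _stage("summaries")(scoring.participant_summaries)(table)
        d_not = scoring.standardize(
            scoring.not_values(table), table.records["participant_id"],
            summaries, "not", config.not_reference)
        d_r = scoring.standardize(
            scoring.score_ratings(table), table.records["participant_id"],
            summaries, "r", config.r_reference)
        values = pd.DataFrame({"d_not": d_not, "d_r": d_r})
        segments = _stage("segmentation")(traj.segment_events)(table, values)
        log.info("built %d segments", segments.n_segments)

        # ---- binning and homogeneity --------------------------------
        binned_not = _stage("binning")(traj.bin_and_average)(segments, "d_not")
        binned_r = _stage("binning")(traj.bin_and_average)(segments, "d_r")
        for b in segments.bins:
            log.info("bin %+d: %d participants (NoT), %d (R)", b,
                     binned_not.n_participants[b], binned_r.n_participants[b])
        emit("binned_not.csv", lambda p: binned_not.to_frame().to_csv(p))
        emit("binned_r.csv", lambda p: binned_r.to_frame().to_csv(p))

        mwp = _stage("homogeneity")(traj.mw_probability_series)(segments)
        emit("mw_probability.csv", lambda p: mwp.to_frame().to_csv(p))

        # ---- bootstrap percentiles and trajectory -------------------
        boot = _stage("bootstrap")(traj.bootstrap_percentiles)
        not_pct, not_dist = boot(binned_not, config.B, config.bootstrap_seed)
        r_pct, r_dist = boot(binned_r, config.B, config.bootstrap_seed + 1)
        radii = None
        if config.variability:
            radii = _stage("variability")(traj.interindividual_variability)(
                binned_not, binned_r, config.B, config.bootstrap_seed)
        trajectory = _stage("trajectory")(traj.build_trajectory)(
            not_pct, r_pct, radii,
            binned_not.n_participants, binned_r.n_participants,
            r_measure=f"d{config.r_reference}_r",
            not_measure=f"d{config.not_reference}_not")
        result.trajectory = trajectory
        emit("trajectory.csv", trajectory.to_csv)

        # ---- report -------------------------------------------------
        report_payload = {
            "cohort": summary.to_dict(),
            "exclusions": report.to_dict(),
            "state_comparison": states.to_dict(),
            "homogeneity_anova": mwp.anova,
            "n_segments": segments.n_segments,
            "measures": {"not": f"d{config.not_reference}", "r": f"d{config.r_reference}"},
            "bootstrap": {"B": config.B, "seed": config.bootstrap_seed},
        }
        emit("report.json", lambda p: p.write_text(json.dumps(report_payload, indent=2)))

        # ---- plots --------------------------------------------------
        if config.make_plots:
            figs = _stage("plots")(lambda: {
                "mw_probability.png": plotting.fig_mw_probability(mwp),
                "not_percentiles.png": plotting.fig_percentile_series(
                    not_pct, f"d{config.not_reference} NoT"),
                "r_percentiles.png": plotting.fig_percentile_series(
                    r_pct, f"d{config.r_reference} R score"),
                "trajectory.png": plotting.fig_trajectory(trajectory),
            })()
            for name, fig in figs.items():
                emit(name, lambda p, f=fig: f.savefig(p, dpi=150))
    except Exception:
        for path in result.files:
            path.unlink(missing_ok=True)
        raise
    return result
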