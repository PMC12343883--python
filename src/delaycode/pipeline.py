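"""Session-level orchestration: run every analysis stage and build a report.

Stages run in dependency order (theta -> time cells -> precession;
assemblies; SWR -> population events; selectivity; error consistency), each
drawing its randomness from a named child stream of one master seed so any
stage can be re-run in isolation. A stage failure marks the stage failed in
the report and skips its dependents.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblies as asm
from . import errors as err
from . import lfp as lfpmod
from . import popevents as pe
from . import precession as prec
from . import selectivity as sel
from . import timecells as tc
from .session import Session, read_session

logger = logging.getLogger(__name__)

STAGES = (
    "theta", "swr", "timecells", "precession", "assemblies",
    "popevents", "selectivity", "errors",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_shuffle: int = tc.N_SHUFFLE
    n_perm: int = sel.N_PERM
    stages: tuple[str, ...] = STAGES
    bin_s: float = tc.BIN_S
    sigma_s: float = tc.SIGMA_S
    selectivity_regions: tuple[str, ...] = ("delay", "stem", "T")
    statistic: str = "abs"
    swr_power_mode: str = "squared_envelope"
    popevent_mode: str = "sliding"

    def stage_seed(self, name: str) -> int:
        """Deterministic per-stage child seed derived from the master seed."""
        child = np.random.SeedSequence([self.seed, STAGES.index(name)])
        return int(child.generate_state(1)[0] % (2**31 - 1))


@dataclass
class SessionReport:
    session_id: str
    stages: dict = field(default_factory=dict)   # stage -> ok | failed | skipped
    behavior: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    cell_census: dict = field(default_factory=dict)
    selectivity: dict = field(default_factory=dict)
    assemblies: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict, repr=False)  # in-memory only

    def to_json(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "artifacts"}
        return json.dumps(payload, indent=1, default=_jsonable)

    def to_text(self) -> str:
        lines = [f"session {self.session_id}"]
        lines.append("  behavior: " + ", ".join(
            f"{k}={v:.0%}" for k, v in self.behavior.get("percent_correct", {}).items()
        ))
        c = self.cell_census
        if c:
            lines.append(
                f"  cells: {c['n_principal']} principal, {c['n_delay_active']} delay-active, "
                f"{c['n_time_cells']} time cells ({c['n_time_limited']} time-limited, "
                f"{c['n_persistent']} persistent)"
            )
        for stage, status in self.stages.items():
            lines.append(f"  [{status}] {stage}")
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    return str(o)


def overrepresentation_ratio(active_fraction: float, zone_size_fraction: float) -> float:
    """(% of cells active in a zone) / (% of maze area in the zone)."""
    if zone_size_fraction <= 0:
        raise ValueError("zone size fraction must be positive")
    return active_fraction / zone_size_fraction


def behavior_summary(session: Session) -> dict:
    pct = {}
    for cond in session.conditions():
        trials = session.trials_of(cond)
        pct[cond] = float(np.mean([t.outcome == "correct" for t in trials]))
    return {"percent_correct": pct, "n_trials": len(session.trials)}


def run_pipeline(
    source: Session | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SessionReport:
    config = config or PipelineConfig()
    session = source if isinstance(source, Session) else read_session(source)
    report = SessionReport(session_id=session.session_id)
    report.behavior = behavior_summary(session)
    report.seeds = {s: config.stage_seed(s) for s in config.stages}
    artifacts = report.artifacts

    def run_stage(name, fn, depends=()):
        if name not in config.stages:
            report.stages[name] = "disabled"
            return
        for dep in depends:
            if report.stages.get(dep) != "ok":
                report.stages[name] = f"skipped (needs {dep})"
                return
        try:
            fn()
            report.stages[name] = "ok"
        except Exception as e:
            logger.exception("stage %s failed", name)
            report.stages[name] = f"failed: {e}"

    # --- theta ------------------------------------------------------------
    def stage_theta():
        bouts = lfpmod.detect_theta_bouts(session.lfp)
        metrics = lfpmod.delay_theta_metrics(bouts, session.lfp, session.trials)
        artifacts["theta_bouts"] = bouts
        artifacts["theta_metrics"] = metrics
        tab = metrics.table
        report.theta = {
            cond: {
                "coverage": float(g["coverage"].mean()),
                "initial_bout_s": float(g["initial_bout_s"].mean()),
                "z_power": float(g["z_power"].mean()),
                "frac_sustained": float(g["sustained"].mean()),
            }
            for cond, g in tab.groupby("condition")
        }

    def stage_swr():
        artifacts["swr"] = lfpmod.detect_swr(
            session.lfp, power_mode=config.swr_power_mode
        )

    def stage_timecells():
        table = tc.classify_session(
            session, n_shuffle=config.n_shuffle, seed=config.stage_seed("timecells")
        )
        artifacts["timecells"] = table
        per_unit = table.groupby("unit_id")
        n_principal = len(session.principal_units())
        n_active = int(table.groupby("unit_id")["delay_active"].first().sum())
        is_tc = per_unit["is_time_cell"].any()
        kinds = table[table["is_time_cell"]].groupby("unit_id")["kind"].agg(
            lambda k: "time_limited" if (k == "time_limited").any() else "persistent"
        )
        report.cell_census = {
            "n_principal": n_principal,
            "n_delay_active": n_active,
            "n_time_cells": int(is_tc.sum()),
            "n_time_limited": int((kinds == "time_limited").sum()),
            "n_persistent": int((kinds == "persistent").sum()),
        }

    def stage_precession():
        artifacts["precession"] = prec.session_precession(
            session, artifacts["timecells"],
            n_perm=config.n_perm, seed=config.stage_seed("precession"),
        )
        tab = artifacts["precession"]
        elig = tab[tab["eligible"]]
        report.cell_census["n_precessing"] = int(elig["is_precessing"].sum())
        report.cell_census["n_precession_eligible"] = int(len(elig))

    def stage_assemblies():
        out = {}
        models = {}
        for tm in ("on", "off"):
            ivs = asm.delay_intervals(session, tm)
            z = asm.bin_and_zscore(session, ivs, condition=tm)
            model = asm.extract_assemblies(
                z, rng=config.stage_seed("assemblies")
            )
            models[tm] = model
            strengths = asm.assembly_strength(z.z, model.weights)
            act = asm.activation_events(strengths, z.bin_starts) if model.k else None
            out[tm] = {
                "k": model.k,
                "mp_lambda_max": model.mp_lambda_max,
                "members": model.members,
            }
            artifacts[f"assembly_model_{tm}"] = model
            artifacts[f"assembly_z_{tm}"] = z
            artifacts[f"assembly_activation_{tm}"] = act
        match = asm.match_assemblies(models["on"], models["off"])
        out["n_common"] = int(sum(match.common))
        out["matches"] = match.pairs
        report.assemblies = out

    def stage_popevents():
        swr = artifacts["swr"]
        out = {}
        for area in ("delay", "reward"):
            ivs = pe.rest_intervals(session, area)
            events = pe.detect_population_events(
                session, ivs, area=area, mode=config.popevent_mode
            )
            eligible = pe.session_eligibility(events)
            frac_ev, frac_swr = pe.event_swr_overlap(events, swr)
            out[area] = {
                "n_events": len(events),
                "eligible": eligible,
                "frac_events_with_swr": frac_ev,
                "frac_swrs_with_event": frac_swr,
            }
            artifacts[f"popevents_{area}"] = events
        report.population = out

    def stage_selectivity():
        out = {}
        seed = config.stage_seed("selectivity")
        for region in config.selectivity_regions:
            tabs = []
            for cond in session.conditions():
                tabs.append(sel.cell_turn_selectivity(
                    session, region=region, condition=cond,
                    n_perm=config.n_perm, seed=seed, statistic=config.statistic,
                ))
            tab = pd.concat(tabs, ignore_index=True)
            inc = tab[~tab["excluded"]]
            n_sig = int(inc["significant"].sum())
            n_tot = int(len(inc))
            p = sel.proportion_vs_chance(n_sig, n_tot).p_value if n_tot else None
            out[region] = {
                "n_selective": n_sig, "n_included": n_tot, "binomial_p": p,
            }
            artifacts[f"selectivity_{region}"] = tab
        report.selectivity = out

    def stage_errors():
        out = {}
        for cond in session.conditions():
            res = err.error_consistency(
                session, cond, seed=config.stage_seed("errors")
            )
            if res is None:
                out[cond] = {"skipped": "fewer than 4 error trials"}
            else:
                out[cond] = {
                    "mean_r_diff_error": float(res.table["r_diff_error"].mean())
                    if len(res.table) else None,
                    "mean_r_diff_baseline": float(res.table["r_diff_baseline"].mean())
                    if len(res.table) else None,
                    "t": res.t_statistic if np.isfinite(res.t_statistic) else None,
                    "p": res.p_value if np.isfinite(res.p_value) else None,
                    "n_cells": int(len(res.table)),
                }
        report.errors = out

    run_stage("theta", stage_theta)
    run_stage("swr", stage_swr)
    run_stage("timecells", stage_timecells)
    run_stage("precession", stage_precession, depends=("timecells",))
    run_stage("assemblies", stage_assemblies)
    run_stage("popevents", stage_popevents, depends=("swr",))
    run_stage("selectivity", stage_selectivity)
    run_stage("errors", stage_errors)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.txt").write_text(report.to_text())
        for key in ("timecells", "precession"):
            if key in artifacts:
                artifacts[key].to_csv(out_dir / f"{key}.csv", index=False)
    return report
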