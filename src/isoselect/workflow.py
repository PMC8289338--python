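"""End-to-end orchestration of the nine-stage solvent-selection workflow.

Stages: (1-4) crystallization solvent ranking, (5) wash solvent
filtering and Pareto ranking, (6) binary-curve screening for dissolution
risk, (8-9) isolation simulation with the displacement model (A) and/or
the dispersion model (B).  One config drives the run; every stage's
filters, thresholds and outputs are logged to an audit trail, and
outputs are deterministic — re-running an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field

from . import datasets
from .crystallization import RankingGrid, rank_crystallization_solvents
from .curves import detect_maximum
from .model_a import simulate_isolation_a
from .model_b import simulate_isolation_b
from .solvents import (
    SolubilityTable,
    SolventTable,
    read_solubility_table,
    read_solvent_table,
)
from .streams import IsolationResult
from .washing import WashCandidate, filter_pipeline, pareto_rank, WashFilterConfig

__all__ = ["WorkflowConfig", "WorkflowError", "run_workflow", "write_report"]

STAGES = ("rank_cryst", "rank_wash", "screen_curves", "simulate")


class WorkflowError(RuntimeError):
    """A stage failure carrying the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


class WorkflowConfig(BaseModel):
    """Configuration for one workflow run (YAML/JSON loadable)."""

    output_dir: Path = Path("isoselect-report")
    cryst_solvent: str = "2-propanol"
    api: str = datasets.API
    impurities: list[str] = Field(default_factory=lambda: list(datasets.IMPURITIES))
    solvent_table: Path | None = None  # None -> bundled case-study table
    solubility_table: Path | None = None
    experiments: list[str] = Field(default_factory=lambda: list(datasets.EXPERIMENT_NAMES))
    model: Literal["a", "b", "both"] = "both"
    wash_filter: WashFilterConfig = Field(default_factory=WashFilterConfig)
    stop_after: Literal["rank_cryst", "rank_wash", "screen_curves", "simulate"] | None = None
    seed: int = 0  # fixture generation only
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"output_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_tables(config: WorkflowConfig) -> tuple[SolventTable, SolubilityTable]:
    solvents = (
        read_solvent_table(config.solvent_table)
        if config.solvent_table
        else datasets.case_study_solvents()
    )
    sols = (
        read_solubility_table(config.solubility_table)
        if config.solubility_table
        else datasets.case_study_solubilities()
    )
    return solvents, sols


def _rank_cryst(audit: list[str]) -> pd.DataFrame:
    ranking = rank_crystallization_solvents(datasets.crystallization_candidates())
    audit.append(
        f"stage rank_cryst: {len(ranking.ranked)} ranked, "
        f"{len(ranking.excluded)} excluded (grid={RankingGrid()})"
    )
    rows = [
        {
            "solvent": r.candidate.solvent.name,
            "return_g": round(r.return_mass, 2),
            "yield_pct": round(r.yield_pct, 2),
            "solvent_ratio_g_per_g": round(r.solvent_ratio, 2),
            "category": r.category,
            "color": r.color,
            "demoted": r.demoted,
            "status": "ranked",
        }
        for r in ranking.ranked
    ]
    rows += [
        {"solvent": c.solvent.name, "status": f"excluded: {reason}"}
        for c, reason in ranking.excluded
    ]
    return pd.DataFrame(rows)


def _rank_wash(
    config: WorkflowConfig,
    solvents: SolventTable,
    sols: SolubilityTable,
    audit: list[str],
) -> pd.DataFrame:
    try:
        cryst = solvents.get(config.cryst_solvent)
        cryst_api_sol = sols.get(config.api, config.cryst_solvent, 22.0)
    except KeyError as exc:
        raise WorkflowError("rank_wash", str(exc)) from exc
    candidates = []
    for solvent in solvents:
        if solvent.name == cryst.name:
            continue
        try:
            api_sol = sols.get(config.api, solvent.name, 22.0)
            imps = {i: sols.get(i, solvent.name, 22.0) for i in config.impurities}
        except KeyError:
            continue  # no solubility data: not a candidate
        candidates.append(
            WashCandidate(solvent=solvent, api_solubility=api_sol, impurity_solubilities=imps)
        )
    levels = filter_pipeline(candidates, cryst, cryst_api_sol, config.wash_filter)
    for lvl, pool in levels.items():
        n_ok = sum(c.unflagged for c in pool)
        audit.append(f"stage rank_wash: filter {lvl} -> {n_ok}/{len(pool)} unflagged")
    fronts = pareto_rank(levels[4])
    if not fronts:
        audit.append("stage rank_wash: no candidates passed filters")
    rows = []
    for front_idx, front in enumerate(fronts, start=1):
        for rank_in_front, cand in enumerate(front, start=1):
            rows.append(
                {
                    "wash_solvent": cand.solvent.name,
                    "front": front_idx,
                    "rank_in_front": rank_in_front,
                    "api_solubility_g_per_100g": cand.api_solubility,
                    **{
                        f"{i}_solubility_g_per_100g": cand.impurity_solubilities[i]
                        for i in config.impurities
                    },
                }
            )
    flagged = [c for c in levels[4] if c.flags]
    rows += [
        {
            "wash_solvent": c.solvent.name,
            "front": None,
            "flags": "|".join(sorted(f.value for f in c.flags)),
        }
        for c in flagged
    ]
    return pd.DataFrame(rows)


def _screen_curves(
    config: WorkflowConfig,
    ranked_wash: pd.DataFrame,
    sols: SolubilityTable,
    audit: list[str],
) -> pd.DataFrame:
    from .curves import build_binary_curve

    rows = []
    top = ranked_wash[ranked_wash["front"].notna()] if len(ranked_wash) else ranked_wash
    for wash_solvent in top.get("wash_solvent", pd.Series(dtype=str)):
        for solute in [config.api, *config.impurities]:
            try:
                s0 = sols.get(solute, config.cryst_solvent, 22.0)
                s1 = sols.get(solute, wash_solvent, 22.0)
            except KeyError as exc:
                raise WorkflowError(
                    "screen_curves",
                    f"missing solubility for solute {solute!r} in pair "
                    f"({config.cryst_solvent!r} -> {wash_solvent!r})",
                ) from exc
            curve = build_binary_curve(
                [(0.0, s0), (1.0, s1)],
                interpolation="log_linear",
                solute=solute,
                cryst_solvent=config.cryst_solvent,
                wash_solvent=wash_solvent,
            )
            has_max, location = detect_maximum(curve)
            rows.append(
                {
                    "solute": solute,
                    "wash_solvent": wash_solvent,
                    "endpoint_cryst_g_per_100g": s0,
                    "endpoint_wash_g_per_100g": s1,
                    "interior_maximum": has_max,
                    "maximum_wash_fraction": location,
                }
            )
    n_risky = sum(r["interior_maximum"] for r in rows)
    audit.append(f"stage screen_curves: {len(rows)} curves screened, {n_risky} with maxima")
    return pd.DataFrame(rows)


def _result_table(result: IsolationResult, porosity: float) -> pd.DataFrame:
    """Result rows keyed like the published simulation tables."""
    rows = [
        ("input stream", "paracetamol concentration solid and dissolved phase (g/g)",
         result.feed.api_fraction),
    ]
    for imp in result.feed.impurities:
        rows.append(("input stream", f"{imp} concentration (g/g)",
                     result.feed.impurity_fraction(imp)))
    filt = result.filtration_filtrate
    if filt.total_mass > 0:
        rows.append(("filtration", "paracetamol concentration removed (g/g)",
                     filt.api_fraction))
        for imp in filt.impurities:
            rows.append(("filtration", f"{imp} concentration removed (g/g)",
                         filt.impurity_fraction(imp)))
    rows.append(("filtration", "filtration yield (%)", result.filtration_yield))
    for cp in result.checkpoints:
        ecv = f"{cp.ecv:.2f} ECV"
        if cp.filtrate.total_mass > 0:
            rows.append(("washing", f"paracetamol concentration removed at {ecv} (g/g)",
                         cp.filtrate.api_fraction))
            for imp in cp.filtrate.impurities:
                rows.append(("washing", f"{imp} concentration removed at {ecv} (g/g)",
                             cp.filtrate.impurity_fraction(imp)))
        rows.append(("washing", f"washing yield at {ecv} (%)", cp.washing_yield))
        for imp, pct in cp.removal.items():
            rows.append(("washing", f"removed {imp} at {ecv} (%)", pct))
    return pd.DataFrame(rows, columns=["stage", "quantity", "value"])


def _simulate(config: WorkflowConfig, audit: list[str]) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for name in config.experiments:
        try:
            exp = datasets.experiment(name)
        except KeyError as exc:
            raise WorkflowError("simulate", str(exc)) from exc
        if config.model in ("a", "both"):
            result = simulate_isolation_a(
                exp.feed, exp.porosity, exp.wash_spec(), exp.curves(), exp.cryst_solvent
            )
            out[f"{name}_model_a"] = _result_table(result, exp.porosity)
            audit.append(
                f"stage simulate: {name} model A flags="
                f"{sorted(result.flags) if result.flags else 'none'}"
            )
        if config.model in ("b", "both"):
            result_b, outcome = simulate_isolation_b(
                exp.feed, exp.filtration_setup(), exp.dispersion_setup(),
                exp.cryst_solvent, exp.curves(),
            )
            table = _result_table(result_b, exp.porosity)
            table.loc[len(table)] = ["filtration", "filtration time (s)", outcome.time]
            out[f"{name}_model_b"] = table
            audit.append(
                f"stage simulate: {name} model B filtration time {outcome.time:.1f} s"
            )
    return out


def run_workflow(config: WorkflowConfig) -> dict[str, pd.DataFrame | list[str]]:
    """Execute the workflow stages in order; returns tables plus the audit log."""
    audit: list[str] = [f"config hash {config.config_hash()}"]
    solvents, sols = _load_tables(config)
    report: dict[str, pd.DataFrame | list[str]] = {}
    report["crystallization_ranking"] = _rank_cryst(audit)
    if config.stop_after != "rank_cryst":
        report["wash_ranking"] = _rank_wash(config, solvents, sols, audit)
        if config.stop_after != "rank_wash":
            report["curve_screening"] = _screen_curves(
                config, report["wash_ranking"], sols, audit
            )
            if config.stop_after != "screen_curves":
                report.update(_simulate(config, audit))
    report["audit"] = audit
    return report


def write_report(
    report: dict[str, pd.DataFrame | list[str]],
    config: WorkflowConfig,
    fmt: str = "csv",
) -> list[Path]:
    """Write the report bundle (CSV tables or one markdown file)."""
    if not report:
        raise ValueError("empty report")
    if fmt not in ("csv", "markdown"):
        raise ValueError(f"unknown report format {fmt!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    header = f"# isoselect {__version__} | config {config.config_hash()}"
    written: list[Path] = []
    audit = report.get("audit", [])
    if fmt == "csv":
        for key, value in report.items():
            if key == "audit":
                path = outdir / "audit.log"
                path.write_text("\n".join([header, *value]) + "\n")
            else:
                path = outdir / f"{key}.csv"
                with open(path, "w") as fh:
                    fh.write(header + "\n")
                    value.to_csv(fh, index=False)
            written.append(path)
    else:
        lines = [header, ""]
        for key, value in report.items():
            if key == "audit":
                continue
            lines += [f"## {key}", "", value.to_markdown(index=False), ""]
        lines += ["## flags and audit log", ""] + [f"- {entry}" for entry in audit]
        path = outdir / "report.md"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    manifest = outdir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "files": sorted(p.name for p in written)},
            indent=2,
        )
        + "\n"
    )
    return written + [manifest]
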