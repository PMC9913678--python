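"""End-to-end orchestration: simulate -> validate -> networks -> indices -> models -> report.

Each stage consumes the previous stage's standard files inside one output
directory, so the stages are independently runnable (and the CLI exposes
them as subcommands).  Running all stages in sequence is exactly what
:func:`run_pipeline` does, so chained stage runs and a single pipeline run
produce byte-identical numeric outputs for the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .indices import build_index_table, read_index_table, write_index_table
from .models import RESPONSES, ModelSpec, fit_lmm
from .networks import build_networks, export_network, read_network
from .scans import (
    BehaviorCatalog,
    Individual,
    ScanTable,
    SeasonRule,
    StudyPhase,
    assign_strata,
    read_scans,
    validate_scans,
    write_scans,
)
from .simulate import Effects, SimulationConfig, default_sim_config, generate_scans
from .study import default_catalog, default_phases, default_roster, default_season_rule

logger = logging.getLogger("groomnet")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``scans`` / simulation input per run."""

    output_dir: Path
    seed: int = 0
    scans: Path | None = None  # external scan CSV; None -> simulate
    simulation: SimulationConfig | None = None
    roster: tuple[Individual, ...] = field(default_factory=default_roster)
    phases: tuple[StudyPhase, ...] = field(default_factory=default_phases)
    catalog: BehaviorCatalog = field(default_factory=default_catalog)
    season_rule: SeasonRule = field(default_factory=default_season_rule)
    responses: tuple[str, ...] = RESPONSES
    strict: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.scans is not None and self.simulation is not None:
            raise ValueError("configure either input scans or a simulation, not both")
        if self.scans is None and self.simulation is None:
            self.simulation = default_sim_config(seed=self.seed)
        if self.simulation is not None:
            self.simulation = dataclasses.replace(
                self.simulation,
                seed=self.seed,
                phases=self.phases,
                roster=self.roster,
                catalog=self.catalog,
                season_rule=self.season_rule,
            )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None, output_dir: str | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        roster = tuple(
            Individual(
                id=e["id"],
                sex=e["sex"],
                birth_year=int(e.get("birth_year", 2000)),
                origin=e["origin"],
                join_date=_parse_date(e["join_date"]),
                exit_date=_parse_date(e["exit_date"]) if e.get("exit_date") else None,
            )
            for e in raw["roster"]
        ) if "roster" in raw else default_roster()
        phases = tuple(
            StudyPhase(
                label=e["label"],
                start_date=_parse_date(e["start_date"]),
                end_date=_parse_date(e["end_date"]),
                roster=tuple(e["roster"]),
                sex_ratio=e["sex_ratio"],
            )
            for e in raw["phases"]
        ) if "phases" in raw else default_phases()
        if "cold_months" in raw:
            cold = set(int(m) for m in raw["cold_months"])
            season_rule = SeasonRule(
                {m: ("cold" if m in cold else "warm") for m in range(1, 13)}
            )
        else:
            season_rule = default_season_rule()

        sim = None
        if raw.get("scans") is None:
            sim_raw = dict(raw.get("simulation") or {})
            if "effects" in sim_raw:
                sim_raw["effects"] = Effects(**sim_raw["effects"])
            if "base_behavior_probs" in sim_raw:
                sim_raw["base_behavior_probs"] = tuple(sim_raw["base_behavior_probs"])
            sim = default_sim_config(**sim_raw)

        return cls(
            output_dir=Path(output_dir or raw.get("output_dir", "groomnet_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            scans=Path(raw["scans"]) if raw.get("scans") else None,
            simulation=sim,
            roster=roster,
            phases=phases,
            season_rule=season_rule,
            responses=tuple(raw.get("responses", RESPONSES)),
            strict=bool(raw.get("strict", False)),
        )


def _parse_date(value) -> date:
    return value if isinstance(value, date) else date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _scan_csv(cfg: PipelineConfig) -> Path:
    if cfg.scans is not None:
        if not Path(cfg.scans).exists():
            raise PipelineError(f"input scan file {cfg.scans} does not exist")
        return Path(cfg.scans)
    path = cfg.output_dir / "scans.csv"
    if not path.exists():
        raise PipelineError("scans.csv missing: run stage 'simulate' first")
    return path


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate scans.csv and ground_truth.json."""
    if cfg.simulation is None:
        raise PipelineError("external scans configured: nothing to simulate")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    table, truth = generate_scans(cfg.simulation)
    out = cfg.output_dir / "scans.csv"
    write_scans(table, out)
    truth.to_json(cfg.output_dir / "ground_truth.json")
    logger.info("simulate: %d records -> %s", len(table), out)
    return out


def stage_validate(cfg: PipelineConfig) -> Path:
    """Protocol validation report; strict mode fails on any finding."""
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    table = read_scans(_scan_csv(cfg), cfg.catalog)
    report = validate_scans(table, cfg.catalog, cfg.phases)
    out = cfg.output_dir / "validation_report.csv"
    report.write_csv(out)
    if cfg.strict and not report.ok:
        raise PipelineError(f"validation failed with {len(report)} finding(s); see {out}")
    logger.info("validate: %d finding(s) -> %s", len(report), out)
    return out


def _load_stratified(cfg: PipelineConfig) -> ScanTable:
    table = read_scans(_scan_csv(cfg), cfg.catalog)
    return assign_strata(table, cfg.phases, cfg.season_rule)


def stage_networks(cfg: PipelineConfig) -> list[Path]:
    """Per-stratum grooming networks: edge-list CSV + GraphML each."""
    table = _load_stratified(cfg)
    nets = build_networks(table, cfg.catalog, cfg.phases, cfg.roster)
    outdir = cfg.output_dir / "networks"
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (phase, season), net in sorted(nets.items()):
        stem = outdir / f"{phase}_{season}"
        export_network(net, stem.with_suffix(".edges.csv"), "edge_list_csv")
        export_network(net, stem.with_suffix(".graphml"), "graphml")
        paths += [stem.with_suffix(".edges.csv"), stem.with_suffix(".graphml")]
    logger.info("networks: %d strata -> %s", len(nets), outdir)
    return paths


def stage_indices(cfg: PipelineConfig) -> Path:
    """Index table (one row per individual x phase x season)."""
    table = _load_stratified(cfg)
    netdir = cfg.output_dir / "networks"
    observed = {
        (str(p), str(s))
        for p, s in table.df[["phase", "season"]].drop_duplicates().itertuples(index=False)
    }
    nets = {}
    for stratum in observed:
        path = netdir / f"{stratum[0]}_{stratum[1]}.graphml"
        if not path.exists():
            raise PipelineError(f"{path.name} missing: run stage 'networks' first")
        nets[stratum] = read_network(path, "graphml")
    index = build_index_table(table, nets, cfg.phases, cfg.roster, cfg.catalog)
    out = cfg.output_dir / "index_table.csv"
    write_index_table(index, out)
    logger.info("indices: %d rows -> %s", len(index), out)
    return out


def stage_fit(cfg: PipelineConfig) -> Path:
    """Fit one LMM per response; CSV tables plus a plain-text summary."""
    index_path = cfg.output_dir / "index_table.csv"
    if not index_path.exists():
        raise PipelineError("index_table.csv missing: run stage 'indices' first")
    index = read_index_table(index_path)
    outdir = cfg.output_dir / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    summary_lines = []
    for response in cfg.responses:
        result = fit_lmm(index, ModelSpec(response))
        if result.anova_table is not None:
            result.anova_table.to_csv(outdir / f"{response}_anova.csv", index=False)
            result.coefficients.to_csv(outdir / f"{response}_coefficients.csv", index=False)
            result.contrasts.to_csv(outdir / f"{response}_contrasts.csv", index=False)
            result.vif.rename_axis("factor").to_csv(outdir / f"{response}_vif.csv")
        summary_lines.append(result.summary_text())
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(summary_lines))
    logger.info("fit: %d models -> %s", len(cfg.responses), outdir)
    return summary


def stage_report(cfg: PipelineConfig) -> Path:
    """Confidence-interval plots per significant factor plus the run log."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    from .models import FACTOR_CODING

    index_path = cfg.output_dir / "index_table.csv"
    modeldir = cfg.output_dir / "models"
    if not index_path.exists():
        raise PipelineError("index_table.csv missing: run stage 'indices' first")
    if not modeldir.exists():
        raise PipelineError("models/ missing: run stage 'fit' first")
    index = read_index_table(index_path)
    figdir = cfg.output_dir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    for response in cfg.responses:
        anova_path = modeldir / f"{response}_anova.csv"
        if not anova_path.exists():
            continue
        anova = pd.read_csv(anova_path)
        for _, row in anova[anova["p"] < 0.05].iterrows():
            factor = row["factor"]
            col, ref, alt = FACTOR_CODING[factor]
            sub = index[index[response].notna()]
            fig, ax = plt.subplots(figsize=(3.2, 3.2))
            for x, level in enumerate((ref, alt)):
                vals = sub.loc[sub[col] == level, response].to_numpy(float)
                m = vals.mean()
                half = sps.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / len(vals) ** 0.5
                ax.errorbar([x], [m], yerr=[half], fmt="o", capsize=4, color="k")
            ax.set_xticks([0, 1], [str(ref), str(alt)])
            ax.set_xlim(-0.5, 1.5)
            ax.set_xlabel(factor)
            ax.set_ylabel(response)
            fig.tight_layout()
            fig.savefig(figdir / f"{response}_{factor}.png", dpi=120)
            plt.close(fig)

    log = {
        "package_version": __version__,
        "seed": cfg.seed,
        "season_rule": {str(m): s for m, s in sorted(cfg.season_rule.month_to_season.items())},
        "responses": list(cfg.responses),
        "simulated": cfg.simulation is not None,
        "library_versions": _library_versions(),
    }
    out = cfg.output_dir / "run_log.json"
    out.write_text(json.dumps(log, indent=1))
    logger.info("report -> %s", figdir)
    return out


def _library_versions() -> dict[str, str]:
    import matplotlib
    import networkx
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
        "matplotlib": matplotlib.__version__,
    }


STAGES = ("simulate", "validate", "networks", "indices", "fit", "report")


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """All stages in order; stage failures abort with the stage name."""
    artifacts: dict[str, object] = {}
    stage_fns = {
        "simulate": stage_simulate,
        "validate": stage_validate,
        "networks": stage_networks,
        "indices": stage_indices,
        "fit": stage_fit,
        "report": stage_report,
    }
    for name in STAGES:
        if name == "simulate" and cfg.simulation is None:
            continue
        try:
            artifacts[name] = stage_fns[name](cfg)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return artifacts
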