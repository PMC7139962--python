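"""Stage orchestration: simulate -> energy -> decompose -> entropy ->
geometry -> states -> report.

Each stage is a pure function of the run config and the preceding
stages' in-memory results; every emitted TSV carries a header recording
the package version, the config hash and the explicit config overrides,
so identical reruns produce byte-identical bodies.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .mmgbsa import (
    DEFAULT_PARAMS,
    EnergyModelParams,
    aggregate_replicas,
    decomposition_frame,
    per_residue_decomposition,
    snapshot_binding_components,
)
from .molsys import (
    MolecularSystem,
    Trajectory,
    load_parameters,
    load_structure,
    load_trajectory,
    select_atoms,
    write_pdb,
)
from .nma_entropy import entropy_term
from .state_analysis import StateThresholds, classify_states, derive_thresholds, pearson_r
from .synthetic_data import (
    ToySystemSpec,
    TwoStateSpec,
    make_fluctuating_trajectory,
    make_toy_system,
    make_two_state_series,
    receptor_ligand_split,
)
from .traj_geometry import (
    DistanceDefinition,
    distance_series,
    hbond_occupancy,
    rmsd_series,
    rmsf,
)

__all__ = ["PipelineError", "StageFailure", "PipelineResult", "run_pipeline", "write_report_tables"]

log = logging.getLogger("ribostate")


class PipelineError(RuntimeError):
    pass


class StageFailure(PipelineError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: RunConfig
    outputs: dict[str, Path] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    values: dict[str, float] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def _header(cfg: RunConfig) -> str:
    lines = [
        f"# ribostate {__version__}",
        f"# config_sha256 {cfg.config_hash()}",
    ]
    for k, v in sorted(cfg.overrides().items()):
        lines.append(f"# override {k}: {v}")
    return "\n".join(lines) + "\n"


def _write_tsv(cfg: RunConfig, out_dir: Path, name: str, df: pd.DataFrame) -> Path:
    path = out_dir / name
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path


def _energy_model(cfg: RunConfig) -> EnergyModelParams:
    if not cfg.energy_params:
        return DEFAULT_PARAMS
    base = {f: getattr(DEFAULT_PARAMS, f) for f in DEFAULT_PARAMS.__dataclass_fields__}
    base.update(cfg.energy_params)
    return EnergyModelParams(**base)


@dataclass
class _Context:
    system: MolecularSystem | None = None
    trajectory: Trajectory | None = None
    receptor: Any = None
    ligand: Any = None
    d1_series: np.ndarray | None = None
    d1_labels: np.ndarray | None = None
    two_state_spec: TwoStateSpec | None = None
    energy_result: Any = None
    components_by_replica: dict[int, list] | None = None
    tds: float = 0.0
    tds_sigma: float = 0.0


def _analysis_frames(cfg: RunConfig, traj: Trajectory) -> np.ndarray:
    """Trailing-window, strided snapshot selection (mirrors the
    last-half / fixed-interval cadence of the energy protocol)."""
    start = int(round((1.0 - cfg.snapshot_fraction) * traj.n_frames))
    return traj.frames[start :: max(1, cfg.snapshot_stride)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    syn = cfg.synthetic or {}
    toy_kwargs = dict(syn.get("toy_system", {}))
    toy_kwargs.setdefault("seed", cfg.seed)
    spec = ToySystemSpec(**toy_kwargs)
    system, frame = make_toy_system(spec)
    traj_kwargs = dict(syn.get("trajectory", {}))
    n_frames = int(traj_kwargs.pop("n_frames", 20))
    sd = float(traj_kwargs.pop("per_atom_sd", 0.1))
    ctx.system = system
    ctx.trajectory = make_fluctuating_trajectory(
        frame, np.full(system.n_atoms, sd), n_frames, seed=cfg.seed, **traj_kwargs
    )
    rec, lig = receptor_ligand_split(system)
    ctx.receptor, ctx.ligand = rec, lig
    ts_kwargs = dict(syn.get("two_state", {}))
    ts_kwargs.setdefault("seed", cfg.seed)
    ctx.two_state_spec = TwoStateSpec(**ts_kwargs)
    ctx.d1_series, ctx.d1_labels = make_two_state_series(ctx.two_state_spec)
    res.outputs["trajectory_pdb"] = out_dir / "synthetic_trajectory.pdb"
    res.outputs["trajectory_pdb"].write_text(write_pdb(system, ctx.trajectory.frames))
    df = pd.DataFrame({"frame": np.arange(len(ctx.d1_series)), "d1": ctx.d1_series,
                       "true_state": ctx.d1_labels})
    res.tables["d1_series"] = df
    res.outputs["d1_series"] = _write_tsv(cfg, out_dir, "d1_series.tsv", df)


def _load_inputs(cfg: RunConfig, ctx: _Context) -> None:
    if ctx.system is not None:
        return
    if "structure" not in cfg.inputs:
        raise PipelineError("no synthetic spec and no structure input given")
    system, frame = load_structure(Path(cfg.inputs["structure"]).read_text())
    if "parameters" in cfg.inputs:
        load_parameters(Path(cfg.inputs["parameters"]).read_text(), system)
    if "trajectory" in cfg.inputs:
        ctx.trajectory = load_trajectory(Path(cfg.inputs["trajectory"]).read_text())
    else:
        ctx.trajectory = Trajectory(frames=frame[None])
    ctx.system = system
    if "receptor" in cfg.selections:
        ctx.receptor = select_atoms(system, cfg.selections["receptor"]).indices
    if "ligand" in cfg.selections:
        ctx.ligand = select_atoms(system, cfg.selections["ligand"]).indices


def _split_replicas(frames: np.ndarray, n_replicas: int) -> dict[int, np.ndarray]:
    chunks = np.array_split(np.arange(len(frames)), n_replicas)
    return {r: frames[c] for r, c in enumerate(chunks) if len(c)}


def _stage_energy(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    _load_inputs(cfg, ctx)
    if ctx.receptor is None or ctx.ligand is None:
        raise PipelineError("energy stage needs receptor/ligand selections")
    params = _energy_model(cfg)
    frames = _analysis_frames(cfg, ctx.trajectory)
    groups: dict[int, list] = {}
    for rep, chunk in _split_replicas(frames, cfg.n_replicas).items():
        groups[rep] = [
            snapshot_binding_components(ctx.system, f, ctx.receptor, ctx.ligand, params)
            for f in chunk
        ]
    ctx.components_by_replica = groups
    ctx.energy_result = aggregate_replicas(groups, ctx.tds, ctx.tds_sigma, cfg.temperature)
    res.values["dG_bind"] = ctx.energy_result["dG_bind"]
    res.values["dH"] = ctx.energy_result["dH"]


def _stage_decompose(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    _load_inputs(cfg, ctx)
    params = _energy_model(cfg)
    frames = _analysis_frames(cfg, ctx.trajectory)
    contribs = per_residue_decomposition(ctx.system, frames, ctx.receptor, ctx.ligand, params)
    df = decomposition_frame(contribs)
    res.tables["decomposition"] = df
    res.outputs["decomposition"] = _write_tsv(cfg, out_dir, "per_residue.tsv", df)


def _stage_entropy(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    _load_inputs(cfg, ctx)
    params = _energy_model(cfg)
    frames = _analysis_frames(cfg, ctx.trajectory)
    traj = Trajectory(frames=frames, frame_interval=ctx.trajectory.frame_interval)
    n_snap = max(1, len(frames) // max(1, cfg.entropy_stride))
    result = entropy_term(
        ctx.system, traj, ctx.receptor, ctx.ligand,
        temperature=cfg.temperature, n_snapshots=n_snap, params=params,
    )
    ctx.tds, ctx.tds_sigma = result.t_delta_s, result.sigma
    res.values["TdS"] = result.t_delta_s
    res.tables["entropy_log"] = result.log
    res.outputs["entropy_log"] = _write_tsv(cfg, out_dir, "entropy_log.tsv", result.log)
    if ctx.energy_result is not None:  # refresh dG_bind with the entropy term
        ctx.energy_result = aggregate_replicas(
            ctx.components_by_replica, ctx.tds, ctx.tds_sigma, cfg.temperature
        )
        res.values["dG_bind"] = ctx.energy_result["dG_bind"]


def _stage_geometry(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    _load_inputs(cfg, ctx)
    traj = ctx.trajectory
    sel = ctx.system.all_atoms()
    series, _hist = rmsd_series(traj, traj.frames[0], sel)
    df_rmsd = pd.DataFrame({"frame": np.arange(len(series)), "rmsd": series})
    res.tables["rmsd"] = df_rmsd
    res.outputs["rmsd"] = _write_tsv(cfg, out_dir, "rmsd.tsv", df_rmsd)
    df_rmsf = rmsf(traj, sel)
    res.tables["rmsf"] = df_rmsf
    res.outputs["rmsf"] = _write_tsv(cfg, out_dir, "rmsf.tsv", df_rmsf)
    hb = cfg.hbonds
    records = hbond_occupancy(
        ctx.system, traj, dist_cut=hb.get("dist_cut", 3.5), angle_cut=hb.get("angle_cut", 135.0)
    )
    df_hb = pd.DataFrame(
        [
            {
                "donor": r.donor, "hydrogen": r.hydrogen, "acceptor": r.acceptor,
                "occupancy": r.occupancy, "mean_distance": r.mean_distance,
                "mean_angle": r.mean_angle,
            }
            for r in records
        ]
    )
    res.tables["hbonds"] = df_hb
    res.outputs["hbonds"] = _write_tsv(cfg, out_dir, "hbonds.tsv", df_hb)
    rows = []
    for dd_cfg in cfg.distances:
        dd = DistanceDefinition(
            label=dd_cfg["label"],
            group_a=select_atoms(ctx.system, dd_cfg["group_a"]),
            group_b=select_atoms(ctx.system, dd_cfg["group_b"]),
        )
        dseries, mean, sd = distance_series(traj, dd)
        rows.append({"label": dd.label, "mean": mean, "sd": sd})
        if dd.label.upper() == "D1":
            ctx.d1_series = dseries
    if rows:
        df_d = pd.DataFrame(rows)
        res.tables["distances"] = df_d
        res.outputs["distances"] = _write_tsv(cfg, out_dir, "distances.tsv", df_d)


def _stage_states(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    if ctx.d1_series is None:
        raise PipelineError("states stage needs a D1 series (simulate or geometry first)")
    if cfg.thresholds is not None:
        thr = StateThresholds(source="configured", **cfg.thresholds)
    elif cfg.derive_thresholds is not None:
        raise PipelineError("derive_thresholds requires bound and apo series inputs")
    else:
        thr = StateThresholds(closed_max=20.59, open_min=22.98, source="configured")
    ss = classify_states(ctx.d1_series, thr)
    df = pd.DataFrame(
        [
            {
                "pct_open": ss.pct_open,
                "pct_middle": ss.pct_middle,
                "pct_closed": ss.pct_closed,
                "closed_max": thr.closed_max,
                "open_min": thr.open_min,
                "threshold_source": thr.source,
                "tie_rule": "strict (boundary -> middle)",
            }
        ]
    )
    res.tables["states"] = df
    res.outputs["states"] = _write_tsv(cfg, out_dir, "states.tsv", df)
    res.values["pct_open"] = ss.pct_open
    res.values["pct_closed"] = ss.pct_closed
    if ctx.two_state_spec is not None:
        res.values["planted_p_open"] = 100.0 * ctx.two_state_spec.stationary_p_open


def _stage_report(cfg: RunConfig, ctx: _Context, out_dir: Path, res: PipelineResult) -> None:
    if ctx.energy_result is None:
        return
    df = write_report_tables(ctx.energy_result)
    res.tables["energy_table"] = df
    res.outputs["energy_table"] = _write_tsv(cfg, out_dir, "energy_table.tsv", df)


def write_report_tables(result) -> pd.DataFrame:
    """Energy report rows with mean ± sigma cells plus an internal audit.

    Derived rows recomputed from component rows must match the stored
    derived rows; a mismatch beyond 0.01 kcal/mol raises.
    """
    df = result.summary().reset_index()
    m = result.means
    audits = {
        "dH": m["dE_ele"] + m["dE_vdw"] + m["dE_int"] + m["dG_pol"] + m["dG_nonpol"],
        "dG_ele_pol": m["dE_ele"] + m["dG_pol"],
        "dG_vdw_nonpol": m["dE_vdw"] + m["dG_nonpol"],
        "dG_bind": m["dH"] - m["TdS"],
    }
    for term, recomputed in audits.items():
        if abs(recomputed - m[term]) > 0.01:
            raise PipelineError(f"internal audit failed for {term}")
    return df


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "energy": _stage_energy,
    "decompose": _stage_decompose,
    "entropy": _stage_entropy,
    "geometry": _stage_geometry,
    "states": _stage_states,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages in canonical order."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config=config)
    ctx = _Context()
    order = [s for s in _STAGE_FUNCS if s in config.stages]
    for stage in order:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, ctx, out_dir, res)
        except PipelineError:
            raise
        except Exception as exc:  # preserve artifacts written so far
            log.error("stage %s failed: %s", stage, exc)
            raise StageFailure(stage, exc) from exc
        res.timings[stage] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", stage, res.timings[stage])
    return res
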