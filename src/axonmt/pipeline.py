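"""Pipeline configuration and the simulate -> analyze -> report chain.

A single TOML-style config selects which analysis arms to run (fdap, smlm,
tracks, phospho) and their parameters; unknown keys are rejected.  Each arm
either loads declared input files or simulates its inputs with the
synthetic-data generators, runs the corresponding analysis, and contributes
per-condition summaries (mean +- SEM) to a consolidated report.  All
randomness flows through the single seed in the config, and identical
config + seed give a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, arraystats, fdap, filaments, phospho, smlm, synth, transport

__all__ = ["PipelineConfig", "RunReport", "load_config", "run_pipeline"]


@dataclass
class FdapArmConfig:
    enabled: bool = True
    presets: list[str] = field(default_factory=lambda: ["control", "h2o2"])
    n_curves: int = 20
    noise_sd: float = 0.02
    d_fixed_um2_s: float = 3.0
    manifest: str | None = None  # analyze files instead of simulating


@dataclass
class SmlmArmConfig:
    enabled: bool = False
    scenario: str = "pc12"  # pc12 | drg
    n_cells: int = 2
    section_thickness_nm: float = 150.0
    locs_files: list[str] = field(default_factory=list)


@dataclass
class TracksArmConfig:
    enabled: bool = False
    n_cells: int = 3
    n_particles: int = 40
    mobile_fraction: float = 0.6
    detections_files: list[str] = field(default_factory=list)


@dataclass
class PhosphoArmConfig:
    enabled: bool = False
    sites_a: str | None = None
    sites_b: str | None = None
    sites_per_condition: list[int] = field(default_factory=lambda: [40, 82])
    shared_count: int = 4


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "axonmt_out"
    fdap: FdapArmConfig = field(default_factory=FdapArmConfig)
    smlm: SmlmArmConfig = field(default_factory=SmlmArmConfig)
    tracks: TracksArmConfig = field(default_factory=TracksArmConfig)
    phospho: PhosphoArmConfig = field(default_factory=PhosphoArmConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    arms: dict = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "arms": self.arms,
                "warnings": self.warnings_,
            },
            indent=1,
            sort_keys=True,
        )


def _build(cls, payload: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in [{context}]: {sorted(unknown)}")
    return cls(**payload)


def load_config(path) -> PipelineConfig:
    """Parse a TOML config file, rejecting unknown keys."""
    import tomllib

    payload = tomllib.loads(Path(path).read_text())
    arms = {}
    for arm, cls in (
        ("fdap", FdapArmConfig),
        ("smlm", SmlmArmConfig),
        ("tracks", TracksArmConfig),
        ("phospho", PhosphoArmConfig),
    ):
        if arm in payload:
            arms[arm] = _build(cls, payload.pop(arm), arm)
    top = {k: v for k, v in payload.items()}
    unknown = set(top) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return PipelineConfig(**top, **arms)


def _mean_sem(values) -> dict:
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return {"mean": None, "sem": None, "n": 0}
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return {"mean": float(values.mean()), "sem": sem, "n": int(values.size)}


def _check_inputs_exist(cfg: PipelineConfig) -> None:
    paths = []
    if cfg.fdap.enabled and cfg.fdap.manifest:
        paths.append(cfg.fdap.manifest)
    paths.extend(cfg.smlm.locs_files if cfg.smlm.enabled else [])
    paths.extend(cfg.tracks.detections_files if cfg.tracks.enabled else [])
    if cfg.phospho.enabled:
        paths.extend(p for p in (cfg.phospho.sites_a, cfg.phospho.sites_b) if p)
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")


def _run_fdap_arm(cfg: PipelineConfig) -> dict:
    from . import io as io_mod

    arm = cfg.fdap
    by_condition: dict[str, list[float]] = {}
    if arm.manifest:
        manifest = io_mod.read_manifest(arm.manifest)
        base = Path(arm.manifest).parent
        groups = [
            (str(row.condition), io_mod.read_fdap_csv(base / row.file))
            for row in manifest.itertuples()
        ]
    else:
        groups = []
        for i, preset in enumerate(arm.presets):
            curves, _ = synth.gen_fdap(preset, arm.n_curves, arm.noise_sd, seed=cfg.seed + 1000 * i)
            groups.extend((preset, c) for c in curves)
    for condition, curve in groups:
        fit = fdap.fit_reaction_diffusion(curve, D_fixed_um2_s=arm.d_fixed_um2_s)
        by_condition.setdefault(condition, []).append(fit.bound_fraction)
    return {
        "bound_fraction": {cond: _mean_sem(v) for cond, v in sorted(by_condition.items())},
    }


def _run_smlm_arm(cfg: PipelineConfig) -> dict:
    from . import io as io_mod

    arm = cfg.smlm
    model = synth.ArrayModel.drg() if arm.scenario == "drg" else synth.ArrayModel.pc12()
    stats_rows = {"mass_um": [], "mean_length_um": [], "mean_straightness": [], "density_per_um": []}
    if arm.locs_files:
        tables = [io_mod.read_localizations_csv(p) for p in arm.locs_files]
    else:
        tables = [
            synth.gen_microtubule_array(model, seed=cfg.seed + 2000 + i)[2] for i in range(arm.n_cells)
        ]
    for locs in tables:
        volume = smlm.render_volume(locs)
        z_mid = volume.origin_nm[2] + volume.intensity.shape[2] * volume.voxel_size_nm[2] / 2
        section = smlm.select_section(volume, z_mid, arm.section_thickness_nm)
        retained = filaments.extract_filaments(section).filaments
        # filament points are (row, col) nm with rows along the process axis
        roi = arraystats.RoiSpec(
            origin_nm=(0.0, 0.0), axis=(1.0, 0.0), length_nm=model.box_length_um * 1000, width_nm=model.box_width_um * 1000
        )
        st = arraystats.compute_stats(retained, roi)
        stats_rows["mass_um"].append(st.mass_um)
        stats_rows["mean_length_um"].append(st.mean_length_um)
        stats_rows["mean_straightness"].append(st.mean_straightness)
        stats_rows["density_per_um"].append(st.density_per_um)
    return {k: _mean_sem(v) for k, v in stats_rows.items()}


def _run_tracks_arm(cfg: PipelineConfig) -> dict:
    from . import io as io_mod

    arm = cfg.tracks
    if arm.detections_files:
        tables = [io_mod.read_detections_csv(p) for p in arm.detections_files]
    else:
        model = synth.MotilityModel(mobile_fraction=arm.mobile_fraction)
        tables = [
            synth.gen_vesicle_series(model, arm.n_particles, seed=cfg.seed + 3000 + i)[0]
            for i in range(arm.n_cells)
        ]
    fractions, velocities, speeds = [], [], []
    for dets in tables:
        tracks = transport.filter_tracks(transport.link_tracks(dets))
        summary = transport.summarize_cell(tracks)
        if summary.mobile_fraction is not None:
            fractions.append(summary.mobile_fraction)
        if summary.mean_velocity_um_s is not None:
            velocities.append(summary.mean_velocity_um_s)
            speeds.append(summary.mean_speed_um_s)
    return {
        "mobile_fraction": _mean_sem(fractions),
        "mean_velocity_um_s": _mean_sem(velocities),
        "mean_speed_um_s": _mean_sem(speeds),
    }


def _run_phospho_arm(cfg: PipelineConfig) -> dict:
    from . import io as io_mod

    arm = cfg.phospho
    if arm.sites_a and arm.sites_b:
        table_a = io_mod.read_sites_tsv(arm.sites_a)
        table_b = io_mod.read_sites_tsv(arm.sites_b)
    else:
        table_a, table_b, _ = synth.gen_phospho_tables(
            sites_per_condition=tuple(arm.sites_per_condition),
            shared_count=arm.shared_count,
            seed=cfg.seed + 4000,
        )
    up_a, _ = phospho.filter_significant(table_a)
    up_b, _ = phospho.filter_significant(table_b)
    overlap = phospho.compare_conditions(up_a, up_b)
    counts = phospho.count_sites_per_protein(up_a)
    return {
        "n_up_a": overlap.n_a,
        "n_up_b": overlap.n_b,
        "n_shared": overlap.n_shared,
        "fraction_of_b_shared": overlap.fraction_of_b_shared,
        "top_protein": counts.iloc[0]["gene"] if len(counts) else None,
    }


_ARM_RUNNERS = {
    "fdap": _run_fdap_arm,
    "smlm": _run_smlm_arm,
    "tracks": _run_tracks_arm,
    "phospho": _run_phospho_arm,
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the enabled analysis arms and build a consolidated report.

    Missing configured inputs fail before any computation; a failure inside
    one arm marks that arm failed in the report while the others complete.
    """
    _check_inputs_exist(config)
    report = RunReport(version=__version__, config_hash=config.config_hash())
    for arm, runner in _ARM_RUNNERS.items():
        if not getattr(config, arm).enabled:
            continue
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                report.arms[arm] = {"status": "ok", "summary": runner(config)}
            for w in caught:
                report.warnings_.append(f"{arm}: {w.message}")
        except Exception as exc:  # partial-arm failure: report and continue
            report.arms[arm] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
    return report
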