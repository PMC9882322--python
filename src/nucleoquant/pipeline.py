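"""Reproducible simulate -> analyze runs: configuration, staging, reports.

A run is described by a :class:`RunConfig` (YAML-serializable); ``run``
executes the requested stages in order, derives one deterministic sub-seed
per stage from the global seed, writes every artifact plus the resolved
configuration under the output directory, and returns an artifact manifest.
Identical config + seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afm, condensate, emsa, io, kinetics, synthetic
from .errors import ConfigError

logger = logging.getLogger("nucleoquant")

KNOWN_STAGES = (
    "simulate_afm",
    "trace_afm",
    "simulate_condensate",
    "condensates",
    "simulate_kinetics",
    "kinetics",
    "simulate_emsa",
    "emsa",
    "report",
)

#: per-stage sub-seed offsets (stable, order-independent)
_STAGE_OFFSET = {name: i + 1 for i, name in enumerate(KNOWN_STAGES)}


@dataclass
class RunConfig:
    """Full pipeline configuration; serializes losslessly to YAML."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(KNOWN_STAGES))
    # synthetic AFM scene
    n_chains: int = 9
    contour_length_nm: float = 383.0
    persistence_length_nm: float = 50.0
    pixel_size_nm: float = 1.0
    dna_height_nm: float = 2.0
    tip_sigma_nm: float = 2.0
    afm_noise_nm: float = 0.05
    particle_mean: float = 2.2
    particle_volume_nm3: float = synthetic.DEFAULT_PARTICLE_VOLUME
    end_bias: float = 0.5
    # AFM analysis
    exclude_threshold_nm: float = 0.5
    height_threshold_nm: float = 0.3
    min_area_px: int = 30
    min_branch_length_px: int = 5
    particle_height_cutoff_nm: float = 1.2
    end_distance_cutoff_nm: float = 10.0
    path_rule: str = "sum"
    # condensates
    n_condensates: int = 6
    core_radius_nm: float = 940.0
    halo_thickness_nm: float = 657.0
    condensate_pixel_size_nm: float = 100.0
    condensate_noise: float = 0.05
    angular_step_deg: float = 10.0
    # kinetics
    decay_rate_per_s: float = synthetic.DEFAULT_DECAY_RATE
    frame_interval_s: float = 2.0
    n_frames: int = 60
    n_traces: int = 20
    trace_noise: float = 0.05
    fit_baseline: bool = False
    # EMSA
    c50_nM: float = 90.0
    emsa_steepness: float = 2.0
    emsa_noise: float = 0.02
    emsa_replicates: int = 3
    emsa_concentrations: list[float] = field(
        default_factory=lambda: [10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0]
    )

    def validate(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        positive = {
            "contour_length_nm": self.contour_length_nm,
            "persistence_length_nm": self.persistence_length_nm,
            "pixel_size_nm": self.pixel_size_nm,
            "height_threshold_nm": self.height_threshold_nm,
            "core_radius_nm": self.core_radius_nm,
            "condensate_pixel_size_nm": self.condensate_pixel_size_nm,
            "frame_interval_s": self.frame_interval_s,
            "c50_nM": self.c50_nM,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        non_negative = {
            "afm_noise_nm": self.afm_noise_nm,
            "tip_sigma_nm": self.tip_sigma_nm,
            "condensate_noise": self.condensate_noise,
            "trace_noise": self.trace_noise,
            "decay_rate_per_s": self.decay_rate_per_s,
        }
        for name, val in non_negative.items():
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")
        if not 0 <= self.end_bias <= 1:
            raise ConfigError("end_bias must be in [0, 1]")
        if self.path_rule not in ("sum", "longest"):
            raise ConfigError("path_rule must be 'sum' or 'longest'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(config: RunConfig, stage: str) -> int:
    return int(
        np.random.SeedSequence(
            config.seed, spawn_key=(_STAGE_OFFSET[stage],)
        ).generate_state(1)[0]
        % (2**31 - 1)
    )


# ---------------------------------------------------------------------------
# stages


def _stage_simulate_afm(config: RunConfig, out: Path, artifacts: dict) -> None:
    wlc = synthetic.WLCParams(
        contour_length=config.contour_length_nm,
        persistence_length=config.persistence_length_nm,
        seed=_stage_seed(config, "simulate_afm"),
    )
    hm, manifest = synthetic.simulate_afm_scene(
        n_chains=config.n_chains,
        wlc=wlc,
        rp=None,
        particle_mean=config.particle_mean,
        end_bias=config.end_bias,
        particle_volume=config.particle_volume_nm3,
        seed=_stage_seed(config, "simulate_afm"),
    )
    io.write_height_map(out / "afm_scene.tif", hm)
    manifest.to_yaml(out / "afm_manifest.yaml")
    artifacts["afm_scene"] = "afm_scene.tif"
    artifacts["afm_manifest"] = "afm_manifest.yaml"


def _stage_trace_afm(config: RunConfig, out: Path, artifacts: dict) -> None:
    hm = io.read_height_map(out / "afm_scene.tif")
    traces, particles, volumes, h_b = afm.analyze_height_map(
        hm,
        exclude_threshold=config.exclude_threshold_nm,
        height_threshold=config.height_threshold_nm,
        min_area=config.min_area_px,
        min_branch_length=config.min_branch_length_px,
        particle_height_cutoff=config.particle_height_cutoff_nm,
        end_distance_cutoff=config.end_distance_cutoff_nm,
        path_rule=config.path_rule,
    )
    per_molecule, grouped = afm.summarize_scene(traces, particles, volumes)
    per_molecule.to_csv(out / "molecules.csv", index=False)
    grouped.to_csv(out / "afm_summary.csv", index=False)
    prows = [
        {
            "molecule_id": p.molecule_id,
            "particle_id": p.particle_id,
            "centroid_y_nm": p.centroid_nm[0],
            "centroid_x_nm": p.centroid_nm[1],
            "volume_nm3": p.volume_nm3,
            "class": p.placement_class,
        }
        for plist in particles
        for p in plist
    ]
    pd.DataFrame(
        prows,
        columns=[
            "molecule_id",
            "particle_id",
            "centroid_y_nm",
            "centroid_x_nm",
            "volume_nm3",
            "class",
        ],
    ).to_csv(out / "particles.csv", index=False)
    artifacts["molecules"] = "molecules.csv"
    artifacts["particles"] = "particles.csv"
    artifacts["afm_summary"] = "afm_summary.csv"
    logger.info("trace_afm: %d molecules, background %.3f nm", len(traces), h_b)


def _stage_simulate_condensate(config: RunConfig, out: Path, artifacts: dict) -> None:
    img, manifest = synthetic.simulate_condensate_field(
        n_condensates=config.n_condensates,
        core_radius=config.core_radius_nm,
        halo_thickness=config.halo_thickness_nm,
        noise=config.condensate_noise,
        pixel_size=config.condensate_pixel_size_nm,
        seed=_stage_seed(config, "simulate_condensate"),
    )
    io.write_multichannel(
        out / "condensates.tif", img, config.condensate_pixel_size_nm
    )
    manifest.to_yaml(out / "condensate_manifest.yaml")
    artifacts["condensate_image"] = "condensates.tif"
    artifacts["condensate_manifest"] = "condensate_manifest.yaml"


def _stage_condensates(config: RunConfig, out: Path, artifacts: dict) -> None:
    img, px = io.read_multichannel(out / "condensates.tif")
    _, table, summary = condensate.morphometry_table(
        img, px, angular_step=config.angular_step_deg
    )
    table.to_csv(out / "condensate_table.csv", index=False)
    summary.to_csv(out / "condensate_summary.csv", index=False)
    artifacts["condensate_table"] = "condensate_table.csv"
    artifacts["condensate_summary"] = "condensate_summary.csv"


def _stage_simulate_kinetics(config: RunConfig, out: Path, artifacts: dict) -> None:
    times, counts, manifest = synthetic.simulate_decay_traces(
        k=config.decay_rate_per_s,
        dt=config.frame_interval_s,
        n_frames=config.n_frames,
        n_traces=config.n_traces,
        noise_model="multiplicative",
        noise_level=config.trace_noise,
        seed=_stage_seed(config, "simulate_kinetics"),
    )
    io.write_traces_csv(out / "traces.csv", times, counts)
    manifest.to_yaml(out / "kinetics_manifest.yaml")
    artifacts["traces"] = "traces.csv"
    artifacts["kinetics_manifest"] = "kinetics_manifest.yaml"


def _stage_kinetics(config: RunConfig, out: Path, artifacts: dict) -> None:
    traces = io.read_traces_csv(out / "traces.csv")
    rows = []
    for tid, (times, counts) in sorted(traces.items()):
        norm = kinetics.normalize_trace(counts)
        fit = kinetics.fit_dissociation_rate(
            times, norm, with_baseline=config.fit_baseline
        )
        rows.append(
            {
                "trace_id": tid,
                "k_per_s": fit.k,
                "k_stderr": fit.k_stderr,
                "n_frames": len(times),
            }
        )
    pd.DataFrame(
        rows, columns=["trace_id", "k_per_s", "k_stderr", "n_frames"]
    ).to_csv(out / "kinetics_fits.csv", index=False)
    artifacts["kinetics_fits"] = "kinetics_fits.csv"


def _stage_simulate_emsa(config: RunConfig, out: Path, artifacts: dict) -> None:
    table, _ = synthetic.simulate_binding_table(
        c50=config.c50_nM,
        concentrations=np.asarray(config.emsa_concentrations),
        steepness=config.emsa_steepness,
        noise=config.emsa_noise,
        n_replicates=config.emsa_replicates,
        seed=_stage_seed(config, "simulate_emsa"),
    )
    table.to_csv(out / "binding.csv", index=False)
    artifacts["binding"] = "binding.csv"


def _stage_emsa(config: RunConfig, out: Path, artifacts: dict) -> None:
    df = pd.read_csv(out / "binding.csv")
    result = emsa.c50_by_substrate(df)
    result.to_csv(out / "c50.csv", index=False)
    artifacts["c50"] = "c50.csv"


def _stage_report(config: RunConfig, out: Path, artifacts: dict) -> None:
    rows = []
    if (out / "afm_summary.csv").exists():
        g = pd.read_csv(out / "afm_summary.csv", dtype={"n_particles_bin": str})
        for _, r in g.iterrows():
            rows.append(
                {
                    "stage": "afm",
                    "metric": f"contour_length_mean_nm[N_p={r['n_particles_bin']}]",
                    "value": r["contour_length_mean_nm"],
                }
            )
        mols = pd.read_csv(out / "molecules.csv")
        rows.append({"stage": "afm", "metric": "n_molecules", "value": len(mols)})
        if len(mols):
            rows.append(
                {
                    "stage": "afm",
                    "metric": "mean_particles_per_molecule",
                    "value": mols["n_particles"].mean(),
                }
            )
    if (out / "condensate_summary.csv").exists():
        s = pd.read_csv(out / "condensate_summary.csv").iloc[0]
        rows.append(
            {
                "stage": "condensate",
                "metric": "core_radius_median_um",
                "value": s["core_radius_median_um"],
            }
        )
        rows.append(
            {
                "stage": "condensate",
                "metric": "halo_thickness_median_um",
                "value": s["halo_thickness_median_um"],
            }
        )
    if (out / "kinetics_fits.csv").exists():
        f = pd.read_csv(out / "kinetics_fits.csv")
        rows.append(
            {"stage": "kinetics", "metric": "k_mean_per_s", "value": f["k_per_s"].mean()}
        )
    if (out / "c50.csv").exists():
        c = pd.read_csv(out / "c50.csv")
        for _, r in c.iterrows():
            rows.append(
                {
                    "stage": "emsa",
                    "metric": f"c50_nM[{r['substrate']}]",
                    "value": r["c50_nM"],
                }
            )
    pd.DataFrame(rows, columns=["stage", "metric", "value"]).to_csv(
        out / "report.csv", index=False
    )
    artifacts["report"] = "report.csv"


_STAGE_FUNCS = {
    "simulate_afm": _stage_simulate_afm,
    "trace_afm": _stage_trace_afm,
    "simulate_condensate": _stage_simulate_condensate,
    "condensates": _stage_condensates,
    "simulate_kinetics": _stage_simulate_kinetics,
    "kinetics": _stage_kinetics,
    "simulate_emsa": _stage_simulate_emsa,
    "emsa": _stage_emsa,
    "report": _stage_report,
}


def run(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages; returns the artifact manifest.

    The resolved configuration is written beside the outputs before any
    computation. Raises on the first stage failure.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    artifacts: dict = {"resolved_config": "resolved_config.yaml"}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, out, artifacts)
    manifest = {
        name: {
            "path": rel,
            "sha256": hashlib.sha256((out / rel).read_bytes()).hexdigest(),
        }
        for name, rel in sorted(artifacts.items())
    }
    with open(out / "artifacts.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
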