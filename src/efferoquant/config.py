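"""Run configuration: strict YAML schema and provenance capture.

One flat schema with per-stage parameter sub-blocks; unknown keys are hard
errors (silent typo-defaults are worse than a failed run).  Every run writes
a provenance record — parameters, package version, seed, input checksums —
sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, missing input, bad value)."""


#: Allowed parameter keys per stage sub-block.
STAGE_SCHEMAS: dict[str, set[str]] = {
    "simulate": {"kind", "field_size_nm", "mode", "species_densities",
                 "cluster_diameter_nm", "cluster_occupancy", "contact_gap_nm",
                 "localization_precision_sd_nm", "n_clusters",
                 "n_steps", "unit_intensity", "frame_interval_s",
                 "bleach_rate", "noise_sd", "baseline",
                 "model", "d_um2_s", "corral_diameter_nm", "velocity_um_s",
                 "n_tracks", "track_length", "localization_error_sd_nm",
                 "n_cells", "beads_internal_per_cell",
                 "beads_external_per_cell", "scene_mode"},
    "smlm": {"command", "reference", "target", "roi", "bin_width_nm",
             "r_max_nm", "n_reps", "min_points", "max_reach_nm",
             "contact_dist_nm", "intermix_frac", "n_random"},
    "bleach": {"trace", "penalty", "min_step_size", "window_last_k",
               "direct_count_limit", "baseline"},
    "fret": {"command", "stack", "donor_only", "acceptor_only", "unstained",
             "roi", "pixel_size_nm", "e_max", "iaa_floor"},
    "spt": {"tracks", "max_precision_nm", "min_length", "frame_interval_s",
            "fit_lags", "slope_low", "slope_high"},
    "morph": {"command", "scene", "mode", "outside_overlap_threshold",
              "control_mean"},
}

TOP_LEVEL_KEYS = {"stage", "seed", "out", "params", "inputs"}


@dataclass
class RunConfig:
    stage: str
    seed: int = 0
    out: str = "results"
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - TOP_LEVEL_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        stage = raw.get("stage")
        if stage not in STAGE_SCHEMAS:
            raise ConfigError(
                f"stage must be one of {sorted(STAGE_SCHEMAS)}, got {stage!r}"
            )
        params = raw.get("params") or {}
        bad = set(params) - STAGE_SCHEMAS[stage]
        if bad:
            raise ConfigError(
                f"unknown parameter key(s) for stage {stage!r}: {sorted(bad)}"
            )
        return cls(stage=stage, seed=int(raw.get("seed", 0)),
                   out=str(raw.get("out", "results")), params=dict(params),
                   inputs=dict(raw.get("inputs") or {}))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(config: RunConfig, out_dir: str | Path,
                     extra: dict | None = None) -> Path:
    """Write the provenance record for a completed run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "efferoquant",
        "version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "params": config.params,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in config.inputs.items() if Path(str(p)).is_file()
        },
    }
    if extra:
        record.update(extra)
    path = out / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    return path
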