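"""Configuration files, result persistence and run manifests.

Scenario configurations are YAML mappings validated against
:class:`~matesim.simulation.ScenarioConfig` (unknown keys are rejected, so a
typo never silently falls back to a default).  Results are stored in a
single ``.npz`` archive holding every sampled series as a named array plus a
JSON metadata blob; batch summaries are flat CSV tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from matesim import __version__
from matesim.simulation import ScenarioConfig, SimulationResult


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML scenario configuration; absent keys take the defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ScenarioConfig(**data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )


def config_hash(config: ScenarioConfig) -> str:
    """Stable hash of the full configuration (identifies a run setup)."""
    canon = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: config hash + seed pin down a run exactly."""

    config_hash: str
    seed: int
    version: str = __version__
    wall_time_s: float = 0.0
    event_counts: dict = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def make_manifest(result: SimulationResult, wall_time_s: float = 0.0) -> RunManifest:
    return RunManifest(
        config_hash=config_hash(result.config),
        seed=result.seed,
        wall_time_s=wall_time_s,
        event_counts={"polarity_clamps": dict(result.clamp_events)},
    )


# --------------------------------------------------------------- result I/O

def save_result(result: SimulationResult, path: str | Path) -> None:
    """Persist a result losslessly to a compressed array archive."""
    arrays: dict[str, np.ndarray] = {"times": result.times}
    for cid in result.cell_ids:
        arrays[f"pol_points__{cid}"] = result.polarisome_points[cid]
        arrays[f"pol_angles__{cid}"] = result.polarisome_angles[cid]
        arrays[f"u2_max__{cid}"] = result.u2_max[cid]
        arrays[f"u2_mean__{cid}"] = result.u2_mean[cid]
        arrays[f"perimeters__{cid}"] = result.perimeters[cid]
        arrays[f"proj_len__{cid}"] = result.projection_lengths[cid]
        arrays[f"final_curve__{cid}"] = result.final_curves[cid]
    for (a, b), d in result.distances.items():
        arrays[f"dist__{a}__{b}"] = d
    for t, snap in result.snapshots.items():
        for name, arr in snap.items():
            arrays[f"snap__{t:g}__{name}"] = arr
    meta = {
        "version": __version__,
        "success": result.success,
        "mating_time": result.mating_time,
        "partner": list(result.partner) if result.partner else None,
        "cell_ids": result.cell_ids,
        "mating_types": result.mating_types,
        "centers0": {k: list(v) for k, v in result.centers0.items()},
        "clamp_events": result.clamp_events,
        "seed": result.seed,
        "config": json.loads(result.config.model_dump_json()),
        "snapshot_times": sorted(result.snapshots),
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_result(path: str | Path) -> SimulationResult:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != __version__:
            import warnings
            warnings.warn(
                f"result written by matesim {meta['version']}, "
                f"loading with {__version__}"
            )
        cell_ids = meta["cell_ids"]
        snapshots: dict[float, dict[str, np.ndarray]] = {}
        for t in meta["snapshot_times"]:
            prefix = f"snap__{t:g}__"
            snapshots[t] = {
                k[len(prefix):]: z[k] for k in z.files if k.startswith(prefix)
            }
        distances = {}
        for k in z.files:
            if k.startswith("dist__"):
                _, a, b = k.split("__")
                distances[(a, b)] = z[k]
        return SimulationResult(
            success=meta["success"],
            mating_time=meta["mating_time"],
            partner=tuple(meta["partner"]) if meta["partner"] else None,
            times=z["times"],
            cell_ids=cell_ids,
            mating_types=meta["mating_types"],
            centers0={k: tuple(v) for k, v in meta["centers0"].items()},
            polarisome_points={c: z[f"pol_points__{c}"] for c in cell_ids},
            polarisome_angles={c: z[f"pol_angles__{c}"] for c in cell_ids},
            u2_max={c: z[f"u2_max__{c}"] for c in cell_ids},
            u2_mean={c: z[f"u2_mean__{c}"] for c in cell_ids},
            perimeters={c: z[f"perimeters__{c}"] for c in cell_ids},
            projection_lengths={c: z[f"proj_len__{c}"] for c in cell_ids},
            distances=distances,
            final_curves={c: z[f"final_curve__{c}"] for c in cell_ids},
            clamp_events=meta["clamp_events"],
            seed=meta["seed"],
            config=ScenarioConfig(**meta["config"]),
            snapshots=snapshots,
        )


# -------------------------------------------------------------- tabular I/O

def samples_to_dataframe(result: SimulationResult) -> pd.DataFrame:
    """Long-format per-sample table: one row per (time, cell)."""
    rows = []
    for cid in result.cell_ids:
        for i, t in enumerate(result.times):
            rows.append({
                "time_s": t,
                "cell_id": cid,
                "polarisome_angle": result.polarisome_angles[cid][i],
                "u2_max": result.u2_max[cid][i],
                "u2_mean": result.u2_mean[cid][i],
                "perimeter": result.perimeters[cid][i],
                "projection_length": result.projection_lengths[cid][i],
            })
    return pd.DataFrame(rows)


def batch_to_dataframe(batch: list[SimulationResult]) -> pd.DataFrame:
    """One row per replicate: outcome, partner, angles, projection lengths."""
    from matesim.assays import direction_pair

    rows = []
    for r in batch:
        dp = direction_pair(r)
        row = {
            "seed": r.seed,
            "success": r.success,
            "mating_time_s": r.mating_time,
            "partner_a": r.partner[0] if r.partner else None,
            "partner_alpha": r.partner[1] if r.partner else None,
            "theta_alpha": dp.theta_alpha if dp else np.nan,
            "theta_a": dp.theta_a if dp else np.nan,
        }
        for cid in r.cell_ids:
            row[f"proj_len_{cid}"] = r.projection_lengths[cid][-1]
        rows.append(row)
    return pd.DataFrame(rows)
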