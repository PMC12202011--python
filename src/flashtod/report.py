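"""End-to-end pipeline, run manifest, and parallel-coordinates export."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comet import (
    build_damage_table,
    filter_for_correlation,
    read_comet_csv,
    records_to_frame,
)
from .correlation import correlate, pair_ratios
from .depletion import KineticParams
from .errors import PipelineStageError, ValidationError
from .grid import Condition, TODTable, cooper_design, full_factorial, run_grid
from .oer import OERParams
from .synth import SyntheticConfig, generate

#: Axes whose plot scale is logarithmic (span several decades).
LOG_AXES = {"dose_rate_gy_s"}


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValidationError(f"config root must be a mapping, got {type(config)}")
    return config


def resolve_params(config: Mapping) -> tuple[KineticParams, OERParams]:
    kinetic = KineticParams(**dict(config.get("kinetics") or {}))
    oer_params = OERParams(**dict(config.get("oer") or {}))
    return kinetic, oer_params


def _design_from_config(config: Mapping) -> list[Condition]:
    grid_cfg = dict(config.get("grid") or {})
    design = grid_cfg.get("design", "cooper")
    if design == "cooper":
        return cooper_design()
    if design == "factorial":
        return full_factorial(
            include_zero_dose=bool(grid_cfg.get("include_zero_dose", False))
        )
    raise ValidationError(f"unknown grid design {design!r}")


@dataclass
class RunManifest:
    """Snapshot of everything that affected a pipeline run's outputs."""

    config: dict
    kinetic: dict
    oer: dict
    seed: int | None
    software_version: str = __version__
    started_at: str = ""
    finished_at: str = ""
    output_digests: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.output_digests[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _StageContext()


def run_pipeline(config: Mapping, out_dir) -> dict:
    """Grid -> depletion -> sparing ratios -> damage ratios -> correlation.

    Writes all tables, the correlation report, figures, and a manifest to
    ``out_dir``.  A rerun with an identical config (and seed) reproduces the
    tables and figures byte-for-byte; only the manifest timestamps differ.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kinetic, oer_params = resolve_params(config)
    synth_cfg = dict(config.get("synth") or {})
    seed = synth_cfg.get("seed", 0)
    manifest = RunManifest(
        config=json.loads(json.dumps(dict(config))),
        kinetic=dataclasses.asdict(kinetic),
        oer=dataclasses.asdict(oer_params),
        seed=seed,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        notes={
            "damage_ratio_definition": "(test - control) / (conv - control)",
            "control_oxygen_policy": "dataset default 0.5% O2 for all controls",
            "reference_pO2_policy": "initial tension of the environment",
        },
    )
    results: dict = {"manifest": manifest}

    with _stage("grid"):
        design = _design_from_config(config)

    with _stage("simulate"):
        tod = run_grid(design, kinetic, oer_params)
        tod_path = out / "tod_table.csv"
        tod.write_csv(tod_path)
        results["tod_table"] = tod

    comet_cfg = dict(config.get("comet") or {})
    if not comet_cfg.get("enabled", True):
        # Grid-only run (e.g. the full factorial, which has no 0 Gy controls
        # to anchor damage ratios).
        with _stage("figures"):
            fig_tod = out / "tod_parallel_coordinates.pdf"
            export_parallel_coordinates(
                tod.frame,
                axes=["oxygen_percent", "dose_gy", "dose_rate_gy_s", "tod_ratio"],
                intensity_field="tod_ratio",
                path=fig_tod,
            )
        with _stage("manifest"):
            manifest.add_output(tod_path)
            manifest.add_output(fig_tod)
            manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S%z")
            manifest.write(out / "manifest.json")
        return results

    with _stage("comet-input"):
        if comet_cfg.get("input"):
            records = read_comet_csv(comet_cfg["input"])
        else:
            synthetic = SyntheticConfig(
                **{**synth_cfg, "design": tuple(design)}
            )
            records = generate(synthetic, kinetic, oer_params)
        records_path = out / "comet_records.csv"
        records_to_frame(records).to_csv(records_path, index=False)
        results["records"] = records

    with _stage("damage-ratios"):
        ratios = build_damage_table(records)
        damage_frame = pd.DataFrame(
            {
                "dataset": [r.condition.dataset_label for r in ratios],
                "oxygen_percent": [r.condition.oxygen_percent for r in ratios],
                "dose_gy": [r.condition.dose for r in ratios],
                "dose_rate_gy_s": [r.condition.dose_rate for r in ratios],
                "role": [r.condition.role for r in ratios],
                "damage_ratio": [r.damage_ratio for r in ratios],
            }
        )
        damage_path = out / "damage_table.csv"
        damage_frame.to_csv(damage_path, index=False)
        results["damage_ratios"] = ratios

    with _stage("filter"):
        retained = filter_for_correlation(ratios)
        results["retained"] = retained

    with _stage("correlate"):
        pairs = pair_ratios(tod, retained)
        paired_path = out / "paired_table.csv"
        pairs.write_csv(paired_path)
        correlation = correlate(pairs)
        corr_path = out / "correlation.json"
        corr_path.write_text(correlation.to_json())
        corr_txt = out / "correlation.txt"
        corr_txt.write_text(
            "n: {n}\nspearman_rho: {spearman_rho:.6g}\np_spearman: {p_spearman:.6g}\n"
            "pearson_r: {pearson_r:.6g}\np_pearson: {p_pearson:.6g}\n".format(
                **correlation.to_dict()
            )
        )
        results["pairs"] = pairs
        results["correlation"] = correlation

    with _stage("figures"):
        fig_tod = out / "tod_parallel_coordinates.pdf"
        export_parallel_coordinates(
            tod.frame,
            axes=["oxygen_percent", "dose_gy", "dose_rate_gy_s", "tod_ratio"],
            intensity_field="tod_ratio",
            path=fig_tod,
        )
        fig_damage = out / "damage_parallel_coordinates.pdf"
        export_parallel_coordinates(
            damage_frame,
            axes=["oxygen_percent", "dose_gy", "dose_rate_gy_s", "damage_ratio"],
            intensity_field="damage_ratio",
            path=fig_damage,
        )

    with _stage("manifest"):
        for path in (
            tod_path,
            records_path,
            damage_path,
            paired_path,
            corr_path,
            corr_txt,
            fig_tod,
            fig_damage,
        ):
            manifest.add_output(path)
        manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        manifest.write(out / "manifest.json")

    return results


def line_intensities(ratio_values: np.ndarray) -> np.ndarray:
    """Per-line alpha, monotone increasing in (1 - ratio): darker = more sparing."""
    change = 1.0 - np.asarray(ratio_values, dtype=float)
    span = np.ptp(change)
    if span == 0:
        return np.full(change.shape, 0.6)
    return 0.15 + 0.85 * (change - change.min()) / span


def export_parallel_coordinates(
    table: pd.DataFrame,
    axes: Sequence[str],
    intensity_field: str,
    path,
) -> Path:
    """One polyline per row across normalized axes; written as vector output."""
    if len(table) == 0:
        raise ValidationError("parallel-coordinates table is empty")
    for axis in list(axes) + [intensity_field]:
        if axis not in table.columns:
            raise ValidationError(f"unknown axis {axis!r}")

    normalized = np.empty((len(table), len(axes)))
    for j, axis in enumerate(axes):
        values = table[axis].to_numpy(dtype=float)
        if axis in LOG_AXES:
            values = np.log10(np.maximum(values, 1e-12))
        span = np.ptp(values)
        normalized[:, j] = 0.5 if span == 0 else (values - values.min()) / span

    alphas = line_intensities(table[intensity_field].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1.8 * len(axes), 4.0))
    xs = np.arange(len(axes))
    for i in range(len(table)):
        ax.plot(xs, normalized[i], color="#4b0082", alpha=float(alphas[i]), lw=1.0)
    ax.set_xticks(xs)
    ax.set_xticklabels(list(axes), rotation=20, ha="right")
    ax.set_yticks([])
    for x in xs:
        ax.axvline(x, color="0.8", lw=0.6, zorder=0)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata={"CreationDate": None})
    plt.close(fig)
    return path
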