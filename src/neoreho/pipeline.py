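"""End-to-end orchestration: motion censoring -> ReHo -> group GLMs -> reports.

A single config (YAML or :class:`PipelineConfig`) drives the whole run.
Motion exclusion is applied before any group statistics; if exclusions
unbalance the sexes no automatic re-matching is performed (the seeded
sex-matching subsample used at cohort construction is exposed separately as
:func:`match_sex_ratio`). Every output is a pure function of the config and
seed; the run manifest records both.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import demographics_table
from .glm import permutation_glm
from .motion import censor_series, read_motion_trace
from .reho import reho_map
from .roi import roi_results_table, roi_voxel_tests
from .volume_io import (
    BoldSeries,
    check_grid_compatible,
    participants_frame,
    read_atlas,
    read_bold,
    read_mask,
    read_participants,
    write_map,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "match_sex_ratio"]


class PipelineError(RuntimeError):
    """A stage-labelled pipeline failure."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the YAML example in the docs."""

    participants_csv: str
    bold_paths: dict
    motion_paths: dict
    mask_path: str
    atlas_path: str
    output_dir: str
    atlas_control_labels: tuple[int, ...] = ()
    window_length: int = 1600
    fd_threshold: float = 0.5
    max_suprathreshold_fraction: float = 0.05
    head_radius: float = 50.0
    rotation_units: str = "rad"
    neighborhood: int = 26
    mode: str = "literal"
    q: float = 0.05
    n_permutations: int = 5000
    connectivity: int = 26
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory in the pipeline config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["atlas_control_labels"] = tuple(raw.get("atlas_control_labels", ()))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["atlas_control_labels"] = list(d["atlas_control_labels"])
        return d


def _stage(name: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"[{name}] {exc}")

    return wrap


def match_sex_ratio(participants, reference_group: str = "R+", seed: int | None = None):
    """Randomly subsample the larger group to the reference group's size and
    sex composition (seeded). Returns the retained participant list."""
    if seed is None:
        raise ValueError("a seed is required for reproducible subsampling")
    df = participants if isinstance(participants, pd.DataFrame) else participants_frame(list(participants))
    other = [g for g in df["group"].unique() if g != reference_group]
    if len(other) != 1:
        raise ValueError("expected exactly two groups")
    other = other[0]
    rng = np.random.default_rng(seed)
    keep = df[df["group"] == reference_group]
    target = keep["sex"].value_counts().to_dict()
    pieces = [keep]
    for sex, n_target in target.items():
        pool = df[(df["group"] == other) & (df["sex"] == sex)]
        if len(pool) < n_target:
            raise ValueError(f"not enough {sex} participants in group {other} to match")
        pieces.append(pool.iloc[np.sort(rng.choice(len(pool), size=n_target, replace=False))])
    return pd.concat(pieces).sort_index()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the complete analysis; returns the output directory.

    Outputs: per-participant motion QC and censoring decisions, exclusion
    list, per-participant ReHo z maps and the stacked 4D map, a
    demographics table of retained participants, per-ROI and whole-brain
    permutation-GLM results for both models, and a machine-readable
    manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    err = _stage("inputs")
    try:
        participants = read_participants(config.participants_csv)
        pdf = participants_frame(participants)
        missing_ids = [p.id for p in participants if p.id not in config.bold_paths or p.id not in config.motion_paths]
        if missing_ids:
            raise ValueError(f"no BOLD/motion path for participant(s): {missing_ids}")
        mask = read_mask(config.mask_path)
        atlas = read_atlas(config.atlas_path, control_labels=config.atlas_control_labels)
        check_grid_compatible(mask, atlas)
    except Exception as exc:  # noqa: BLE001
        raise err(exc) from exc

    err = _stage("motion-censoring")
    qc_rows = []
    decisions = {}
    try:
        for p in participants:
            trace = read_motion_trace(
                config.motion_paths[p.id],
                head_radius=config.head_radius,
                rotation_units=config.rotation_units,
            )
            max_count = int(round(config.max_suprathreshold_fraction * config.window_length))
            decision = censor_series(
                trace,
                window_length=config.window_length,
                fd_threshold=config.fd_threshold,
                max_count=max_count,
            )
            decisions[p.id] = decision
            qc_rows.append(
                {
                    "id": p.id,
                    "group": p.group,
                    "n_volumes": trace.n_volumes,
                    "mean_fd": float(trace.fd.mean()),
                    "max_fd": float(trace.fd.max()),
                    "window_start": decision.window_start,
                    "window_length": decision.window_length,
                    "n_suprathreshold": decision.n_suprathreshold,
                    "excluded": decision.excluded,
                }
            )
    except Exception as exc:  # noqa: BLE001
        raise err(exc) from exc
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "motion_qc.csv", index=False)
    excluded_ids = qc.loc[qc["excluded"], "id"].tolist()
    (out / "excluded_participants.txt").write_text("\n".join(excluded_ids) + ("\n" if excluded_ids else ""))
    retained = [p for p in participants if p.id not in excluded_ids]
    rdf = pdf[~pdf["id"].isin(excluded_ids)].reset_index(drop=True)
    counts = rdf["group"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise PipelineError(
            f"[motion-censoring] fewer than 2 participants per group remain after exclusion: {counts.to_dict()}"
        )

    err = _stage("reho")
    z_maps = []
    try:
        zdir = out / "reho"
        zdir.mkdir(exist_ok=True)
        for p in retained:
            bold = read_bold(config.bold_paths[p.id])
            check_grid_compatible(bold, mask)
            d = decisions[p.id]
            if bold.n_volumes < d.window_start + d.window_length:
                raise ValueError(f"participant {p.id}: BOLD shorter than the censoring window")
            cropped = BoldSeries(
                bold.data[..., d.window_start : d.window_start + d.window_length],
                voxel_size=bold.voxel_size,
                repetition_time=bold.repetition_time,
            )
            rh = reho_map(cropped, mask, neighborhood=config.neighborhood, mode=config.mode)
            write_map(rh.z, zdir / f"{p.id}_z.nii.gz", voxel_size=bold.voxel_size)
            z_maps.append(rh.z)
        z4d = np.stack(z_maps, axis=3)
        write_map(z4d, out / "z4d.nii.gz")
    except Exception as exc:  # noqa: BLE001
        raise err(exc) from exc

    err = _stage("demographics")
    try:
        table = demographics_table(rdf)
        table.to_csv(out / "demographics.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise err(exc) from exc

    err = _stage("glm")
    try:
        all_roi_rows = []
        medians_rows = []
        for model in ("main", "interaction"):
            results = roi_voxel_tests(
                z4d,
                atlas,
                rdf,
                model=model,
                q=config.q,
                n_permutations=config.n_permutations,
                seed=config.seed,
                mask=mask.data,
                connectivity=config.connectivity,
            )
            all_roi_rows.append(roi_results_table(results))
            # assemble full-volume maps from the per-ROI pieces
            for name in ("t", "p_perm", "p_fdr", "sig"):
                combined = np.full(mask.data.shape, np.nan)
                for res in results:
                    piece = getattr(res.stat, name)
                    sel = np.isfinite(piece)
                    combined[sel] = piece[sel]
                write_map(combined, out / f"roi_{model}_{name}.nii.gz")
            for res in results:
                if res.participant_medians is not None:
                    for pid, med in zip(rdf["id"], res.participant_medians):
                        medians_rows.append(
                            {
                                "model": model,
                                "roi_label": res.roi_label,
                                "roi_name": res.roi_name,
                                "id": pid,
                                "median_z": float(med),
                            }
                        )
            # whole-brain exploratory model over the full mask
            from .glm import build_design_interaction, build_design_main

            design = build_design_main(rdf) if model == "main" else build_design_interaction(rdf)
            wb = permutation_glm(
                z4d,
                mask.data & np.isfinite(z4d).all(axis=3),
                design,
                n_permutations=config.n_permutations,
                seed=[int(config.seed), 0],
                q=config.q,
                connectivity=config.connectivity,
            )
            for name in ("t", "p_perm", "p_fdr", "sig"):
                write_map(getattr(wb, name), out / f"wholebrain_{model}_{name}.nii.gz")
            wb.clusters.to_csv(out / f"wholebrain_{model}_clusters.csv", index=False)
        pd.concat(all_roi_rows, ignore_index=True).to_csv(out / "roi_results.csv", index=False)
        pd.DataFrame(
            medians_rows, columns=["model", "roi_label", "roi_name", "id", "median_z"]
        ).to_csv(out / "participant_medians.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise err(exc) from exc

    cfg = config.to_dict()
    manifest = {
        "neoreho_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "n_input_participants": len(participants),
        "excluded": excluded_ids,
        "n_retained": len(retained),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
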