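"""Pipeline orchestration and result export.

Stages run in order: read -> [normalize] -> diagrams -> vineyard ->
extract_vine -> permutation test -> loop overlay, each stage writing its
output before the next begins, with a run manifest recording the full
configuration, seed and per-stage wall-clock.  Execution is single-process
and deterministic: rerunning a manifest reproduces the results.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import MaskRegion, Series, ValidationError
from .homology import DEFAULT_R_MAX, Diagram, Feature, diagrams_over_time
from .io import apply_mask, read_series
from .normalize import compute_bounds, normalize_amplitudes
from .stats import TaskDesign, permutation_test
from .vineyard import (
    DEFAULT_D_REF,
    DEFAULT_MIN_PERSISTENCE,
    Vineyard,
    build_vineyard,
    extract_vine,
    rank_vines,
)

FORMAT_TAG = "tdavine-export-v1"


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    design_path: str | None = None
    mask_lo: tuple | None = None
    mask_hi: tuple | None = None
    normalize: bool = True
    r_max: float = DEFAULT_R_MAX
    max_dim: int = 1
    persistence_floor: float = 0.0
    d_ref: float = DEFAULT_D_REF
    d_link: float | None = None
    vine_lo: tuple | None = None        # explicit vine region; default: top-ranked
    vine_hi: tuple | None = None
    min_persistence: float = DEFAULT_MIN_PERSISTENCE
    conditions: tuple = ("encoding", "retrieval")
    q: float = 2.0
    n_perm: int = 4999
    seed: int = 0
    overlay_t: int | None = None        # time index for the loop overlay export
    point_cap: int | None = None


def diagrams_to_frame(diagrams: list[Diagram]) -> pd.DataFrame:
    rows = [
        {
            "t": f.t,
            "dim": f.dim,
            "birth": f.birth,
            "death": f.death,
            "persistence": f.persistence,
            "truncated": int(f.truncated),
            "feature_id": f.id,
        }
        for d in diagrams
        for f in d.features
    ]
    return pd.DataFrame(
        rows,
        columns=["t", "dim", "birth", "death", "persistence", "truncated", "feature_id"],
    )


def representatives_to_frame(diagrams: list[Diagram]) -> pd.DataFrame:
    rows = [
        {"feature_id": f.id, "x": p[0], "y": p[1], "z": p[2]}
        for d in diagrams
        for f in d.features
        for p in f.representative
    ]
    return pd.DataFrame(rows, columns=["feature_id", "x", "y", "z"])


def vineyard_to_dict(v: Vineyard) -> dict:
    return {
        "format": FORMAT_TAG,
        "d_ref": v.d_ref,
        "edges": [
            [e.t, e.from_feature, e.to_feature, e.spatial_distance, e.shade]
            for e in v.edges
        ],
    }


def export_loop_overlay(series: Series, feature: Feature) -> pd.DataFrame:
    """Rows (x, y, z, amplitude_at_t, on_loop) for the feature's time index.

    The flagged voxels are exactly the representative's vertex set, ready
    to superimpose a loop on an amplitude heat map.
    """
    if feature.dim == 0 or len(feature.representative) == 0:
        raise ValidationError("feature has no loop representative")
    cloud = series.clouds[feature.t]
    loop = {tuple(p) for p in feature.representative}
    on = np.array([tuple(p) in loop for p in cloud.coords], dtype=int)
    return pd.DataFrame(
        {
            "x": cloud.coords[:, 0],
            "y": cloud.coords[:, 1],
            "z": cloud.coords[:, 2],
            "amplitude": cloud.amplitudes,
            "on_loop": on,
        }
    )


def _load_design(path: str) -> TaskDesign:
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        raise ValidationError("design file needs a 'condition' column")
    if "t" in df.columns:
        df = df.sort_values("t")
    return TaskDesign.from_labels(df["condition"].astype(str).tolist())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also on disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "format": FORMAT_TAG,
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    stage_t0 = time.perf_counter()

    def finish(stage: str) -> None:
        nonlocal stage_t0
        now = time.perf_counter()
        manifest["stages"][stage] = round(now - stage_t0, 4)
        stage_t0 = now
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        series = read_series(config.input_path)
        if config.mask_lo is not None and config.mask_hi is not None:
            series = apply_mask(
                series, MaskRegion.from_bounds(config.mask_lo, config.mask_hi)
            )
        manifest["T"] = series.T
        manifest["n_voxels"] = series.n_points
        finish("read")

        if config.normalize:
            bounds = compute_bounds(series)
            series = normalize_amplitudes(series, bounds)
            (out / "normalization.json").write_text(json.dumps(bounds.to_dict()))
        finish("normalize")

        diagrams = diagrams_over_time(
            series,
            r_max=config.r_max,
            max_dim=config.max_dim,
            persistence_floor=config.persistence_floor,
            point_cap=config.point_cap,
        )
        diagrams_to_frame(diagrams).to_csv(out / "diagrams.csv", index=False)
        representatives_to_frame(diagrams).to_csv(
            out / "representatives.csv", index=False
        )
        finish("diagrams")

        vy = build_vineyard(diagrams, d_ref=config.d_ref)
        (out / "vineyard.json").write_text(json.dumps(vineyard_to_dict(vy)))
        finish("vineyard")

        if config.vine_lo is not None and config.vine_hi is not None:
            region = MaskRegion.from_bounds(config.vine_lo, config.vine_hi)
        else:
            ranked = rank_vines(vy, d_link=config.d_link)
            if not ranked:
                raise ValidationError("no vine candidates found; widen the search")
            region = ranked[0].region
        selection = extract_vine(vy, region, config.min_persistence)
        (out / "vine_selection.json").write_text(
            json.dumps(
                {
                    "format": FORMAT_TAG,
                    "region": region.box.tolist(),
                    "min_persistence": selection.min_persistence,
                    "feature_ids": [
                        [f.id for f in fs] for fs in selection.per_t_features
                    ],
                }
            )
        )
        manifest["vine_region"] = region.box.tolist()
        manifest["vine_present_at"] = selection.n_present
        finish("vine")

        result = None
        if config.design_path is not None:
            design = _load_design(config.design_path)
            result = permutation_test(
                selection.to_diagrams(),
                design,
                conditions=tuple(config.conditions),
                n_perm=config.n_perm,
                q=config.q,
                seed=config.seed,
            )
            (out / "permutation.json").write_text(json.dumps(result.to_dict()))
            manifest["p_value"] = result.p_value
        finish("vinetest")

        overlay_t = config.overlay_t
        if overlay_t is None:
            present = [t for t, fs in enumerate(selection.per_t_features) if fs]
            overlay_t = present[0] if present else None
        if overlay_t is not None and selection.per_t_features[overlay_t]:
            feat = selection.per_t_features[overlay_t][0]
            export_loop_overlay(series, feat).to_csv(
                out / f"overlay_t{overlay_t}.csv", index=False
            )
        finish("overlay")
    except Exception as exc:  # partial outputs stay on disk for inspection
        order = ["read", "normalize", "diagrams", "vineyard", "vine", "vinetest", "overlay"]
        failed = next((s for s in order if s not in manifest["stages"]), "unknown")
        manifest["error"] = f"stage {failed}: {type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    return manifest
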