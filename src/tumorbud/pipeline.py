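"""End-to-end pipeline: simulate -> detect -> sample -> patches -> consensus -> agreement.

Every stage reads its inputs from, and writes its outputs to, a run directory,
so each is independently runnable from files on disk; :func:`run_pipeline`
simply composes the stages.  All randomness derives from the single master
seed in the config (per-stage streams are spawned deterministically), so a
repeated run reproduces every tabular output byte for byte.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .agreement import compute_agreement
from .consensus import summarize_consensus, consensus_table, per_rater_counts
from .detection import detect_candidates, candidates_to_frame
from .sampling import (CandidateSet, assign_strata, extract_patch,
                       split_groups, stratify_sample)
from .stains import StainModel, quantize_tile
from .synthetic import (ObjectClass, PanelSpec, SceneSpec, SpecError,
                        generate_rating_panel, generate_tile, noisy_confusion)

log = logging.getLogger("tumorbud")

STAGES = ("simulate", "detect", "sample", "patches", "panel",
          "consensus", "agreement")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric constant of the pipeline, with the study's defaults."""

    pixel_size_um: float = 0.24
    dab_threshold: float = 0.15
    closing_radius_um: float = 0.0
    min_area_um2: float = 25.0
    max_area_um2: float = 5000.0
    stratum_boundary_um2: float = 1000.0
    n_small: int = 1900
    n_large: int = 300
    group_sizes: tuple[int, ...] = (1500, 1500)
    patch_side_um: float = 256.0
    marker_area_mm2: float = 0.03
    vote_fraction: float = 0.7
    # synthetic scene
    n_tiles: int = 2
    tile_size_px: tuple[int, int] = (1536, 1536)
    noise_sd: float = 2.0
    background_hematoxylin: float = 0.3
    objects_per_tile: tuple[tuple[str, int, float, float], ...] = (
        ("artifact", 3, 5.0, 20.0),
        ("bud", 8, 30.0, 900.0),
        ("pdc", 2, 1100.0, 4500.0),
        ("oversize", 1, 5500.0, 6500.0),
    )
    dab_concentration: tuple[float, float] = (0.5, 1.2)
    # synthetic panel
    n_raters: int = 7
    rater_error: float = 0.15
    class_prevalence: tuple[float, float, float] = (0.5, 0.1, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "dab_threshold", "patch_side_um",
                     "marker_area_mm2"):
            if getattr(self, name) < 0 or (name == "pixel_size_um"
                                           and getattr(self, name) == 0):
                raise SpecError(f"{name} must be positive")
        if not 0.5 < self.vote_fraction <= 1.0:
            raise SpecError("vote_fraction must lie in (0.5, 1]")

    # -- plain-text (INI) round trip --
    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["pipeline"] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "objects_per_tile":
                v = "; ".join(f"{n},{c},{lo},{hi}" for n, c, lo, hi in v)
            elif isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            cp["pipeline"][f.name] = str(v)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        sec = cp["pipeline"]
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in sec:
                continue
            raw = sec[f.name]
            if f.name == "objects_per_tile":
                items = []
                for part in raw.split(";"):
                    n, c, lo, hi = (p.strip() for p in part.split(","))
                    items.append((n, int(c), float(lo), float(hi)))
                kwargs[f.name] = tuple(items)
            elif f.name in ("group_sizes", "tile_size_px"):
                kwargs[f.name] = tuple(int(x) for x in raw.split(","))
            elif f.name in ("class_prevalence", "dab_concentration"):
                kwargs[f.name] = tuple(float(x) for x in raw.split(","))
            elif f.type == "int" or f.name in ("n_tiles", "n_small", "n_large",
                                               "n_raters", "seed"):
                kwargs[f.name] = int(raw)
            else:
                kwargs[f.name] = float(raw)
        return cls(**kwargs)

    def scene_spec(self, seed: int) -> SceneSpec:
        classes = tuple(
            ObjectClass(n, c, (lo, hi), self.dab_concentration)
            for n, c, lo, hi in self.objects_per_tile)
        return SceneSpec(tile_size_px=tuple(self.tile_size_px),
                         pixel_size_um=self.pixel_size_um,
                         object_classes=classes,
                         background_hematoxylin=self.background_hematoxylin,
                         noise_sd=self.noise_sd, seed=seed)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2 ** 31))
            for s, c in zip(STAGES, children)}


# --- stages (each reads/writes the run directory) --------------------------

def stage_simulate(config: PipelineConfig, outdir: Path, seed: int,
                   stain: StainModel) -> list[str]:
    tile_ids = []
    for i in range(config.n_tiles):
        tid = f"tile{i:03d}"
        spec = config.scene_spec(seed + i)
        tile, gt = generate_tile(spec, stain)
        tio.write_tile(outdir / f"{tid}.png", quantize_tile(tile))
        tio.write_label_mask(outdir / f"{tid}_labels.tiff", gt.label_mask)
        gt.table.to_csv(outdir / f"{tid}_truth.csv", index=False)
        tile_ids.append(tid)
    return tile_ids


def stage_detect(config: PipelineConfig, outdir: Path, stain: StainModel,
                 tile_ids: list[str]) -> Path:
    frames = []
    for tid in tile_ids:
        tile = tio.read_tile(outdir / f"{tid}.png")
        objs = detect_candidates(
            tile, stain, pixel_size_um=config.pixel_size_um,
            dab_threshold=config.dab_threshold,
            closing_radius_um=config.closing_radius_um,
            min_area_um2=config.min_area_um2,
            max_area_um2=config.max_area_um2, tile_id=tid)
        df = candidates_to_frame(objs)
        df["object_id"] = [f"{tid}-{i:05d}" for i in df["object_id"]]
        frames.append(df)
    cand = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    path = outdir / "candidates.csv"
    tio.write_candidates(path, cand.drop(columns=["stratum"]))
    return path


def stage_sample(config: PipelineConfig, outdir: Path, seed: int) -> Path:
    pool = tio.read_candidates(outdir / "candidates.csv")
    cset = stratify_sample(pool, config.n_small, config.n_large,
                           config.stratum_boundary_um2, seed=seed)
    cset = split_groups(cset, config.group_sizes, seed=seed + 1)
    path = outdir / "sampled.csv"
    tio.write_candidates(path, cset.table)
    return path


def stage_patches(config: PipelineConfig, outdir: Path,
                  set_id: str = "set") -> Path:
    from .detection import CandidateObject

    sampled = tio.read_candidates(outdir / "sampled.csv")
    patch_dir = outdir / "patches"
    patch_dir.mkdir(exist_ok=True)
    rows = []
    for _, r in sampled.iterrows():
        tile = tio.read_tile(outdir / f"{r['tile_id']}.png")
        obj = CandidateObject(r["object_id"], r["tile_id"],
                              (r["centroid_x_um"], r["centroid_y_um"]),
                              r["area_um2"], int(r["pixel_count"]),
                              (0, 0, 0, 0))
        patch = extract_patch(tile, obj, config.pixel_size_um,
                              config.patch_side_um, config.marker_area_mm2,
                              background=255, marker_value=0)
        fname = f"{set_id}_{r['object_id']}.png"
        tio.write_tile(patch_dir / fname, patch.image)
        rows.append((r["object_id"], r.get("group", ""), r.get("stratum", ""),
                     f"patches/{fname}", r["centroid_x_um"], r["centroid_y_um"]))
    manifest = pd.DataFrame(rows, columns=["object_id", "group", "stratum",
                                           "patch_path", "com_x_um", "com_y_um"])
    path = outdir / "patches.csv"
    manifest.to_csv(path, index=False)
    return path


def stage_panel(config: PipelineConfig, outdir: Path, seed: int) -> Path:
    sampled = tio.read_candidates(outdir / "sampled.csv")
    spec = PanelSpec(n_objects=len(sampled), n_raters=config.n_raters,
                     class_prevalence=config.class_prevalence,
                     rater_confusions=noisy_confusion(config.rater_error),
                     seed=seed)
    panel, truth = generate_rating_panel(
        spec, object_ids=list(sampled["object_id"]))
    tio.write_panel(outdir / "panel.csv", panel)
    tio.write_labels(outdir / "panel_truth.csv", truth)
    return outdir / "panel.csv"


def stage_consensus(config: PipelineConfig, outdir: Path) -> Path:
    panel_path = outdir / "panel.csv"
    if not panel_path.exists():
        raise FileNotFoundError(f"rating file {panel_path} not found")
    panel = tio.read_panel(panel_path)
    table = consensus_table(panel, config.vote_fraction)
    table.to_csv(outdir / "consensus_objects.csv")
    summary = summarize_consensus(panel, config.vote_fraction)
    summary.to_frame().to_csv(outdir / "consensus_summary.csv", index=False)
    (outdir / "consensus_summary.txt").write_text(str(summary) + "\n")
    per_rater, _ = per_rater_counts(panel)
    per_rater.to_csv(outdir / "per_rater_counts.csv")
    return outdir / "consensus_summary.csv"


def stage_agreement(config: PipelineConfig, outdir: Path) -> Path:
    panel_path = outdir / "panel.csv"
    if not panel_path.exists():
        raise FileNotFoundError(f"rating file {panel_path} not found")
    panel = tio.read_panel(panel_path)
    groups = None
    sampled_path = outdir / "sampled.csv"
    if sampled_path.exists():
        sampled = tio.read_candidates(sampled_path)
        if "group" in sampled.columns:
            groups = sampled.set_index("object_id")["group"]
            groups.index = groups.index.astype(str)
            gp = groups.reindex([str(i) for i in panel.ratings.index])
            groups = pd.Series(gp.to_numpy(), index=panel.ratings.index)
    report = compute_agreement(panel, groups)
    report.to_frame().to_csv(outdir / "agreement.csv", index=False)
    report.cohen_matrix.to_csv(outdir / "cohen_matrix.csv")
    return outdir / "agreement.csv"


def run_pipeline(config: PipelineConfig, outdir,
                 ratings_path=None) -> dict[str, str]:
    """Run every stage into ``outdir``; returns stage -> artifact path.

    ``ratings_path`` substitutes a real observer panel CSV for the simulated
    one.  On stage failure, partial outputs are retained next to a
    ``FAILED_<stage>`` marker and a :class:`PipelineError` naming the stage is
    raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stain = StainModel.hdab()
    artifacts: dict[str, str] = {}
    manifest = outdir / "manifest.jsonl"
    config.to_file(outdir / "config.ini")

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (outdir / f"FAILED_{name}").write_text(str(exc) + "\n")
            raise PipelineError(name, str(exc)) from exc
        log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        with open(manifest, "a") as fh:
            fh.write(json.dumps({"stage": name, "seed": seeds[name],
                                 "artifact": str(result)}) + "\n")
        artifacts[name] = str(result)
        return result

    manifest.unlink(missing_ok=True)
    with open(manifest, "a") as fh:
        import tumorbud
        fh.write(json.dumps({"config": str(outdir / "config.ini"),
                             "master_seed": config.seed,
                             "version": tumorbud.__version__}) + "\n")
    tile_ids = run_stage("simulate",
                         lambda: stage_simulate(config, outdir,
                                                seeds["simulate"], stain))
    run_stage("detect", lambda: stage_detect(config, outdir, stain, tile_ids))
    run_stage("sample", lambda: stage_sample(config, outdir, seeds["sample"]))
    run_stage("patches", lambda: stage_patches(config, outdir))
    if ratings_path is not None:
        def copy_panel():
            panel = tio.read_panel(ratings_path)
            tio.write_panel(outdir / "panel.csv", panel)
            return outdir / "panel.csv"
        run_stage("panel", copy_panel)
    else:
        run_stage("panel", lambda: stage_panel(config, outdir, seeds["panel"]))
    run_stage("consensus", lambda: stage_consensus(config, outdir))
    run_stage("agreement", lambda: stage_agreement(config, outdir))
    return artifacts
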