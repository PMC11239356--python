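"""End-to-end pipeline orchestration with manifests and fixtures.

Runs simulate -> label -> encode -> train -> call -> evaluate on
synthetic sections, writing each stage's artifacts plus a run manifest
(config hash, per-stage output checksums, seeds).  A single global seed
fans out to per-stage seeds through ``numpy.random.SeedSequence`` so
stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calling, encoding, labeling
from .config import PipelineConfig
from .gan import Pix2PixTranslator
from .simulate import generate_section, truth_mask, write_section

STAGES = ("simulate", "label", "encode", "train", "call", "evaluate")


@dataclass
class RunConfig:
    """Scale parameters of a pipeline run (on top of PipelineConfig)."""

    n_sections: int = 8
    canvas: tuple = (256, 256)
    n_cells: int = 100
    frac_cd3: float = 0.4
    patch_size: int = 64
    gen_filters: int = 8
    disc_filters: int = 8
    schedule: tuple = ((2, 100.0),)
    batch_size: int = 16
    blur_kernel: int = 25
    blur_sigma: float = 3.0
    seed: int = 0


SMOKE = RunConfig()


def _stage_seeds(seed: int) -> dict[str, int]:
    states = np.random.SeedSequence(seed).generate_state(len(STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(STAGES, states)}


def _checksum_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(
    outdir: str | Path,
    run_cfg: RunConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
) -> dict:
    """Execute all stages and return the run manifest (also written as JSON)."""
    run_cfg = run_cfg or SMOKE
    pipe_cfg = pipe_cfg or PipelineConfig(
        patch_size=run_cfg.patch_size,
        blur_kernel=run_cfg.blur_kernel,
        blur_sigma=run_cfg.blur_sigma,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(run_cfg.seed)
    log_path = outdir / "log.jsonl"
    log_path.write_text("")

    def _log(stage: str, info: dict) -> None:
        with log_path.open("a") as fh:
            fh.write(json.dumps({"stage": stage, "t": time.time(), **info}) + "\n")

    manifest = {
        "version": __version__,
        "config_hash": pipe_cfg.hash(),
        "run_config": {**dataclasses.asdict(run_cfg), "canvas": list(run_cfg.canvas)},
        "seeds": seeds,
        "stages": {},
        "started": time.time(),
    }

    # simulate
    sec_dir = outdir / "sections"
    sections = []
    for i in range(run_cfg.n_sections):
        sec = generate_section(
            run_cfg.n_cells, run_cfg.frac_cd3, tuple(run_cfg.canvas), seed=seeds["simulate"] + i
        )
        write_section(sec, sec_dir / f"section_{i:03d}")
        sections.append(sec)
    manifest["stages"]["simulate"] = {
        "out": str(sec_dir),
        "checksum": _checksum_dir(sec_dir),
        "n_sections": len(sections),
    }
    _log("simulate", manifest["stages"]["simulate"])

    # label
    label_dir = outdir / "labels"
    label_dir.mkdir(exist_ok=True)
    nuclei_list, label_list = [], []
    for i, sec in enumerate(sections):
        nuclei = truth_mask(sec)
        labels = labeling.derive_labels_mihc(
            sec.cd3, nuclei, pipe_cfg.mihc_threshold, pipe_cfg.dilation_size
        )
        labels.to_csv(label_dir / f"labels_{i:03d}.csv", index=False)
        nuclei_list.append(nuclei)
        label_list.append(labels)
    manifest["stages"]["label"] = {"out": str(label_dir), "checksum": _checksum_dir(label_dir)}
    _log("label", manifest["stages"]["label"])

    # encode
    tile_dir = outdir / "tiles"
    tile_dir.mkdir(exist_ok=True)
    X, Y, manifests, tile_meta = [], [], [], []
    for i, sec in enumerate(sections):
        ts = encoding.encode_and_tile(sec.he_rgb, label_list[i], nuclei_list[i], pipe_cfg, f"s{i}")
        kept = ts.kept()
        x = ts.tiles[kept].copy()
        x[..., 0] = 0.0
        X.append(x)
        Y.append(ts.tiles[kept])
        manifests.append(ts.manifest())
        for k in kept:
            tile_meta.append((i, int(k)))
    X = np.concatenate(X) if X else np.empty((0, pipe_cfg.patch_size, pipe_cfg.patch_size, 3))
    Y = np.concatenate(Y) if Y else X
    pd.concat(manifests, ignore_index=True).to_csv(tile_dir / "manifest.csv", index=False)
    np.savez_compressed(tile_dir / "tiles.npz", X=X, Y=Y)
    manifest["stages"]["encode"] = {
        "out": str(tile_dir),
        "checksum": _checksum_dir(tile_dir),
        "n_kept_tiles": len(X),
    }
    _log("encode", manifest["stages"]["encode"])

    # train
    train_dir = outdir / "model"
    train_dir.mkdir(exist_ok=True)
    if len(X) == 0:
        raise RuntimeError("no tiles survived flagging; enlarge the run")
    tr_idx, te_idx = encoding.split_tiles(len(X), pipe_cfg.train_frac, seeds["train"])
    model = Pix2PixTranslator(
        patch_size=run_cfg.patch_size,
        gen_filters=run_cfg.gen_filters,
        disc_filters=run_cfg.disc_filters,
        schedule=run_cfg.schedule,
        batch_size=run_cfg.batch_size,
        random_state=seeds["train"],
    ).fit(X[tr_idx], Y[tr_idx])
    hist = pd.DataFrame([dataclasses.asdict(h) for h in model.history_])
    hist.to_csv(train_dir / "loss_history.csv", index=False)
    (train_dir / "meta.json").write_text(
        json.dumps({"epochs": model.n_epochs_, "seed": seeds["train"], "n_train": len(tr_idx)})
    )
    manifest["stages"]["train"] = {"out": str(train_dir), "checksum": _checksum_dir(train_dir)}
    _log("train", manifest["stages"]["train"])

    # call
    call_dir = outdir / "calls"
    call_dir.mkdir(exist_ok=True)
    eval_idx = te_idx if len(te_idx) else tr_idx
    pred = model.predict(X[eval_idx])
    rows = []
    for p, gi in zip(pred, eval_idx):
        si, k = tile_meta[gi]
        nuc_tiles, _ = encoding.pad_and_tile(nuclei_list[si], pipe_cfg.patch_size)
        res = calling.call_nuclei(calling.extract_pred_mask(p, pipe_cfg.pred_threshold), nuc_tiles[k])
        truth = label_list[si][label_list[si]["id"].isin(res.calls["id"])]
        acc = calling.tile_accuracy(res, truth) if len(res.calls) else None
        rows.append({"section": si, "tile": k, "n_pos": res.n_pos, "n_neg": res.n_neg, "accuracy": acc})
    calls_df = pd.DataFrame(rows)
    calls_df.to_csv(call_dir / "summary.csv", index=False)
    manifest["stages"]["call"] = {"out": str(call_dir), "checksum": _checksum_dir(call_dir)}
    _log("call", manifest["stages"]["call"])

    # evaluate
    eval_dir = outdir / "eval"
    eval_dir.mkdir(exist_ok=True)
    accs = calls_df["accuracy"].dropna()
    summary = {
        "mean_accuracy": float(accs.mean()) if len(accs) else None,
        "n_eval_tiles": int(len(calls_df)),
    }
    (eval_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest["stages"]["evaluate"] = {"out": str(eval_dir), "checksum": _checksum_dir(eval_dir)}
    _log("evaluate", manifest["stages"]["evaluate"])

    manifest["finished"] = time.time()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Write a small versioned fixture set (sections + labels + checksums)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for i in range(2):
        sec = generate_section(30, 0.2, (256, 256), seed=seed + i)
        d = outdir / f"section_{i}"
        write_section(sec, d)
        nuclei = truth_mask(sec)
        labeling.derive_labels_mihc(sec.cd3, nuclei).to_csv(d / "labels.csv", index=False)
        checksums[f"section_{i}"] = _checksum_dir(d)
    (outdir / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return checksums
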