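"""End-to-end pipeline with config handling and stage caching.

A run config is a nested mapping with sections ``simulate``,
``reconstruct``, ``preprocess``, ``train``, ``evaluate`` plus global
``seed``; unknown keys are rejected.  Each stage writes its outputs and a
``.stage.json`` receipt recording a hash of its effective inputs and of
every output file; a re-run skips stages whose receipts still match
(corrupting an output invalidates the receipt and re-runs the stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io
from .dataset import (
    load_examples,
    preprocess_fields,
    reconstruct_fields,
    save_manifest,
    simulate_fields,
)
from .evaluate import evaluate_run, make_unet_predictor
from .optics import OpticalConfig
from .recon import ReconSettings
from .simulate import CellPopulationSpec, FluorescenceParams
from .unet import TrainConfig, UNetConfig, build_model, load_checkpoint, save_checkpoint, train

logger = logging.getLogger("holostain")

_SECTIONS = {"simulate", "reconstruct", "preprocess", "train", "evaluate"}
_GLOBALS = {"seed", "out", "log_level"}

_DEFAULTS: Dict[str, dict] = {
    "simulate": {
        "donors": 5,
        "unseen_donors": 2,
        "ratios": [10, 50, 1000],
        "optics": {},
        "population": {},
        "fluorescence": {},
        "hologram_noise_sigma": 0.02,
    },
    "reconstruct": {
        "autofocus": None,  # None = only when the config records defocus
        "filter_radius": 0.0,
        "carrier_mode": "auto-peak",
        "focus_metric": "tenengrad_phase",
        "window": "hard_disk",
    },
    "preprocess": {
        "crop_size": 512,
        "crops_per_combo": 100,
        "mask_blur_sigma": 1.0,
        "mask_opening_radius_px": 2,
    },
    "train": {
        "base_channels": 64,
        "levels": 4,
        "in_channels": 3,
        "lr": 1e-3,
        "batch_size": 8,
        "epochs": 100,
        "patience": 10,
    },
    "evaluate": {"splits": ["test"]},
}


def resolve_config(user: Optional[dict]) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    user = dict(user or {})
    unknown = set(user) - _SECTIONS - _GLOBALS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg: dict = {"seed": int(user.get("seed", 0))}
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        overrides = dict(user.get(section) or {})
        bad = set(overrides) - set(defaults)
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        merged.update(overrides)
        cfg[section] = merged
    return cfg


# ----------------------------------------------------------------------
# Stage caching
# ----------------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    def __init__(self, out_root: Path, name: str, input_hash: str):
        self.root = out_root
        self.name = name
        self.input_hash = input_hash
        self.receipt_path = out_root / f".stage_{name}.json"

    def is_current(self) -> bool:
        if not self.receipt_path.exists():
            return False
        try:
            receipt = json.loads(self.receipt_path.read_text())
        except json.JSONDecodeError:
            return False
        if receipt.get("input_hash") != self.input_hash:
            return False
        for rel, digest in receipt.get("outputs", {}).items():
            p = self.root / rel
            if not p.exists() or _hash_file(p) != digest:
                return False
        return True

    def record(self, outputs: List[Path]) -> None:
        receipt = {
            "input_hash": self.input_hash,
            "outputs": {
                str(p.relative_to(self.root)): _hash_file(p) for p in outputs
            },
        }
        self.receipt_path.write_text(json.dumps(receipt, indent=1))


def _tree_files(root: Path, subdirs: List[str]) -> List[Path]:
    out: List[Path] = []
    for sub in subdirs:
        d = root / sub
        if d.is_file():
            out.append(d)
        elif d.is_dir():
            out.extend(p for p in sorted(d.rglob("*")) if p.is_file())
    return out


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

def run_pipeline(config: Optional[dict], out_dir: str | Path, seed: Optional[int] = None) -> dict:
    """Execute simulate -> reconstruct -> preprocess -> train -> evaluate,
    skipping stages whose inputs and outputs are unchanged.  Returns the
    evaluation report(s) as a dict keyed by split."""
    cfg = resolve_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(out / "resolved_config.json", cfg)

    timings: Dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: running", name)
                return self_

            def __exit__(self_, *exc):
                timings[name] = time.perf_counter() - self_.t0
                logger.info("stage %s: %.1fs", name, timings[name])

        return _T()

    optics = OpticalConfig.from_dict({**OpticalConfig().to_dict(), **cfg["simulate"]["optics"]})
    population = CellPopulationSpec(
        **{**CellPopulationSpec().to_dict(), **cfg["simulate"]["population"]}
    )
    fluo = FluorescenceParams(**cfg["simulate"]["fluorescence"])

    # -- simulate -------------------------------------------------------
    sim_hash = _hash_obj({"seed": cfg["seed"], "simulate": cfg["simulate"]})
    stage = _Stage(out, "simulate", sim_hash)
    if stage.is_current():
        logger.info("stage simulate: cached, skipping")
        manifest, _ = _load_stage_manifest(out, "manifest_simulate.json")
    else:
        with timed("simulate"):
            manifest = simulate_fields(
                out,
                optics,
                population,
                donors=cfg["simulate"]["donors"],
                unseen_donors=cfg["simulate"]["unseen_donors"],
                ratios=cfg["simulate"]["ratios"],
                seed=cfg["seed"],
                fluo_params=fluo,
                hologram_noise_sigma=cfg["simulate"]["hologram_noise_sigma"],
            )
            io.write_json(out / "manifest_simulate.json", manifest)
            stage.record(_tree_files(out, ["fields", "manifest_simulate.json"]))

    # -- reconstruct ----------------------------------------------------
    rec_hash = _hash_obj({"up": sim_hash, "reconstruct": cfg["reconstruct"]})
    stage = _Stage(out, "reconstruct", rec_hash)
    if stage.is_current():
        logger.info("stage reconstruct: cached, skipping")
        manifest, _ = _load_stage_manifest(out, "manifest_reconstruct.json")
    else:
        with timed("reconstruct"):
            rc = cfg["reconstruct"]
            settings = ReconSettings(
                filter_radius=rc["filter_radius"],
                carrier_mode=rc["carrier_mode"],
                focus_metric=rc["focus_metric"],
                window=rc["window"],
            )
            manifest = reconstruct_fields(
                manifest, out, settings=settings, run_autofocus=rc["autofocus"]
            )
            io.write_json(out / "manifest_reconstruct.json", manifest)
            stage.record(_tree_files(out, ["fields", "manifest_reconstruct.json"]))

    # -- preprocess -----------------------------------------------------
    pre_hash = _hash_obj({"up": rec_hash, "preprocess": cfg["preprocess"]})
    stage = _Stage(out, "preprocess", pre_hash)
    if stage.is_current():
        logger.info("stage preprocess: cached, skipping")
        manifest, _ = _load_stage_manifest(out, "manifest.json")
    else:
        with timed("preprocess"):
            pp = cfg["preprocess"]
            manifest = preprocess_fields(
                manifest,
                out,
                crop_size=pp["crop_size"],
                crops_per_combo=pp["crops_per_combo"],
                mask_blur_sigma=pp["mask_blur_sigma"],
                mask_opening_radius_px=pp["mask_opening_radius_px"],
            )
            save_manifest(manifest, out)
            stage.record(_tree_files(out, ["examples", "manifest.json"]))

    # -- train ----------------------------------------------------------
    tr_hash = _hash_obj({"up": pre_hash, "train": cfg["train"]})
    stage = _Stage(out, "train", tr_hash)
    ckpt = out / "model.npz"
    if stage.is_current():
        logger.info("stage train: cached, skipping")
        model = load_checkpoint(ckpt)
    else:
        with timed("train"):
            tr = cfg["train"]
            ucfg = UNetConfig(
                levels=tr["levels"],
                base_channels=tr["base_channels"],
                input_side=cfg["preprocess"]["crop_size"],
                in_channels=tr["in_channels"],
                seed=cfg["seed"],
            )
            tcfg = TrainConfig(
                lr=tr["lr"],
                batch_size=tr["batch_size"],
                epochs=tr["epochs"],
                patience=tr["patience"],
                seed=cfg["seed"],
            )
            train_set = load_examples(manifest, out, "train")
            val_set = load_examples(manifest, out, "val")
            if tr["in_channels"] == 1:  # phase-only ablation
                for e in train_set + val_set:
                    e.input = e.input[2:3]
            model = build_model(ucfg)
            model, history = train(model, train_set, val_set, tcfg)
            save_checkpoint(model, ckpt, history=history, extra_meta={"seed": cfg["seed"]})
            _write_history_csv(out / "training_log.csv", history)
            stage.record([ckpt, ckpt.with_suffix(".json"), out / "training_log.csv"])

    # -- evaluate -------------------------------------------------------
    ev_hash = _hash_obj({"up": tr_hash, "evaluate": cfg["evaluate"]})
    stage = _Stage(out, "evaluate", ev_hash)
    reports: dict = {}
    eval_dirs = [out / "metrics" / s for s in cfg["evaluate"]["splits"]]
    if stage.is_current():
        logger.info("stage evaluate: cached, skipping")
        for s, d in zip(cfg["evaluate"]["splits"], eval_dirs):
            reports[s] = io.read_json(d / "metrics.json")
    else:
        with timed("evaluate"):
            predictor = make_unet_predictor(model)
            in_channels = cfg["train"]["in_channels"]
            if in_channels == 1:
                base_predictor = predictor
                predictor = lambda x, e: base_predictor(x[2:3], e)
            for s, d in zip(cfg["evaluate"]["splits"], eval_dirs):
                report = evaluate_run(predictor, manifest, out, split=s, out_dir=d)
                reports[s] = report.to_dict()
            stage.record(
                [p for d in eval_dirs for p in sorted(d.glob("*")) if p.is_file()]
            )

    io.write_json(out / "timings.json", timings)
    return reports


def _load_stage_manifest(out: Path, name: str):
    return io.read_json(out / name), out


def _write_history_csv(path: Path, history) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "epoch": np.arange(len(history.train_mae)),
            "train_mae": history.train_mae,
            "val_mae": history.val_mae,
        }
    ).to_csv(path, index=False)
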