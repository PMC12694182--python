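"""Dataset generation: the simulated acquisition campaign.

Mirrors the study design: several donors, each imaged at PBMC:tumor ratios
of 10:1, 50:1 and 1000:1, with a fixed number of crops per donor/ratio
combination (5 donors x 3 ratios x 100 crops = 1500 primary examples,
split 3:1:1, plus 2 held-out donors x 3 ratios x 100 crops = 600 unseen
examples that never touch training).

The generator is staged so each step can also run standalone:

* :func:`simulate_fields` - ground-truth fields, sample/reference holograms
  and raw fluorescence;
* :func:`reconstruct_fields` - aberration-corrected phase from the
  hologram pairs;
* :func:`preprocess_fields` - masks, input stacks, stain targets,
  co-registered crops and the split manifest.

:func:`generate_dataset` chains the three and writes ``manifest.json``.
All randomness derives from one integer seed; regenerating with the same
arguments reproduces every file bit-identically (float images are written
as 32-bit).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import io
from .optics import OpticalConfig
from .preprocess import (
    compose_target,
    crop_pairs,
    default_min_area_px,
    fluo_to_mask,
    gradient_channels,
    split_manifest,
)
from .recon import ReconSettings, reconstruct_pair
from .simulate import (
    CellPopulationSpec,
    CellRecord,
    FluorescenceParams,
    random_aberration,
    render_fluorescence,
    sample_cell_field,
    synthesize_hologram,
    synthesize_reference_hologram,
)
from .unet import TrainingExample

__all__ = [
    "generate_dataset",
    "simulate_fields",
    "reconstruct_fields",
    "preprocess_fields",
    "load_manifest",
    "save_manifest",
    "load_examples",
    "load_field_cells",
]

_SEED_CAP = 2**31


def save_manifest(manifest: dict, base_dir: str | Path) -> Path:
    path = Path(base_dir) / "manifest.json"
    io.write_json(path, manifest)
    return path


def load_manifest(path: str | Path):
    """Read a manifest; returns (manifest dict, base directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    return io.read_json(path), path.parent


def _donor_labels(donors: int, unseen_donors: int) -> List[tuple]:
    labels = [(f"donor{i:02d}", False) for i in range(donors)]
    labels += [(f"unseen{i:02d}", True) for i in range(unseen_donors)]
    return labels


def simulate_fields(
    base_dir: str | Path,
    cfg: OpticalConfig,
    spec_template: CellPopulationSpec,
    donors: int = 5,
    unseen_donors: int = 2,
    ratios: Sequence[int] = (10, 50, 1000),
    seed: int = 0,
    fluo_params: Optional[FluorescenceParams] = None,
    hologram_noise_sigma: float = 0.02,
    aberration_tilt: float = 0.5,
    aberration_quad: float = 0.3,
) -> dict:
    """Simulate one field per (donor, ratio): ground truth, sample and
    reference holograms (sharing the field's aberration map) and raw
    fluorescence.  Returns the manifest skeleton."""
    if donors < 1 or unseen_donors < 0 or not ratios:
        raise ValueError("need >= 1 donor and a non-empty ratio list")
    base_dir = Path(base_dir)
    fluo_params = fluo_params or FluorescenceParams()
    rng = np.random.default_rng(seed)

    manifest: dict = {
        "schema_version": io.SCHEMA_VERSION,
        "seed": int(seed),
        "config": {
            "optics": cfg.to_dict(),
            "population": spec_template.to_dict(),
            "fluorescence": {
                "psf_sigma": fluo_params.psf_sigma,
                "background_level": fluo_params.background_level,
                "leakage_level": fluo_params.leakage_level,
                "noise_sigma": fluo_params.noise_sigma,
            },
            "hologram_noise_sigma": hologram_noise_sigma,
            "ratios": [int(r) for r in ratios],
            "donors": int(donors),
            "unseen_donors": int(unseen_donors),
        },
        "fields": [],
        "entries": [],
    }

    for donor_id, unseen in _donor_labels(donors, unseen_donors):
        for ratio in ratios:
            field_id = f"{donor_id}_r{int(ratio)}"
            fdir = Path("fields") / field_id
            spec = replace(
                spec_template,
                ratio_pbmc_to_tumor=int(ratio),
                donor_id=donor_id,
            )
            field_seed = int(rng.integers(_SEED_CAP))
            noise_seed = int(rng.integers(_SEED_CAP))
            fluo_seed = int(rng.integers(_SEED_CAP))
            ab_seed = int(rng.integers(_SEED_CAP))
            crop_seed = int(rng.integers(_SEED_CAP))

            field = sample_cell_field(spec, cfg, seed=field_seed)
            field.field_id = field_id
            aberration = random_aberration(
                tuple(cfg.sensor_shape), ab_seed, aberration_tilt, aberration_quad
            )
            holo = synthesize_hologram(
                field, cfg, aberration, hologram_noise_sigma, seed=noise_seed
            )
            ref = synthesize_reference_hologram(
                cfg, aberration, hologram_noise_sigma, seed=noise_seed + 1
            )
            fluo = render_fluorescence(field, fluo_params, seed=fluo_seed)

            paths = {
                "hologram": str(fdir / "hologram.tif"),
                "reference": str(fdir / "reference.tif"),
                "phase_true": str(fdir / "phase_true.tif"),
                "cancer_mask": str(fdir / "cancer_mask.tif"),
                "fluorescence": str(fdir / "fluorescence.tif"),
                "cells": str(fdir / "cells.json"),
            }
            io.write_image(base_dir / paths["hologram"], holo)
            io.write_image(base_dir / paths["reference"], ref)
            io.write_image(base_dir / paths["phase_true"], field.phase)
            io.write_image(base_dir / paths["cancer_mask"], field.cancer_mask)
            io.write_image(base_dir / paths["fluorescence"], fluo.image)
            io.write_json(
                base_dir / paths["cells"],
                {
                    "field_id": field_id,
                    "donor_id": donor_id,
                    "ratio": int(ratio),
                    "cells": [c.to_dict() for c in field.cells],
                },
            )
            manifest["fields"].append(
                {
                    "field_id": field_id,
                    "donor_id": donor_id,
                    "ratio": int(ratio),
                    "unseen": bool(unseen),
                    "n_cells": len(field.cells),
                    "crop_seed": crop_seed,
                    "paths": paths,
                }
            )
    return manifest


def reconstruct_fields(
    manifest: dict,
    base_dir: str | Path,
    settings: Optional[ReconSettings] = None,
    run_autofocus: Optional[bool] = None,
) -> dict:
    """Reconstruct the aberration-corrected phase of every field from its
    hologram pair.  ``run_autofocus=None`` enables the focus search only
    when the config records a non-zero defocus."""
    base_dir = Path(base_dir)
    cfg = OpticalConfig.from_dict(manifest["config"]["optics"])
    if run_autofocus is None:
        run_autofocus = cfg.defocus_z != 0.0
    settings = settings or ReconSettings()
    for f in manifest["fields"]:
        holo = io.read_image(base_dir / f["paths"]["hologram"])
        ref = io.read_image(base_dir / f["paths"]["reference"])
        pm = reconstruct_pair(holo, ref, cfg, settings, run_autofocus=run_autofocus)
        rel = str(Path("fields") / f["field_id"] / "recon_phase.tif")
        io.write_image(base_dir / rel, pm.phase)
        f["paths"]["recon_phase"] = rel
        f["recon_z_best"] = float(pm.provenance.get("z_best", 0.0))
    return manifest


def preprocess_fields(
    manifest: dict,
    base_dir: str | Path,
    crop_size: int = 512,
    crops_per_combo: int = 100,
    split_seed: Optional[int] = None,
    mask_blur_sigma: float = 1.0,
    mask_opening_radius_px: int = 2,
) -> dict:
    """Build input stacks, masks and stain targets from the reconstructed
    phase and fluorescence, cut co-registered crops, and assign the 3:1:1
    split (unseen donors stay quarantined)."""
    if crops_per_combo < 1:
        raise ValueError("crops_per_combo must be >= 1")
    base_dir = Path(base_dir)
    cfg = OpticalConfig.from_dict(manifest["config"]["optics"])
    spec = CellPopulationSpec(**manifest["config"]["population"])
    if crop_size > min(cfg.sensor_shape):
        raise ValueError(
            f"crop_size {crop_size} exceeds field size {cfg.sensor_shape}"
        )
    min_area = default_min_area_px(cfg, spec)
    manifest["config"].update(
        {
            "crop_size": int(crop_size),
            "crops_per_combo": int(crops_per_combo),
            "mask": {
                "blur_sigma": mask_blur_sigma,
                "threshold_mode": "otsu",
                "min_area_px": int(min_area),
                "opening_radius_px": int(mask_opening_radius_px),
                "fill_holes": True,
            },
        }
    )

    entries: List[dict] = []
    for f in manifest["fields"]:
        if "recon_phase" not in f["paths"]:
            raise ValueError(f"field {f['field_id']} has no reconstruction yet")
        phase = io.read_image(base_dir / f["paths"]["recon_phase"]).astype(np.float64)
        fluo = io.read_image(base_dir / f["paths"]["fluorescence"]).astype(np.float64)
        mask = fluo_to_mask(
            fluo,
            blur_sigma=mask_blur_sigma,
            min_area_px=min_area,
            opening_radius_px=mask_opening_radius_px,
        )
        rel_mask = str(Path("fields") / f["field_id"] / "fluo_mask.tif")
        io.write_image(base_dir / rel_mask, mask)
        f["paths"]["fluo_mask"] = rel_mask

        stack = gradient_channels(phase)
        target = compose_target(phase, mask)
        crops = crop_pairs(
            stack,
            target,
            size=crop_size,
            n=crops_per_combo,
            seed=f["crop_seed"],
            extras={"fluorescence": fluo},
        )
        for k, crop in enumerate(crops):
            example_id = f"{f['field_id']}_c{k:03d}"
            edir = Path("examples")
            paths = {
                "input": str(edir / f"{example_id}_input.tif"),
                "target": str(edir / f"{example_id}_target.tif"),
                "fluorescence": str(edir / f"{example_id}_fluo.tif"),
            }
            io.write_image(base_dir / paths["input"], crop["input"])
            io.write_image(base_dir / paths["target"], crop["target"])
            io.write_image(base_dir / paths["fluorescence"], crop["fluorescence"])
            entries.append(
                {
                    "example_id": example_id,
                    "field_id": f["field_id"],
                    "donor_id": f["donor_id"],
                    "ratio": f["ratio"],
                    "crop_origin": [int(v) for v in crop["origin"]],
                    "split": "unseen" if f["unseen"] else None,
                    "paths": paths,
                }
            )

    seed = manifest["seed"] if split_seed is None else split_seed
    split_manifest(entries, seed=seed)
    ids = [e["example_id"] for e in entries]
    if len(ids) != len(set(ids)):
        raise RuntimeError("duplicate example ids generated")
    manifest["entries"] = entries
    manifest["split_sizes"] = {
        name: sum(1 for e in entries if e["split"] == name)
        for name in ("train", "val", "test", "unseen")
    }
    return manifest


def generate_dataset(
    base_dir: str | Path,
    donors: int = 5,
    unseen_donors: int = 2,
    ratios: Sequence[int] = (10, 50, 1000),
    crops_per_combo: int = 100,
    crop_size: int = 512,
    cfg: Optional[OpticalConfig] = None,
    spec_template: Optional[CellPopulationSpec] = None,
    seed: int = 0,
    fluo_params: Optional[FluorescenceParams] = None,
    hologram_noise_sigma: float = 0.02,
    recon_settings: Optional[ReconSettings] = None,
) -> dict:
    """Run the full campaign (simulate -> reconstruct -> preprocess) and
    write ``manifest.json`` under ``base_dir``."""
    cfg = cfg or OpticalConfig()
    spec_template = spec_template or CellPopulationSpec()
    manifest = simulate_fields(
        base_dir,
        cfg,
        spec_template,
        donors=donors,
        unseen_donors=unseen_donors,
        ratios=ratios,
        seed=seed,
        fluo_params=fluo_params,
        hologram_noise_sigma=hologram_noise_sigma,
    )
    reconstruct_fields(manifest, base_dir, settings=recon_settings)
    preprocess_fields(
        manifest, base_dir, crop_size=crop_size, crops_per_combo=crops_per_combo
    )
    save_manifest(manifest, base_dir)
    return manifest


# ----------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------

def load_examples(
    manifest: dict, base_dir: str | Path, split: str
) -> List[TrainingExample]:
    """Materialize the (input, target) pairs of one split."""
    base_dir = Path(base_dir)
    out = []
    for e in manifest["entries"]:
        if e["split"] != split:
            continue
        x = io.read_image(base_dir / e["paths"]["input"]).astype(np.float32)
        y = io.read_image(base_dir / e["paths"]["target"]).astype(np.float32)
        out.append(
            TrainingExample(input=x, target=y, example_id=e["example_id"], split=split)
        )
    return out


def load_field_cells(manifest: dict, base_dir: str | Path) -> dict:
    """Map field_id -> list of :class:`CellRecord` (the per-field ground
    truth used by cell-level evaluation)."""
    base_dir = Path(base_dir)
    cells = {}
    for f in manifest["fields"]:
        d = io.read_json(base_dir / f["paths"]["cells"])
        cells[f["field_id"]] = [CellRecord.from_dict(c) for c in d["cells"]]
    return cells
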