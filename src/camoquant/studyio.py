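"""Study-folder layout: write a synthetic study to disk and analyse it back.

Layout written by ``simulate`` (and read by ``catch`` / ``measure`` /
``fluor``)::

    study/
      study.yaml            # scale, standards bboxes, config echo
      spectra/*.csv         # background reflectances (wavelength_nm,value)
      images/raw/*.tif      # camera-linear trial images (float32, HxWxC)
      images/catch/*.tif    # cone-catch images (written by `catch`)
      masks/*.tif           # body / background ROI masks (uint8)
      images_manifest.csv   # one row per trial image
      fluorescence/*.tif    # red channel (float32, 0-255 scale)
      fluorescence_manifest.csv
      trajectories.csv      # experiment-2 luminance time series
      ground_truth.json

All images are plain TIFF; nothing is gamma-encoded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fluorescence import FluorescenceImage, equalize_exposure, fluorescent_area
from .images import (
    ROI,
    StandardPatch,
    TrialImage,
    acuity_blur,
    average_timepoints,
    measure_roi,
    normalize_with_standards,
    rnl_ranked_filter,
    to_cone_catch_image,
    trial_metrics,
)
from .observers import builtin_observer
from .spectra import WavelengthGrid, write_spectrum_csv
from .synth import (
    BACKGROUNDS,
    SPECIES,
    TRIAL_OBSERVERS,
    SimConfig,
    body_reflectance,
    make_background_spectra,
    observer_catches,
    render_fluorescence_image,
    render_trial_image,
    simulate_fluorescence_counts,
    simulate_trajectories,
)

__all__ = ["write_study", "catch_study", "measure_study", "count_fluorescence"]


def _imwrite(path: Path, arr: np.ndarray) -> None:
    # channels are cone classes, not display colours: store as plain planes
    tifffile.imwrite(path, arr.astype(np.float32), photometric="minisblack")


def write_study(cfg: SimConfig, outdir: str | Path) -> Path:
    """Generate and write a complete synthetic study folder."""
    out = Path(outdir)
    for sub in ("spectra", "images/raw", "masks", "fluorescence"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    grid = WavelengthGrid()
    rng = cfg.rng(salt=404)
    backgrounds = make_background_spectra(cfg, grid)
    for name, spec in backgrounds.items():
        write_spectrum_csv(spec, out / "spectra" / f"{name}.csv")
    observers = {name: builtin_observer(name) for name in TRIAL_OBSERVERS}
    bg_catches = {(bg, ob): observer_catches(s, observers[ob], grid)
                  for bg, s in backgrounds.items() for ob in observers}

    manifest, std_bboxes = [], None
    truth: dict = {"trials": {}}
    for species in SPECIES:
        for i in range(cfg.n_fish[species]):
            fish_id = f"{species}_{i:02d}"
            u = rng.normal(0.0, cfg.fish_sd_log)
            u_red = rng.normal(0.0, cfg.fish_redness_sd)
            for background in BACKGROUNDS:
                level_cell = (cfg.baseline_level[species]
                              + cfg.background_level_effect[species][background])
                redness = float(np.clip(
                    cfg.baseline_redness[species]
                    + cfg.background_redness_effect[background] + u_red, 0.0, 0.9))
                for time_min in (1, 5):
                    level = level_cell * np.exp(
                        u + rng.normal(0.0, cfg.timepoint_jitter_log))
                    refl = body_reflectance(level, redness, cfg, grid)
                    for ob_name, obs in observers.items():
                        body_q = observer_catches(refl, obs, grid)
                        img, rois, tr = render_trial_image(
                            cfg, body_q, bg_catches[(background, ob_name)], rng)
                        stem = f"{fish_id}_{background}_t{time_min}_{ob_name}"
                        _imwrite(out / "images/raw" / f"{stem}.tif", img.pixels)
                        if std_bboxes is None:
                            std_bboxes = [
                                {"bbox": list(s.bbox),
                                 "nominal_reflectance": s.nominal_reflectance}
                                for s in img.standards
                            ]
                            for label, roi in rois.items():
                                tifffile.imwrite(out / "masks" / f"{label}.tif",
                                                 roi.mask.astype(np.uint8))
                        manifest.append({
                            "fish_id": fish_id, "species": species,
                            "background": background, "time_min": time_min,
                            "observer": ob_name, "image": f"images/raw/{stem}.tif",
                        })
                        truth["trials"][stem] = {
                            "body_catches": list(tr["body_catches"]),
                            "background_catches": list(tr["background_catches"]),
                        }
    pd.DataFrame(manifest).to_csv(out / "images_manifest.csv", index=False)

    counts, fluor_truth = simulate_fluorescence_counts(cfg)
    fl_manifest = []
    fl_rng = cfg.rng(salt=505)
    for _, rec in counts.iterrows():
        img, tr = render_fluorescence_image(cfg, int(rec["true_count"]), fl_rng)
        stem = f"{rec['fish_id']}_{rec['background']}_fluor"
        _imwrite(out / "fluorescence" / f"{stem}.tif", img.red_channel)
        tifffile.imwrite(out / "fluorescence" / "body_mask.tif",
                         img.body_mask.astype(np.uint8))
        fl_manifest.append({
            "fish_id": rec["fish_id"], "species": rec["species"],
            "background": rec["background"], "image": f"fluorescence/{stem}.tif",
            "shutter_s": img.shutter_s, "true_count": int(rec["true_count"]),
        })
    pd.DataFrame(fl_manifest).to_csv(out / "fluorescence_manifest.csv", index=False)
    truth["fluorescence_cell_means"] = fluor_truth

    trajs, kin_truth = simulate_trajectories(cfg)
    pd.DataFrame([
        {"fish_id": tr.fish_id, "species": tr.species, "time_s": t, "luminance": l}
        for tr in trajs for t, l in zip(tr.times_s, tr.luminance)
    ]).to_csv(out / "trajectories.csv", index=False)
    truth["kinetics"] = kin_truth

    (out / "study.yaml").write_text(yaml.safe_dump({
        "scale_px_per_cm": cfg.scale_px_per_cm,
        "standards": std_bboxes,
        "reference_shutter_s": cfg.fluor_reference_shutter_s,
        "seed": cfg.seed,
    }))
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out


def _load_meta(studydir: Path):
    meta = yaml.safe_load((studydir / "study.yaml").read_text())
    standards = tuple(
        StandardPatch(bbox=tuple(s["bbox"]),
                      nominal_reflectance=s["nominal_reflectance"])
        for s in meta["standards"]
    )
    return meta, standards


def catch_study(studydir: str | Path, use_filters: bool = True) -> pd.DataFrame:
    """Normalize raw images and write cone-catch images (``catch`` step)."""
    studydir = Path(studydir)
    meta, standards = _load_meta(studydir)
    manifest = pd.read_csv(studydir / "images_manifest.csv")
    (studydir / "images/catch").mkdir(parents=True, exist_ok=True)
    out_paths = []
    for _, rec in manifest.iterrows():
        obs = builtin_observer(rec["observer"])
        pixels = tifffile.imread(studydir / rec["image"]).astype(float)
        img = TrialImage(pixels=pixels, channel_meaning="camera-linear",
                         scale_px_per_cm=meta["scale_px_per_cm"],
                         standards=standards)
        img = normalize_with_standards(img)
        img = to_cone_catch_image(img, obs)
        if use_filters:
            img = acuity_blur(img, obs)
            img = rnl_ranked_filter(img, obs, radius=1, n_iter=1)
        rel = rec["image"].replace("images/raw", "images/catch")
        _imwrite(studydir / rel, img.pixels)
        out_paths.append(rel)
    manifest["catch_image"] = out_paths
    manifest.to_csv(studydir / "images_manifest.csv", index=False)
    return manifest


def measure_study(studydir: str | Path) -> pd.DataFrame:
    """Measure ROIs on cone-catch images and build the tidy trial table.

    Rows with a missing time point are dropped (with a log entry) rather
    than half-averaged.
    """
    import logging

    studydir = Path(studydir)
    meta, _ = _load_meta(studydir)
    manifest = pd.read_csv(studydir / "images_manifest.csv")
    if "catch_image" not in manifest.columns:
        raise ValueError("run the catch step first (no catch_image column)")
    body_mask = tifffile.imread(studydir / "masks/body.tif").astype(bool)
    bg_mask = tifffile.imread(studydir / "masks/background.tif").astype(bool)
    rois = {"body": ROI(body_mask, "body"), "background": ROI(bg_mask, "background")}
    rows = []
    keys = ["fish_id", "species", "background", "observer"]
    for cell, group in manifest.groupby(keys):
        recs = {}
        for _, rec in group.iterrows():
            obs = builtin_observer(rec["observer"])
            pixels = tifffile.imread(studydir / rec["catch_image"]).astype(float)
            img = TrialImage(pixels=pixels, channel_meaning="cone-catch",
                             scale_px_per_cm=meta["scale_px_per_cm"])
            img.meta["observer_obj"] = obs
            body = measure_roi(img, rois["body"])
            backgr = measure_roi(img, rois["background"])
            recs[int(rec["time_min"])] = trial_metrics(body, backgr)
        if set(recs) != {1, 5}:
            logging.getLogger(__name__).warning(
                "dropping %s: time points %s incomplete", cell, sorted(recs))
            continue
        rows.append({**dict(zip(keys, cell)), **average_timepoints(recs[1], recs[5])})
    table = pd.DataFrame(rows)
    table.to_csv(studydir / "trial_table.csv", index=False)
    return table


def count_fluorescence(studydir: str | Path) -> pd.DataFrame:
    """Equalize exposure and count fluorescent pixels (``fluor`` step)."""
    studydir = Path(studydir)
    meta, _ = _load_meta(studydir)
    manifest = pd.read_csv(studydir / "fluorescence_manifest.csv")
    mask = tifffile.imread(studydir / "fluorescence/body_mask.tif").astype(bool)
    rows = []
    for _, rec in manifest.iterrows():
        red = tifffile.imread(studydir / rec["image"]).astype(float)
        img = FluorescenceImage(red_channel=red, body_mask=mask,
                                shutter_s=rec["shutter_s"])
        img = equalize_exposure([img], meta["reference_shutter_s"])[0]
        rows.append({"fish_id": rec["fish_id"], "species": rec["species"],
                     "background": rec["background"],
                     "fluorescent_area": fluorescent_area(img)})
    table = pd.DataFrame(rows)
    table.to_csv(studydir / "fluorescence_table.csv", index=False)
    return table
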