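"""End-to-end orchestration: configuration, staging, logging and provenance.

A single-process sequential executor runs the canonical stage order

    synth -> illum -> stitch -> (dearray, per-core) -> probmap -> segment
          -> quantify -> spatial

on a whole-slide (``wsi``) or tissue-microarray (``tma``) synthetic run, or on
pre-assembled inputs.  Every executed stage is recorded in a provenance
manifest — module name, package version, full parameter set, input/output
file digests, seed, timestamps and wall-clock seconds — sufficient to
re-execute the run; identical config and seeds reproduce identical output
digests for all deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import LabelMask, MosaicImage
from . import dearray as dearray_mod
from . import illumcorr, pixelclass, quant, s3seg, spatial, stitchreg, synthgen

__all__ = ["default_config", "validate_config", "run_pipeline", "report_resources"]

STAGE_ORDER = ["synth", "illum", "stitch", "dearray", "probmap", "segment", "quantify", "spatial"]


def default_config(mode: str = "wsi", seed: int = 0, output_dir: str = "mcmini_out") -> dict:
    """A complete, valid configuration for a synthetic run."""
    return {
        "mode": mode,  # wsi | tma
        "seed": seed,
        "output_dir": output_dir,
        "synth": {
            "n_cells": 80,
            "frame_size": [384, 384],
            "n_types": 3,
            "background": 10.0,  # autofluorescence-like baseline
            "grid": [2, 2],
            "overlap": 0.1,
            "jitter_sd": 2.0,
            "cycles": 2,
            "cycle_offset": [5, 5],
            "noise_sd": 2.0,
            "vignette_strength": 0.25,
            "tma": {"rows": 3, "cols": 3, "core_diameter": 60, "spacing": 100,
                    "dropout_frac": 0.0, "fragment_frac": 0.0},
        },
        "illum": {"enabled": True, "smoothing_scale": None},
        "stitch": {"enabled": True, "max_shift": 8, "register_max_shift": 12,
                   "overlap_policy": "last-write-wins"},
        "dearray": {"downsample": 2, "pad_frac": 0.25},
        "probmap": {"nucleus_diameter": 13.0},
        "segment": {"expected_diameter": 13.0, "fp_source": "probability",
                    "cyto_method": "ring", "ring_radius": 3.0, "max_distance": 8.0},
        "quantify": {"compartments": ["nucleus", "cytoplasm", "cell"], "primary": "nucleus"},
        "spatial": {"enabled": True, "method": "kmeans", "n_clusters": 3,
                    "neighborhood_mode": "knn", "radius_or_k": 10, "n_neighborhoods": 2},
    }


def validate_config(config: dict) -> dict:
    """Pre-flight validation: fill defaults, check modes and stage coherence."""
    cfg = copy.deepcopy(default_config())
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["mode"] not in ("wsi", "tma"):
        raise ValueError(f"mode must be 'wsi' or 'tma', got {cfg['mode']!r}")
    if cfg["segment"]["cyto_method"] not in ("ring", "edt", "gwdt"):
        raise ValueError("segment.cyto_method must be ring, edt or gwdt")
    if cfg["mode"] == "wsi" and not cfg["stitch"]["enabled"]:
        raise ValueError(
            "stitch is disabled but wsi mode supplies no pre-assembled mosaic: "
            "downstream stages would have no input"
        )
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Provenance:
    def __init__(self, config: dict) -> None:
        self.stages: list[dict] = []
        self.config = config
        cfg_bytes = json.dumps(config, sort_keys=True, default=str).encode()
        self.config_digest = hashlib.sha256(cfg_bytes).hexdigest()

    def record(self, name: str, params: dict, seed: int, t0: float, t1: float,
               inputs: list[Path], outputs: list[Path], data_level: int | None) -> None:
        try:
            import resource

            peak_kb = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
        except Exception:
            peak_kb = None
        self.stages.append(
            {
                "module": name,
                "version": __version__,
                "params": params,
                "seed": seed,
                "start": datetime.fromtimestamp(t0, timezone.utc).isoformat(),
                "end": datetime.fromtimestamp(t1, timezone.utc).isoformat(),
                "wall_seconds": t1 - t0,
                "peak_memory_kb": peak_kb,
                "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
                "outputs": {str(p): _digest(p) for p in outputs if p.exists()},
                "data_level": data_level,
            }
        )

    def manifest(self) -> dict:
        return {
            "pipeline": "mcmini",
            "version": __version__,
            "config_digest": self.config_digest,
            "config": self.config,
            "stages": self.stages,
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)


def _segment_one(mosaic: MosaicImage, cfg: dict, nuclear_channel: str):
    pm = pixelclass.classical_probability_maps(
        mosaic.channel(nuclear_channel),
        cfg["probmap"]["nucleus_diameter"],
        source_channel=nuclear_channel,
    )
    seeds = s3seg.detect_seeds(pm.center, cfg["segment"]["expected_diameter"])
    raw = mosaic.channel(nuclear_channel)
    nuclei = s3seg.segment_nuclei(pm, seeds, raw, cfg["segment"]["fp_source"])
    method = cfg["segment"]["cyto_method"]
    if method == "ring":
        cyto = s3seg.segment_cytoplasm_ring(nuclei, cfg["segment"]["ring_radius"])
    elif method == "edt":
        cyto = s3seg.segment_cytoplasm_edt(nuclei, raw, cfg["segment"]["max_distance"])
    else:
        cyto = s3seg.segment_cytoplasm_gwdt(
            nuclei, raw, max_distance=cfg["segment"]["max_distance"]
        )
    cell = s3seg.combine_cell_mask(nuclei, cyto)
    return pm, {"nucleus": nuclei, "cytoplasm": cyto, "cell": cell}


def _quantify_one(masks: dict[str, LabelMask], mosaic: MosaicImage, cfg: dict):
    compartments = cfg["quantify"]["compartments"]
    selected = {c: masks[c] for c in compartments if c in masks}
    return quant.quantify(selected, mosaic, primary=cfg["quantify"]["primary"])


def run_pipeline(config: dict | str | Path) -> tuple[dict, dict]:
    """Execute the configured pipeline; returns (artifacts, provenance manifest).

    ``config`` is a dict or a path to a YAML file.  Any stage error aborts
    with the stage name in the exception and a partial manifest persisted to
    ``<output_dir>/manifest.json``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    prov = _Provenance(cfg)
    rng = np.random.default_rng(cfg["seed"])
    stage_seed = {s: int(rng.integers(2**31)) for s in STAGE_ORDER}
    artifacts: dict = {}
    nuclear = "DNA"

    def _run(stage: str, fn, params: dict, inputs: list[Path], outputs: list[Path],
             data_level: int | None):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            prov.write(out / "manifest.json")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        prov.record(stage, params, stage_seed[stage], t0, time.time(), inputs, outputs, data_level)
        return result

    s = cfg["synth"]
    if cfg["mode"] == "wsi":
        def _synth():
            truth = synthgen.make_tissue_truth(
                s["n_cells"], tuple(s["frame_size"]), s["n_types"],
                background=s["background"], seed=stage_seed["synth"],
            )
            field = synthgen.make_vignette(
                synthgen._grid_geometry(
                    tuple(s["frame_size"]), tuple(s["grid"]), s["overlap"]
                )[0],
                s["vignette_strength"],
            )
            acq = synthgen.render_tiles(
                truth, *s["grid"], overlap=s["overlap"], jitter_sd=s["jitter_sd"],
                cycles=s["cycles"], cycle_offset=tuple(s["cycle_offset"]),
                illum_field=field, noise_sd=s["noise_sd"], seed=stage_seed["synth"],
            )
            synthgen.write_truth(truth, out / "truth")
            return truth, acq

        truth, acq = _run("synth", _synth, s, [], [out / "truth" / "cells_truth.csv"], 1)
        artifacts["truth"] = truth
        artifacts["acquisition"] = acq

        if cfg["illum"]["enabled"]:
            _run(
                "illum",
                lambda: illumcorr.correct_acquisition(acq, cfg["illum"]["smoothing_scale"]),
                cfg["illum"], [], [], 1,
            )

        def _stitch():
            mosaic, positions = stitchreg.stitch_acquisition(
                acq, nuclear, cfg["stitch"]["max_shift"],
                cfg["stitch"]["register_max_shift"],
                cfg["stitch"]["overlap_policy"], seed=stage_seed["stitch"],
            )
            mosaic.save(out / "mosaic.tif")
            return mosaic, positions

        mosaic, positions = _run("stitch", _stitch, cfg["stitch"], [], [out / "mosaic.tif"], 2)
        artifacts["mosaic"] = mosaic
        artifacts["positions"] = positions
        units = [("", mosaic)]
    else:  # tma: render the array raster as a pre-assembled mosaic, then dearray
        def _synth():
            tma = synthgen.make_tma_truth(seed=stage_seed["synth"], **s["tma"])
            mosaic = MosaicImage(tma.raster.copy(), list(tma.markers))
            mosaic.save(out / "mosaic.tif")
            return tma, mosaic

        tma, mosaic = _run("synth", _synth, s["tma"], [], [out / "mosaic.tif"], 2)
        artifacts["tma_truth"] = tma
        artifacts["mosaic"] = mosaic

        def _dearray():
            return dearray_mod.dearray_mosaic(
                mosaic, nuclear, cfg["dearray"]["downsample"],
                cfg["dearray"]["pad_frac"], out_dir=out / "cores",
            )

        cores = _run("dearray", _dearray, cfg["dearray"],
                     [out / "mosaic.tif"], [out / "cores" / "index.csv"], 3)
        artifacts["cores"] = cores
        units = []
        for rec in cores:
            y0, y1, x0, x1 = rec.bounds
            sub = MosaicImage(mosaic.data[:, y0:y1, x0:x1].copy(), list(mosaic.channel_names))
            units.append((f"core_{rec.core_id:03d}", sub))

    # segment and quantify run per unit (the whole WSI, or each TMA core) but
    # are each recorded once in the manifest
    def _segment_all():
        seg = {}
        for tag, unit_mosaic in units:
            subdir = out / tag if tag else out
            subdir.mkdir(exist_ok=True)
            pm, masks = _segment_one(unit_mosaic, cfg, nuclear)
            pm.save(subdir / "probmaps.tif")
            s3seg.export_masks(masks, unit_mosaic.channel(nuclear), subdir / "masks")
            seg[tag] = (pm, masks)
        return seg

    seg_results = _run("segment", _segment_all, {**cfg["probmap"], **cfg["segment"]},
                       [], [((out / t) if t else out) / "probmaps.tif" for t, _ in units], 3)
    for tag, (pm, masks) in seg_results.items():
        prefix = f"{tag}_" if tag else ""
        artifacts[f"{prefix}masks"] = masks
        artifacts[f"{prefix}probmaps"] = pm

    def _quantify_all():
        tables = {}
        for tag, unit_mosaic in units:
            _, masks = seg_results[tag]
            table = _quantify_one(masks, unit_mosaic, cfg)
            quant.write_feature_table(table, ((out / tag) if tag else out) / "cells.csv",
                                      allow_empty=True)
            tables[tag] = table
        return tables

    tables = _run("quantify", _quantify_all, cfg["quantify"], [],
                  [((out / t) if t else out) / "cells.csv" for t, _ in units], 4)
    for tag, table in tables.items():
        artifacts[f"{(tag + '_') if tag else ''}table"] = table

    if cfg["spatial"]["enabled"]:
        sp = cfg["spatial"]

        def _spatial():
            results = {}
            for tag, table in tables.items():
                if len(table) < max(2, sp["n_clusters"]):
                    continue
                markers = [c for c in table.columns if c.endswith("_nucleus")]
                types = spatial.cluster_expression(
                    table, markers, sp["method"],
                    {"n_clusters": sp["n_clusters"]}, seed=stage_seed["spatial"],
                )
                profiles = spatial.neighborhood_composition(
                    table, types, sp["neighborhood_mode"], sp["radius_or_k"]
                )
                try:
                    hoods = spatial.recurrent_neighborhoods(
                        profiles, sp["n_neighborhoods"], seed=stage_seed["spatial"]
                    )
                except ValueError:
                    hoods = None
                subdir = (out / tag) if tag else out
                spatial.write_annotations(table, types, hoods, subdir / "annotations.csv")
                results[tag] = (types, hoods)
            return results

        artifacts["spatial"] = _run(
            "spatial", _spatial, sp, [],
            [((out / t) if t else out) / "annotations.csv" for t in tables], 4,
        )

    prov.write(out / "manifest.json")
    artifacts["manifest_path"] = out / "manifest.json"
    return artifacts, prov.manifest()


def report_resources(manifest: dict) -> str:
    """Human-readable per-stage wall-clock / peak-memory summary."""
    lines = [f"{'stage':<12} {'wall (s)':>10} {'peak mem':>12}"]
    total = 0.0
    for st in manifest["stages"]:
        total += st["wall_seconds"]
        mem = st.get("peak_memory_kb")
        mem_s = f"{mem / 1024:.1f} MB" if mem else "n/a"
        lines.append(f"{st['module']:<12} {st['wall_seconds']:>10.2f} {mem_s:>12}")
    lines.append(f"{'total':<12} {total:>10.2f}")
    return "\n".join(lines)
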