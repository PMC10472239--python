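"""Stage orchestration: run configured stages and write a run manifest.

The manifest records inputs, per-stage seeds, package version and SHA-256
hashes of every output file, enabling bit-reproducible reruns for the
deterministic stages. A stage failure stops the run, keeps partial outputs
and marks the failure in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig

logger = logging.getLogger(__name__)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_simulate_images(params: dict, seed: int, out: Path) -> list[Path]:
    from .io import write_image
    from .synth.scenes import SceneConfig, render_scene, sample_scene
    cfg = SceneConfig(**{**params, "seed": seed})
    scene = sample_scene(cfg)
    img = render_scene(scene)
    paths = [write_image(out / "dna.tif", img[0]),
             write_image(out / "membrane.tif", img[1]),
             write_image(out / "nucleus_truth.tif", scene.nucleus_mask),
             write_image(out / "mitotic_truth.tif",
                         scene.mitotic_mask.astype(np.uint16) * 65535)]
    scene.nuclei.to_csv(out / "nuclei_truth.csv", index=False)
    scene.cells.to_csv(out / "cells_truth.csv", index=False)
    paths += [out / "nuclei_truth.csv", out / "cells_truth.csv"]
    return paths


def _stage_profile_ploidy(params: dict, seed: int, out: Path) -> list[Path]:
    from .io import read_image
    from .ploidy import PloidyProfiler
    dna = read_image(params["dna"]).astype(np.float64)
    membrane = read_image(params["membrane"]).astype(np.float64) \
        if "membrane" in params else None
    mitotic = read_image(params["mitotic_mask"]) > 0 \
        if "mitotic_mask" in params else None
    est_params = {k: v for k, v in params.items()
                  if k not in ("dna", "membrane", "mitotic_mask")}
    prof = PloidyProfiler(**est_params)
    X = dna if membrane is None else np.stack([dna, membrane])
    prof.fit(X, mitotic_mask=mitotic)
    prof.nuclei_frame().to_csv(out / "nuclei.csv", index=False)
    prof.cells_frame().to_csv(out / "cells.csv", index=False)
    with open(out / "profile.json", "w") as fh:
        json.dump(prof.profile_.to_dict(), fh, indent=2)
    return [out / "nuclei.csv", out / "cells.csv", out / "profile.json"]


def _stage_simulate_mitoses(params: dict, seed: int, out: Path) -> list[Path]:
    import pandas as pd

    from .io import write_image
    from .synth.mitoses import sample_mitotic_figures
    figs = sample_mitotic_figures(seed=seed, **params)
    rows = []
    paths = []
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for mask, truth in figs:
        p = fig_dir / f"figure_{truth.figure_id:04d}.png"
        write_image(p, mask.astype(np.uint16) * 65535)
        paths.append(p)
        rows.append({"figure_id": truth.figure_id, "phase": truth.phase,
                     "pole_count": truth.pole_count,
                     "plate_asymmetry": truth.plate_asymmetry,
                     "lagging_count": truth.lagging_count,
                     "bridge": truth.bridge, "aberrant": truth.aberrant})
    pd.DataFrame(rows).to_csv(out / "figures_truth.csv", index=False)
    return paths + [out / "figures_truth.csv"]


def _stage_score_mitoses(params: dict, seed: int, out: Path) -> list[Path]:
    import pandas as pd

    from .io import read_image
    from .mitosis import MitosisScorer
    fig_dir = Path(params["figures"])
    masks = [read_image(p) > 0 for p in sorted(fig_dir.glob("*.png"))]
    scorer = MitosisScorer().fit(masks)
    pd.DataFrame([{
        "figure_id": f.figure_id, "phase": f.phase,
        "pole_count": f.pole_count, "plate_asymmetry": f.plate_asymmetry,
        "lagging_count": f.lagging_count, "bridge": f.bridge,
        "aberrant": f.aberrant} for f in scorer.figures_]) \
        .to_csv(out / "mitoses.csv", index=False)
    with open(out / "mitosis_summary.json", "w") as fh:
        json.dump(scorer.summary_.to_dict(), fh, indent=2)
    return [out / "mitoses.csv", out / "mitosis_summary.json"]


def _stage_simulate_catalog(params: dict, seed: int, out: Path) -> list[Path]:
    from .channels import ID83_LABELS, SBS96_LABELS
    from .io import write_catalog_tsv
    from .signatures import load_id_signatures, load_sbs_signatures
    from .synth.catalogs import CatalogSimConfig, simulate_catalog
    from .synth.presets import load_preset
    preset = load_preset(params["preset"]) if "preset" in params else params
    sig = load_id_signatures() if preset.get("signature_set", "").count("id") \
        else load_sbs_signatures()
    expo = [preset["exposures"].get(n, 0.0) for n in sig.names]
    cfg = CatalogSimConfig(signatures=sig, exposures=tuple(expo),
                           n_mutations=int(preset.get("n_mutations", 3000)),
                           seed=seed)
    counts = simulate_catalog(cfg)
    labels = SBS96_LABELS if sig.n_channels == 96 else ID83_LABELS
    return [write_catalog_tsv(out / "catalog.tsv", labels, counts)]


def _stage_fit_signatures(params: dict, seed: int, out: Path) -> list[Path]:
    import pandas as pd

    from .signatures import fit_exposures, load_id_signatures, load_sbs_signatures
    from .io import read_signature_tsv
    cat = pd.read_csv(params["catalog"], sep="\t")
    counts = cat.iloc[:, 1].to_numpy()
    if "signatures" in params:
        sig = read_signature_tsv(params["signatures"])
    else:
        sig = load_sbs_signatures() if len(counts) == 96 else load_id_signatures()
    expo = fit_exposures(counts, sig,
                         min_contribution=params.get("min_contribution", 0.05))
    with open(out / "exposures.json", "w") as fh:
        json.dump({"absolute": expo.as_dict(relative=False),
                   "relative": expo.as_dict(relative=True),
                   "reconstruction_cosine": expo.reconstruction_cosine},
                  fh, indent=2)
    return [out / "exposures.json"]


_STAGES = {
    "simulate_images": _stage_simulate_images,
    "profile_ploidy": _stage_profile_ploidy,
    "simulate_mitoses": _stage_simulate_mitoses,
    "score_mitoses": _stage_score_mitoses,
    "simulate_catalog": _stage_simulate_catalog,
    "fit_signatures": _stage_fit_signatures,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return (and write) a manifest."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    # pre-flight: externally supplied input paths must exist before any
    # stage runs; paths under out_dir are produced by earlier stages and
    # are checked when their consumer stage starts
    def _check_inputs(stage):
        for key in ("dna", "membrane", "mitotic_mask", "figures", "catalog",
                    "signatures"):
            p = config.params.get(stage, {}).get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"stage {stage}: input {key}={p} "
                                        "does not exist")

    for stage in config.stages:
        for key in ("dna", "membrane", "mitotic_mask", "figures", "catalog",
                    "signatures"):
            p = config.params.get(stage, {}).get(key)
            if p is not None and not Path(p).exists() \
                    and out_root.resolve() not in Path(p).resolve().parents:
                raise FileNotFoundError(f"stage {stage}: input {key}={p} "
                                        "does not exist")

    manifest = {"version": __version__, "seed": config.seed,
                "stages": [], "status": "ok"}
    for stage in config.stages:
        _check_inputs(stage)
        seed = config.stage_seed(stage)
        out = out_root / stage
        out.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        entry = {"stage": stage, "seed": seed,
                 "params": config.params.get(stage, {})}
        try:
            paths = _STAGES[stage](dict(config.params.get(stage, {})), seed, out)
        except Exception as exc:   # mark failure, keep partial outputs
            entry["status"] = "failed"
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            manifest["status"] = "failed"
            _write_manifest(out_root, manifest)
            raise
        entry["status"] = "ok"
        entry["runtime_s"] = round(time.time() - t0, 3)
        entry["outputs"] = {str(p): _hash_file(Path(p)) for p in paths}
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", stage, entry["runtime_s"])
    _write_manifest(out_root, manifest)
    return manifest


def _write_manifest(out_root: Path, manifest: dict) -> None:
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
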