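"""File round-tripping, run configuration and the pipeline driver.

Conventions: integer mosaics and maps travel as single-channel TIFF,
float maps and Mueller/intensity stacks as float32 multi-page TIFF,
rendered overlays as PNG, tables as CSV, and every image carries a JSON
sidecar (same stem, ``.json``) with its layout/bitdepth/metadata. All
coordinates are 0-based, row-major, top-left origin; the super-pixel
phase is defined relative to pixel (0, 0).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from . import dofp, mueller, scenes, analysis
from ._seeding import substream

__all__ = ["RunConfig", "read_image", "write_image", "run_pipeline"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, data, metadata: dict | None = None) -> Path:
    """Write an image with a JSON sidecar.

    TIFF for 2-D integer/float arrays and float stacks (pages along the
    first axis), PNG for uint8 renders. Lossless for integer data;
    float data is stored as float32.
    """
    path = Path(path)
    data = np.asarray(data)
    if path.suffix.lower() == ".png":
        if data.dtype != np.uint8:
            raise ValueError("PNG output expects uint8 data")
        iio.imwrite(path, data)
    elif path.suffix.lower() in (".tif", ".tiff"):
        if data.dtype.kind == "f":
            tifffile.imwrite(path, data.astype(np.float32))
        elif data.dtype.kind in "ui":
            if data.dtype.itemsize > 2:
                raise ValueError("integer TIFFs limited to 8/16-bit")
            tifffile.imwrite(path, data)
        else:
            raise ValueError(f"unsupported dtype {data.dtype}")
    else:
        raise ValueError(f"unsupported format {path.suffix!r}")
    meta = dict(metadata or {})
    meta.setdefault("shape", list(data.shape))
    meta.setdefault("dtype", str(data.dtype))
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path, require_sidecar: bool = True):
    """Read an image written by :func:`write_image`; returns (array, metadata)."""
    path = Path(path)
    side = _sidecar_path(path)
    if require_sidecar and not side.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar: expected JSON at {side}"
        )
    if path.suffix.lower() == ".png":
        data = np.asarray(iio.imread(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported format {path.suffix!r}")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return data, meta


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    The resolved config is written next to the outputs; re-running from
    that file reproduces every deterministic stage bit for bit.
    """

    mode: str = "retardance"  # retardance | depolarization | both
    scene: str = "larynx"  # larynx | m-phantom
    out_dir: str = "spe_run"
    shape: tuple = (256, 256)
    seed: int = 0
    bitdepth: int = 8
    gamma: float = 0.5
    layout: tuple = dofp.DEFAULT_LAYOUT
    exposure_scale: float = 180.0
    shot_noise: bool = True
    read_sd: float = 1.0
    gain_spread: float = 0.05
    unit_px: int = 16
    feature_unit_px: int = 30
    feature_subset: str = "joint"
    analyze: bool = False
    mueller_stack: bool = False
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        obj = cls(**cfg)
        return obj

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["layout"] = list(self.layout)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_scene(cfg: RunConfig):
    if cfg.scene == "larynx":
        return scenes.make_larynx_scene(cfg.shape, seed=cfg.seed)
    if cfg.scene in ("m-phantom", "m_phantom"):
        return scenes.make_m_phantom(cfg.shape, seed=cfg.seed)
    raise ValueError(f"unknown scene {cfg.scene!r}")


def _reconstruct_mode(cfg, stokes, calib, mode, out, manifest):
    """Simulate one imaging mode and reconstruct its parameter map."""
    rng = substream(cfg.seed, f"sensor_{mode}")
    frame = dofp.simulate_dofp_mosaic(
        stokes, layout=cfg.layout, calibration=calib,
        exposure_scale=cfg.exposure_scale, shot_noise=cfg.shot_noise,
        read_sd=cfg.read_sd, rng=rng, bitdepth=cfg.bitdepth, mode=mode,
    )
    corrected = dofp.correct_fixed_pattern(frame, calib)
    sub = dofp.demosaic_bilinear(corrected, cfg.layout)
    if mode == "retardance":
        ps = dofp.partial_stokes_linear(sub)
        pmap = dofp.retardance_map(ps)
    else:
        ps = dofp.partial_stokes_circular(sub)
        pmap = dofp.depolarization_map(ps)
    mask = dofp.exposure_mask(ps.S0, cfg.bitdepth)
    pmap = dofp.ParameterMap(pmap.values, pmap.valid & mask, pmap.kind)
    full = 2 * (2**cfg.bitdepth - 1)
    ref = dofp.IntensityReference(
        S0_in=ps.S0,
        S0_out=dofp.gamma_correct(np.clip(ps.S0 / full, 0, 1), cfg.gamma),
        gamma=cfg.gamma,
    )
    render = dofp.render_map(pmap, ref)

    files = {
        f"mosaic_{mode}.tif": (frame.pixels, {"bitdepth": cfg.bitdepth,
                                              "layout": list(cfg.layout)}),
        f"map_{mode}.tif": (pmap.values, {"kind": pmap.kind}),
        f"valid_{mode}.tif": (pmap.valid.astype(np.uint8), {"kind": "validity"}),
        f"render_{mode}.png": (render, {"kind": "render"}),
    }
    for name, (data, meta) in files.items():
        p = write_image(out / name, data, meta)
        manifest["outputs"][name] = _sha256(p)
    return pmap, ref


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate→correct→demosaic→reconstruct→mask→render (and the
    optional Mueller and analysis stages) and write an output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": "config.yaml", "outputs": {}}

    spec, truth = _make_scene(config)
    stokes = scenes.scene_to_stokes(spec, truth)
    (out / "scene.json").write_text(json.dumps(spec.to_dict(), indent=2))
    manifest["outputs"]["scene.json"] = _sha256(out / "scene.json")

    gain_rng = substream(config.seed, "fixed_pattern")
    gain = 1.0 + config.gain_spread * (gain_rng.random(config.shape) - 0.5) * 2
    calib = dofp.CalibrationMap(gain, np.zeros(config.shape))

    modes = (
        ["retardance", "depolarization"] if config.mode == "both" else [config.mode]
    )
    pmaps = {}
    for mode in modes:
        pmaps[mode], _ = _reconstruct_mode(
            config, stokes, calib, mode, out, manifest
        )

    if config.mueller_stack:
        mimg = scenes.scene_to_mueller(spec, truth)
        instrument = mueller.build_instrument()
        stack = mueller.simulate_stack(mimg, instrument)
        p = write_image(out / "mueller_stack.tif",
                        stack.reshape(-1, *config.shape),
                        {"pages": "PSA-major (j*4+k)",
                         "psg_deg": list(mueller.DEFAULT_PSG_ANGLES_DEG)})
        manifest["outputs"]["mueller_stack.tif"] = _sha256(p)

    if config.analyze and set(modes) == {"retardance", "depolarization"}:
        rgb = (scenes.larynx_rgb(spec, truth) if config.scene == "larynx"
               else scenes.phantom_rgb(spec, truth))
        hs = analysis.hue_saturation_from_rgb(rgb)
        valid = pmaps["retardance"].valid & pmaps["depolarization"].valid
        results = {}
        groups = {}
        for cls, code in (("normal", 1), ("cancer", 2)):
            region = truth.labels == code
            groups[cls] = {
                k: analysis.grid_unit_means(
                    pmaps[k].values, region, config.unit_px, valid
                ).means
                for k in pmaps
            }
        for k in pmaps:
            test = analysis.mannwhitney_compare(
                groups["normal"][k], groups["cancer"][k]
            )
            results[f"mannwhitney_{k}"] = test
            results[f"median_contrast_{k}"] = analysis.rms_contrast_medians(
                float(np.median(groups["normal"][k])),
                float(np.median(groups["cancer"][k])),
            )
        (out / "analysis.json").write_text(json.dumps(results, indent=2))
        manifest["outputs"]["analysis.json"] = _sha256(out / "analysis.json")

    # the resolved config names machine-local paths, so it is recorded
    # beside the manifest rather than among the content-hashed outputs
    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
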