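"""Synthetic polarimetric scene generator.

Ground-truth scenes stand in for the phantoms and laryngeal tissue the
endoscope images: each pixel is a depolarizer–retarder sandwich
``M = M_Δ(a,b,c) · M_R(δ,θ)`` (diattenuation omitted — tissue
diattenuation is typically very small), illuminated by the circular
probe state and scaled by a per-pixel brightness. Two stock scenes are
provided:

* :func:`make_m_phantom` — an "M"-shaped uniform birefringent film over
  a purely depolarizing scattering background, brightness-matched so
  the glyph is near-invisible in intensity but prominent in retardance;
* :func:`make_larynx_scene` — a two-class tissue scene (normal vs
  cancer) plus blood (underexposed) and specular (saturating) artifact
  patches. Normal mucosa is strongly retarding (collagen of the lamina
  propria) and strongly depolarizing; cancer erodes both.

Class parameters are drawn per pixel from stated distributions; the
physical two-layer picture is emulated phenomenologically, not by
photon transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import substream
from .core import mueller_depolarizer, mueller_linear_retarder, apply_mueller
from .mueller import MuellerImage

__all__ = [
    "DEFAULT_ILLUMINATION",
    "SceneSpec",
    "GroundTruth",
    "make_m_phantom",
    "make_larynx_scene",
    "scene_to_stokes",
    "scene_to_mueller",
    "phantom_rgb",
    "larynx_rgb",
    "LABEL_CODES",
]

#: Measured Stokes state of the circularly polarized endoscope illumination.
DEFAULT_ILLUMINATION = np.array([1.000, -0.002, 0.028, 0.999])

LABEL_CODES = {
    "background": 0,
    "normal": 1,
    "cancer": 2,
    "blood": 3,
    "specular": 4,
    "retarder_target": 5,
}


@dataclass
class SceneSpec:
    """Serializable description of a generated scene."""

    shape: tuple
    regions: list  # list of {"label", "params"} dicts; masks live in GroundTruth
    illumination: np.ndarray
    seed: int
    name: str = "scene"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "shape": list(self.shape),
            "regions": self.regions,
            "illumination": np.asarray(self.illumination).tolist(),
            "seed": int(self.seed),
            "extras": self.extras,
        }


@dataclass
class GroundTruth:
    """Per-pixel simulator ground truth."""

    delta: np.ndarray  # linear retardance angle, radians, [0, π]
    theta: np.ndarray  # fast-axis angle, radians
    dep_a: np.ndarray  # linear depolarization factors (0°/90° channel)
    dep_b: np.ndarray  # linear depolarization factors (±45° channel)
    dep_c: np.ndarray  # circular depolarization factor; A_dep = 1 − c
    brightness: np.ndarray
    labels: np.ndarray  # integer region ids (LABEL_CODES)

    def __post_init__(self):
        if np.any(self.delta < 0) or np.any(self.delta > np.pi):
            raise ValueError("retardance angles must lie in [0, π]")
        for f in (self.dep_a, self.dep_b, self.dep_c):
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError("depolarization factors must lie in [0, 1]")


def _segment_distance(points, p0, p1):
    """Distance from an (N, 2) point cloud to segment p0–p1."""
    p0 = np.asarray(p0, dtype=float)
    v = np.asarray(p1, dtype=float) - p0
    t = np.clip(((points - p0) @ v) / (v @ v), 0.0, 1.0)
    proj = p0 + t[:, None] * v
    return np.linalg.norm(points - proj, axis=1)


def m_glyph_mask(shape, thickness_frac: float = 0.07) -> np.ndarray:
    """Boolean mask of a stroked capital "M" centred in ``shape``."""
    h, w = shape
    if min(h, w) < 32:
        raise ValueError("shape too small for the M glyph")
    ys, xs = np.indices((h, w))
    pts = np.stack([xs.ravel() / w, ys.ravel() / h], axis=1)
    segs = [
        ((0.20, 0.85), (0.20, 0.15)),
        ((0.20, 0.15), (0.50, 0.60)),
        ((0.50, 0.60), (0.80, 0.15)),
        ((0.80, 0.15), (0.80, 0.85)),
    ]
    d = np.min([_segment_distance(pts, a, b) for a, b in segs], axis=0)
    return (d <= thickness_frac).reshape(h, w)


def make_m_phantom(
    shape=(128, 128),
    delta_target: float = np.pi / 3,
    background_dep: float = 0.15,
    seed: int = 0,
    illumination=None,
):
    """Two-layer phantom: uniform retarding "M" film over a depolarizing bed.

    The film retards by ``delta_target`` (radians) with a single fast
    axis drawn from the seed; the scattering background is a pure
    depolarizer with circular factor ``background_dep`` (so its
    circular-depolarization magnitude is ``1 − background_dep``).
    Brightness is uniform, making the glyph nearly invisible in the
    intensity reference while maximal in retardance.
    """
    if not 0 < delta_target < np.pi:
        raise ValueError("delta_target must lie in (0, π)")
    rng = substream(seed, "m_phantom")
    h, w = shape
    glyph = m_glyph_mask(shape)
    delta = np.where(glyph, delta_target, 0.0)
    theta = np.full(shape, rng.uniform(0, np.pi))
    dep = np.where(glyph, 1.0, background_dep)
    truth = GroundTruth(
        delta=delta,
        theta=theta,
        dep_a=dep.copy(),
        dep_b=dep.copy(),
        dep_c=dep.copy(),
        brightness=np.ones(shape),
        labels=np.where(
            glyph, LABEL_CODES["retarder_target"], LABEL_CODES["background"]
        ),
    )
    spec = SceneSpec(
        shape=tuple(shape),
        regions=[
            {"label": "retarder_target", "params": {"delta": float(delta_target)}},
            {"label": "background", "params": {"dep": float(background_dep)}},
        ],
        illumination=(DEFAULT_ILLUMINATION.copy() if illumination is None
                      else np.asarray(illumination, dtype=float)),
        seed=seed,
        name="m_phantom",
    )
    return spec, truth


DEFAULT_LARYNX_PARAMS = {
    # per-class retardance angle (degrees) and circular depolarization factor
    "normal": {"delta_deg": (50.0, 80.0), "c": (0.1, 0.4)},
    "cancer": {"delta_deg": (0.0, 15.0), "c": (0.5, 0.8)},
    "brightness": (0.7, 1.0),
    "blood_brightness": 0.02,
    "specular_brightness": 10.0,
    "specular_dep": 0.7,  # glare is partially depolarized by surface scatter
    "n_blood": 3,
    "n_specular": 2,
    "artifact_radius_frac": (0.03, 0.07),
    "theta_smooth_px": 6.0,  # fibre fast-axis correlation length
    # linear depolarization factors follow the circular one: backscattered
    # linear states survive better than circular ones in turbid tissue.
    "linear_from_c": (0.5, 0.5),  # a = b = intercept + slope·c
    # minimum pixels per tissue class: absolute if >= 1, fraction of the
    # scene area if < 1
    "min_class_px": 0.02,
}


def _ellipse_mask(shape, center, radii):
    ys, xs = np.indices(shape)
    cy, cx = center
    ry, rx = radii
    return ((ys - cy) / ry) ** 2 + ((xs - cx) / rx) ** 2 <= 1.0


def make_larynx_scene(
    shape=(256, 256),
    seed: int = 0,
    params: dict | None = None,
    illumination=None,
):
    """Two-class laryngeal tissue scene with blood and specular artifacts.

    Normal tissue: retardance δ ~ U(50°, 80°), circular depolarization
    factor c ~ U(0.1, 0.4) (strong depolarization). Cancer: δ ~ U(0°, 15°),
    c ~ U(0.5, 0.8) — low retardance and low depolarization. Blood patches
    sit below the underexposure threshold, specular patches saturate.
    Regeneration with the same seed is bit-identical.
    """
    p = dict(DEFAULT_LARYNX_PARAMS)
    if params:
        p.update(params)
    h, w = shape
    rng = substream(seed, "larynx_scene")

    labels = np.full(shape, LABEL_CODES["normal"], dtype=int)
    cancer = _ellipse_mask(
        shape, (h * rng.uniform(0.35, 0.65), w * rng.uniform(0.25, 0.45)),
        (h * 0.28, w * 0.22),
    )
    labels[cancer] = LABEL_CODES["cancer"]

    for code, count in (
        (LABEL_CODES["blood"], p["n_blood"]),
        (LABEL_CODES["specular"], p["n_specular"]),
    ):
        for _ in range(count):
            r = rng.uniform(*p["artifact_radius_frac"]) * min(h, w)
            mask = _ellipse_mask(
                shape, (rng.uniform(0, h), rng.uniform(0, w)), (r, r)
            )
            labels[mask] = code

    min_px = p["min_class_px"]
    if min_px < 1:
        min_px = min_px * h * w
    for cls in ("normal", "cancer"):
        n = int(np.sum(labels == LABEL_CODES[cls]))
        if n < min_px:
            raise ValueError(f"class {cls!r} area {n} px below minimum {min_px:.0f}")

    delta = np.zeros(shape)
    c = np.ones(shape)
    for cls in ("normal", "cancer"):
        mask = labels == LABEL_CODES[cls]
        lo, hi = p[cls]["delta_deg"]
        delta[mask] = np.deg2rad(rng.uniform(lo, hi, size=int(mask.sum())))
        c[mask] = rng.uniform(*p[cls]["c"], size=int(mask.sum()))
    c[labels == LABEL_CODES["specular"]] = p["specular_dep"]
    # Fast axes follow the collagen fibre orientation, which is spatially
    # smooth; i.i.d. axes would let demosaic averaging cancel S1/S2.
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal(shape), p["theta_smooth_px"])
    theta = np.pi * (f - f.min()) / max(np.ptp(f), 1e-12)
    theta = np.clip(theta, 0, np.pi - 1e-9)

    icpt, slope = p["linear_from_c"]
    ab = np.clip(icpt + slope * c, 0.0, 1.0)

    brightness = rng.uniform(*p["brightness"], size=shape)
    brightness[labels == LABEL_CODES["blood"]] = p["blood_brightness"]
    brightness[labels == LABEL_CODES["specular"]] = p["specular_brightness"]

    truth = GroundTruth(
        delta=delta, theta=theta, dep_a=ab.copy(), dep_b=ab.copy(), dep_c=c,
        brightness=brightness, labels=labels,
    )
    spec = SceneSpec(
        shape=tuple(shape),
        regions=[
            {"label": cls, "params": p[cls]} for cls in ("normal", "cancer")
        ]
        + [{"label": "blood", "params": {"brightness": p["blood_brightness"]}},
           {"label": "specular", "params": {"brightness": p["specular_brightness"]}}],
        illumination=(DEFAULT_ILLUMINATION.copy() if illumination is None
                      else np.asarray(illumination, dtype=float)),
        seed=seed,
        name="larynx",
        extras={"params": {k: v for k, v in p.items() if k not in ("normal", "cancer")}},
    )
    return spec, truth


def _truth_mueller(truth: GroundTruth) -> np.ndarray:
    M_R = mueller_linear_retarder(truth.delta, truth.theta)
    M_dep = mueller_depolarizer(truth.dep_a, truth.dep_b, truth.dep_c)
    return M_dep @ M_R


def scene_to_stokes(spec: SceneSpec, truth: GroundTruth) -> np.ndarray:
    """Per-pixel emergent Stokes image ``brightness · M_Δ M_R · S_illum``."""
    M = _truth_mueller(truth)
    S = apply_mueller(M, np.asarray(spec.illumination, dtype=float))
    return truth.brightness[..., None] * S


def scene_to_mueller(spec: SceneSpec, truth: GroundTruth) -> MuellerImage:
    """Per-pixel sample Mueller image ``brightness · M_Δ M_R`` (the ex-vivo
    polarimeter path; brightness enters as transmittance m00)."""
    M = truth.brightness[..., None, None] * _truth_mueller(truth)
    return MuellerImage(M)


def phantom_rgb(spec: SceneSpec, truth: GroundTruth, noise_sd: float = 0.004):
    """Synthetic white-light colour image of the M phantom.

    The transparent film is colourless, so hue/saturation carry only
    seeded sensor noise — the colour channels show (almost) nothing
    where retardance shows the glyph.
    """
    rng = substream(spec.seed, "phantom_rgb")
    base = 0.75 * truth.brightness
    rgb = np.repeat(base[..., None], 3, axis=-1)
    rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def larynx_rgb(
    spec: SceneSpec,
    truth: GroundTruth,
    noise_sd: float = 0.02,
    mottle_sd: float = 0.05,
    mottle_px: float = 20.0,
):
    """Synthetic white-light image of the larynx scene.

    Normal mucosa is light pink; cancer slightly paler. Low-frequency
    colour mottle (vascularity, uneven illumination) of amplitude
    ``mottle_sd`` and correlation length ``mottle_px`` makes the colour
    cue overlap between classes at the grid-unit level — informative
    but inferior to the polarimetric channels, as in white-light
    endoscopy of early lesions.
    """
    from scipy.ndimage import gaussian_filter

    rng = substream(spec.seed, "larynx_rgb")
    rgb = np.zeros(truth.labels.shape + (3,))
    rgb[...] = (0.85, 0.55, 0.58)  # light pink
    pale = truth.labels == LABEL_CODES["cancer"]
    rgb[pale] = (0.82, 0.62, 0.62)
    rgb[truth.labels == LABEL_CODES["blood"]] = (0.25, 0.02, 0.02)
    rgb[truth.labels == LABEL_CODES["specular"]] = (1.0, 1.0, 1.0)
    rgb *= truth.brightness[..., None].clip(0, 1)
    if mottle_sd > 0:
        mottle = np.stack(
            [gaussian_filter(rng.standard_normal(truth.labels.shape), mottle_px)
             for _ in range(3)], axis=-1)
        sd = mottle.std() or 1.0
        rgb = rgb + mottle_sd * mottle / sd
    rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(rgb, 0.0, 1.0)
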