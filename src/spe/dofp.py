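"""Snapshot polarimetric-endoscopy path: division-of-focal-plane (DoFP)
mosaic formation and reconstruction.

A DoFP sensor carries a micro-polarizer mosaic: every 2×2 super-pixel
holds four linear polarizers. The default layout, reading order of the
super-pixel, is

    90°  45°
    135°  0°

The snapshot endoscope has two modes sharing this sensor:

* retardance mode — no analyzing waveplate; the four orientations give
  the linear Stokes components ``S0, S1, S2`` and the linear-retardance
  magnitude ``A_δ = sqrt(S1² + S2²) / S0`` (equals ``|sin δ_L|`` for a
  pure retarder under circular illumination);
* depolarization mode — a quarter waveplate at 45° in front of the
  sensor maps the circular components onto the 0°/90° sub-images, giving
  ``S0, S3`` and the circular-depolarization magnitude
  ``A_dep = 1 − |S3 / S0|``.

Pixels that are under- or overexposed on the sensor are flagged invalid
and excluded from all downstream statistics; rendering paints them green.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import mueller_linear_retarder, apply_mueller

__all__ = [
    "DEFAULT_LAYOUT",
    "MosaicFrame",
    "CalibrationMap",
    "SubImages",
    "PartialStokesImage",
    "ParameterMap",
    "IntensityReference",
    "simulate_dofp_mosaic",
    "correct_fixed_pattern",
    "estimate_calibration",
    "demosaic_bilinear",
    "partial_stokes_linear",
    "partial_stokes_circular",
    "retardance_map",
    "depolarization_map",
    "exposure_mask",
    "gamma_correct",
    "unsharp_mask",
    "render_map",
    "QWP_ANALYZER_THETA",
]

#: Super-pixel micro-polarizer orientations in degrees, row-major.
DEFAULT_LAYOUT = (90.0, 45.0, 135.0, 0.0)

#: Fast-axis angle (radians) of the analyzing quarter waveplate in
#: depolarization mode, chosen so the 0° sub-image analyses right-circular
#: light and the measured S3 = I0 − I90 is positive for right-circular input.
QWP_ANALYZER_THETA = 3 * np.pi / 4


@dataclass
class MosaicFrame:
    """Raw single-channel DoFP sensor frame."""

    pixels: np.ndarray  # H×W integer counts
    bitdepth: int = 8
    layout: tuple = DEFAULT_LAYOUT

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        h, w = self.pixels.shape
        if h % 2 or w % 2:
            raise ValueError("mosaic dimensions must be even")
        if len(self.layout) != 4:
            raise ValueError("layout must list four orientations")

    @property
    def full_scale(self) -> int:
        return 2**self.bitdepth - 1


@dataclass
class CalibrationMap:
    """Per-pixel fixed-pattern model: ``count = gain·signal + offset``."""

    gain: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("gains must be positive")
        if self.gain.shape != self.offset.shape:
            raise ValueError("gain/offset shapes differ")

    @classmethod
    def identity(cls, shape) -> "CalibrationMap":
        return cls(np.ones(shape), np.zeros(shape))


@dataclass
class SubImages:
    """Four full-resolution demosaiced analyzer images."""

    I0: np.ndarray
    I45: np.ndarray
    I90: np.ndarray
    I135: np.ndarray


@dataclass
class PartialStokesImage:
    """Per-pixel partial Stokes components for one imaging mode."""

    mode: str  # "retardance" or "depolarization"
    S0: np.ndarray
    S1: np.ndarray | None = None
    S2: np.ndarray | None = None
    S3: np.ndarray | None = None


@dataclass
class ParameterMap:
    """Scalar retardance or depolarization image in [0, 1] with validity."""

    values: np.ndarray
    valid: np.ndarray
    kind: str  # "A_delta" or "A_dep"


@dataclass
class IntensityReference:
    """Intensity-reference image before/after optional gamma correction."""

    S0_in: np.ndarray
    S0_out: np.ndarray
    gamma: float = 1.0


def _orientation_masks(shape, layout=DEFAULT_LAYOUT):
    """Boolean site mask per orientation angle (degrees) for an H×W mosaic."""
    h, w = shape
    rows, cols = np.indices((h, w))
    phase = (rows % 2) * 2 + (cols % 2)
    return {float(layout[p]): phase == p for p in range(4)}


def simulate_dofp_mosaic(
    scene,
    *,
    layout=DEFAULT_LAYOUT,
    calibration: CalibrationMap | None = None,
    exposure_scale: float = 1.0,
    shot_noise: bool = False,
    read_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    bitdepth: int = 8,
    mode: str = "retardance",
    quantize: bool = True,
) -> MosaicFrame:
    """Forward-model a DoFP exposure of a Stokes scene.

    Parameters
    ----------
    scene : ndarray, shape (H, W, 4)
        Per-pixel emergent Stokes vectors (linear intensity units).
    mode : {"retardance", "depolarization"}
        In depolarization mode a quarter waveplate at
        :data:`QWP_ANALYZER_THETA` is inserted before the mosaic.
    exposure_scale : float
        Counts per unit of ``S0`` before the ½ analyzer transmission.
    shot_noise, read_sd, rng
        Poisson shot noise on the expected signal, then Gaussian read
        noise of standard deviation ``read_sd`` counts. ``rng`` is
        required when either is active.
    quantize : bool
        Clip to ``[0, 2^bitdepth − 1]`` and round half-up to integers.
        Disable to obtain the noise-free continuous expectation.

    The noise-free expected count at a pixel with micro-polarizer angle
    α is ``gain · exposure_scale · ½(S0 + S1 cos 2α + S2 sin 2α) + offset``.
    """
    scene = np.asarray(scene, dtype=float)
    if scene.ndim != 3 or scene.shape[-1] != 4:
        raise ValueError("scene must have shape (H, W, 4)")
    h, w = scene.shape[:2]
    if h % 2 or w % 2:
        raise ValueError("mosaic dimensions must be even")
    if exposure_scale < 0:
        raise ValueError("exposure_scale must be non-negative")
    if mode == "depolarization":
        qwp = mueller_linear_retarder(np.pi / 2, QWP_ANALYZER_THETA)
        scene = apply_mueller(qwp, scene)
    elif mode != "retardance":
        raise ValueError(f"unknown mode {mode!r}")

    if calibration is None:
        calibration = CalibrationMap.identity((h, w))
    signal = np.zeros((h, w))
    for angle, mask in _orientation_masks((h, w), layout).items():
        a = np.deg2rad(angle)
        proj = 0.5 * (
            scene[..., 0]
            + scene[..., 1] * np.cos(2 * a)
            + scene[..., 2] * np.sin(2 * a)
        )
        signal[mask] = proj[mask]
    signal = np.clip(signal * exposure_scale * calibration.gain, 0, None)

    if shot_noise or read_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise is enabled")
        if shot_noise:
            signal = rng.poisson(signal).astype(float)
        if read_sd > 0:
            signal = signal + rng.normal(0.0, read_sd, size=signal.shape)
    counts = signal + calibration.offset
    if quantize:
        counts = np.floor(np.clip(counts, 0, 2**bitdepth - 1) + 0.5)
        counts = counts.astype(np.uint16 if bitdepth > 8 else np.uint8)
    return MosaicFrame(counts, bitdepth=bitdepth, layout=tuple(layout))


def correct_fixed_pattern(raw: MosaicFrame, calibration: CalibrationMap) -> np.ndarray:
    """Invert the per-pixel gain/offset model: ``(raw − offset)/gain``, floored at 0."""
    pixels = np.asarray(raw.pixels, dtype=float)
    if calibration.gain.shape != pixels.shape:
        raise ValueError("calibration shape does not match frame")
    return np.clip((pixels - calibration.offset) / calibration.gain, 0, None)


def estimate_calibration(
    flat_frames, dark_frames=None, layout=DEFAULT_LAYOUT
) -> CalibrationMap:
    """Estimate per-pixel gain/offset from flat-field (and optional dark) frames.

    Flat fields are exposures of spatially uniform, unpolarized
    illumination: every micro-polarizer orientation then shares one
    expected signal, so the gain of a pixel is its (dark-subtracted)
    mean count divided by the mean over all pixels of the same
    orientation. Offsets come from the dark frames (zero if absent).
    """
    flats = np.mean([np.asarray(f.pixels, dtype=float) for f in flat_frames], axis=0)
    if dark_frames is not None:
        offset = np.mean(
            [np.asarray(f.pixels, dtype=float) for f in dark_frames], axis=0
        )
    else:
        offset = np.zeros_like(flats)
    signal = flats - offset
    gain = np.ones_like(signal)
    for _, mask in _orientation_masks(flats.shape, layout).items():
        m = signal[mask].mean()
        gain[mask] = signal[mask] / m
    gain = np.clip(gain, 1e-6, None)
    return CalibrationMap(gain, offset)


# Normalized 3×3 bilinear kernel: same-orientation neighbours on the
# 2-strided grid fall outside it, so native sites are reproduced exactly.
_BILINEAR_KERNEL = np.array(
    [[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]]
)


def demosaic_bilinear(mosaic, layout=DEFAULT_LAYOUT) -> SubImages:
    """Bilinear demosaicing of a (corrected) DoFP mosaic into four
    full-resolution sub-images, one per analyzer orientation.

    At native sites of each orientation the corrected value is kept
    exactly; elsewhere it is the bilinear average of the same-orientation
    neighbours. Boundary pixels use edge-replicated support; quantitative
    round trips should exclude a 2-px border.
    """
    if isinstance(mosaic, MosaicFrame):
        data = np.asarray(mosaic.pixels, dtype=float)
        layout = mosaic.layout
    else:
        data = np.asarray(mosaic, dtype=float)
    h, w = data.shape
    if h % 2 or w % 2:
        raise ValueError("mosaic dimensions must be even")
    out = {}
    for angle, mask in _orientation_masks((h, w), layout).items():
        sparse = np.where(mask, data, 0.0)
        num = ndimage.convolve(sparse, _BILINEAR_KERNEL, mode="nearest")
        den = ndimage.convolve(mask.astype(float), _BILINEAR_KERNEL, mode="nearest")
        out[angle] = num / den
    try:
        return SubImages(I0=out[0.0], I45=out[45.0], I90=out[90.0], I135=out[135.0])
    except KeyError as exc:  # pragma: no cover - guarded by MosaicFrame
        raise ValueError(f"layout missing orientation {exc}") from exc


def partial_stokes_linear(sub: SubImages) -> PartialStokesImage:
    """Linear Stokes components from the four sub-images (retardance mode):
    ``S0 = (I0+I45+I90+I135)/2``, ``S1 = I0 − I90``, ``S2 = I45 − I135``."""
    S0 = (sub.I0 + sub.I45 + sub.I90 + sub.I135) / 2.0
    return PartialStokesImage(
        mode="retardance", S0=S0, S1=sub.I0 - sub.I90, S2=sub.I45 - sub.I135
    )


def partial_stokes_circular(sub: SubImages) -> PartialStokesImage:
    """Circular components from the 0°/90° sub-images acquired behind the
    45° quarter waveplate: ``S0 = I0 + I90``, ``S3 = I0 − I90``."""
    return PartialStokesImage(
        mode="depolarization", S0=sub.I0 + sub.I90, S3=sub.I0 - sub.I90
    )


def _ratio_map(num, S0, kind) -> ParameterMap:
    valid = S0 > 0
    values = np.zeros_like(S0, dtype=float)
    np.divide(num, S0, out=values, where=valid)
    return ParameterMap(np.clip(values, 0.0, 1.0), valid, kind)


def retardance_map(ps: PartialStokesImage) -> ParameterMap:
    """Linear-retardance magnitude ``A_δ = sqrt(S1² + S2²)/S0`` in [0, 1].

    Under circular illumination of a pure linear retarder this equals
    ``|sin δ_L|``. Pixels with ``S0 = 0`` are marked invalid.
    """
    if ps.mode != "retardance":
        raise ValueError("retardance_map needs retardance-mode Stokes data")
    return _ratio_map(np.hypot(ps.S1, ps.S2), ps.S0, "A_delta")


def depolarization_map(ps: PartialStokesImage) -> ParameterMap:
    """Circular-depolarization magnitude ``A_dep = 1 − |S3/S0|`` in [0, 1].

    For a purely retarding (non-depolarizing) medium under circular
    illumination this reads ``1 − |cos δ|`` — a documented slight
    over-estimation of depolarization, since the emergent light still
    carries linearly polarized components.
    """
    if ps.mode != "depolarization":
        raise ValueError("depolarization_map needs depolarization-mode Stokes data")
    pm = _ratio_map(np.abs(ps.S3), ps.S0, "A_dep")
    return ParameterMap(
        np.where(pm.valid, 1.0 - pm.values, 0.0), pm.valid, "A_dep"
    )


def exposure_mask(S0_in, bitdepth: int = 8) -> np.ndarray:
    """Validity mask from the pre-gamma intensity reference.

    A pixel is invalid when ``S0_in/2 > 0.95·(2^bitdepth − 1)``
    (overexposed) or ``S0_in/2 < 0.03·(2^bitdepth − 1)`` (underexposed).
    """
    S0_in = np.asarray(S0_in, dtype=float)
    full = 2**bitdepth - 1
    half = S0_in / 2.0
    return ~((half > 0.95 * full) | (half < 0.03 * full))


def gamma_correct(S0_in, gamma: float = 0.5) -> np.ndarray:
    """Optional display gamma on a [0, 1]-normalized intensity reference."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    S0_in = np.asarray(S0_in, dtype=float)
    return np.power(S0_in, gamma)


def unsharp_mask(image, radius: float = 2.0, amount: float = 0.8) -> np.ndarray:
    """Cosmetic sharpening of the intensity reference (off in quantitative paths)."""
    from skimage.filters import unsharp_mask as _um

    return _um(np.asarray(image, dtype=float), radius=radius, amount=amount)


def render_map(
    pmap: ParameterMap,
    reference: IntensityReference | None = None,
    cmap: str = "viridis",
) -> np.ndarray:
    """Render a parameter map to an 8-bit RGB image.

    Valid pixels are colour-mapped by value over [0, 1]; invalid pixels
    are painted pure green (0, 255, 0) so viewers cannot mistake them
    for measurements. If a reference is given, its post-gamma image is
    appended side by side as a grey panel. Pure visualization: the
    ParameterMap itself is never modified.
    """
    import matplotlib

    lut = matplotlib.colormaps[cmap]
    rgb = (lut(np.clip(pmap.values, 0, 1))[..., :3] * 255).astype(np.uint8)
    rgb[~pmap.valid] = (0, 255, 0)
    if reference is not None:
        ref = np.asarray(reference.S0_out, dtype=float)
        lo, hi = ref.min(), ref.max()
        grey = np.zeros_like(ref) if hi <= lo else (ref - lo) / (hi - lo)
        panel = (np.repeat(grey[..., None], 3, axis=-1) * 255).astype(np.uint8)
        rgb = np.concatenate([rgb, panel], axis=1)
    return rgb
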