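import numpy as np
import pytest

from spe import dofp, scenes
from spe._seeding import substream

IDEAL_CIRCULAR = np.array([1.0, 0.0, 0.0, 1.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def reconstruct_maps(stokes, *, seed=0, exposure_scale=180.0, shot_noise=False,
                     read_sd=0.0, quantize=True, bitdepth=8):
    """Run both snapshot modes end to end; returns dict of ParameterMaps
    plus the per-mode partial Stokes images."""
    out = {}
    for mode in ("retardance", "depolarization"):
        gen = substream(seed, f"sensor_{mode}") if (shot_noise or read_sd) else None
        frame = dofp.simulate_dofp_mosaic(
            stokes, exposure_scale=exposure_scale, shot_noise=shot_noise,
            read_sd=read_sd, rng=gen, bitdepth=bitdepth, mode=mode,
            quantize=quantize,
        )
        sub = dofp.demosaic_bilinear(
            frame.pixels if quantize else frame.pixels, frame.layout
        )
        if mode == "retardance":
            ps = dofp.partial_stokes_linear(sub)
            pmap = dofp.retardance_map(ps)
        else:
            ps = dofp.partial_stokes_circular(sub)
            pmap = dofp.depolarization_map(ps)
        out[mode] = (pmap, ps)
    return out


@pytest.fixture
def m_phantom_ideal():
    """M phantom under ideal circular illumination (exact analytics)."""
    return scenes.make_m_phantom((64, 64), seed=1, illumination=IDEAL_CIRCULAR)
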