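"""Benchtop imaging Mueller polarimeter: instrument model, per-pixel
Mueller-matrix reconstruction and the polar (Lu–Chipman) decomposition.

The polarimeter probes the sample with four polarization-state-generator
(PSG) states — a 0° linear polarizer followed by a quarter waveplate at
−45°, 0°, 30° and 60° — and analyses the return with six
polarization-state-analyser (PSA) states: linear polarizers at −45°, 0°,
45° and 90° plus left- and right-circular analysers. The 6×4 intensity
stack per pixel over-determines the 16 Mueller elements; reconstruction
is linear least squares over all 24 measurements.

The decomposition factors each normalized matrix as
``M = M_Δ · M_R · M_D`` (depolarizer · retarder · diattenuator) and
derives the scalar maps used for tissue imaging:

* total depolarization ``T_dep = 1 − (tr M_Δ − 1)/3``;
* circular depolarization ``A_dep = 1 − |M_Δ(4,4)|``;
* retardance angle ``R = arccos(tr M_R / 2 − 1)`` on ``[0, π]`` and its
  magnitude ``A_δ = sin R`` (non-injective above π/2 by construction);
* diattenuation ``D = |first-row vector|``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    mueller_linear_polarizer,
    mueller_linear_retarder,
    apply_mueller,
)

__all__ = [
    "InstrumentModel",
    "PolarDecomposition",
    "build_psg",
    "build_psa",
    "build_instrument",
    "simulate_stack",
    "reconstruct_mueller",
    "lu_chipman",
    "decomposition_maps",
    "MuellerImage",
]

DEFAULT_PSG_ANGLES_DEG = (-45.0, 0.0, 30.0, 60.0)
DEFAULT_PSA_LINEAR_DEG = (-45.0, 0.0, 45.0, 90.0)


@dataclass
class InstrumentModel:
    """PSG/PSA description.

    ``W`` (4×4): columns are the four generator Stokes states, S0 = 1.
    ``A`` (6×4): rows are the analyzer vectors (first rows of the six
    analyzer Mueller matrices).
    """

    W: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.W.shape != (4, 4) or self.A.shape != (6, 4):
            raise ValueError("W must be 4×4 and A 6×4")
        if np.linalg.matrix_rank(self.W) < 4:
            raise ValueError("PSG state matrix W is singular")
        if np.linalg.matrix_rank(self.A) < 4:
            raise ValueError("PSA analyzer matrix A is rank deficient")

    @property
    def design_matrix(self) -> np.ndarray:
        """24×16 forward operator G with rows kron(a_j, w_k), PSA-major."""
        G = np.empty((24, 16))
        for j in range(6):
            for k in range(4):
                G[j * 4 + k] = np.kron(self.A[j], self.W[:, k])
        return G

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.design_matrix))


def build_psg(qwp_angles_deg=DEFAULT_PSG_ANGLES_DEG) -> np.ndarray:
    """Generator state matrix W from the quarter-waveplate angles.

    Column k is ``M_qwp(π/2, θ_k) · M_pol(0°) · (1,0,0,0)ᵀ`` renormalized
    to ``S0 = 1``. Raises if the angle set makes W singular.
    """
    angles = np.deg2rad(np.asarray(qwp_angles_deg, dtype=float))
    if angles.shape != (4,) or len(set(np.round(angles, 12))) < 4:
        raise ValueError("need four distinct quarter-waveplate angles")
    src = apply_mueller(mueller_linear_polarizer(0.0), np.array([1.0, 0, 0, 0]))
    cols = [apply_mueller(mueller_linear_retarder(np.pi / 2, t), src) for t in angles]
    W = np.stack([c / c[0] for c in cols], axis=1)
    if np.linalg.matrix_rank(W) < 4:
        raise ValueError("quarter-waveplate angle set yields a singular W")
    return W


def build_psa(linear_angles_deg=DEFAULT_PSA_LINEAR_DEG) -> np.ndarray:
    """Analyzer matrix A: four linear analysers plus left/right circular.

    Row j is the first row of analyzer j's Mueller matrix, i.e. the
    Stokes functional the detector measures behind it.
    """
    rows = [
        mueller_linear_polarizer(np.deg2rad(t))[0] for t in linear_angles_deg
    ]
    rows.append(0.5 * np.array([1.0, 0.0, 0.0, -1.0]))  # left circular
    rows.append(0.5 * np.array([1.0, 0.0, 0.0, 1.0]))  # right circular
    return np.stack(rows, axis=0)


def build_instrument(
    qwp_angles_deg=DEFAULT_PSG_ANGLES_DEG,
    linear_angles_deg=DEFAULT_PSA_LINEAR_DEG,
) -> InstrumentModel:
    return InstrumentModel(W=build_psg(qwp_angles_deg), A=build_psa(linear_angles_deg))


@dataclass
class MuellerImage:
    """Per-pixel 4×4 Mueller matrices with a validity mask."""

    M: np.ndarray  # (H, W, 4, 4)
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape[-2:] != (4, 4):
            raise ValueError("Mueller image must end in 4×4 matrices")
        if self.valid is None:
            self.valid = self.M[..., 0, 0] > 0


def simulate_stack(
    M_img,
    instrument: InstrumentModel,
    *,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward-model the 24-intensity acquisition.

    Returns an array of shape ``(..., 6, 4)``: ``I[j, k] = a_j · (M w_k)``
    per pixel, optionally with additive Gaussian noise of standard
    deviation ``noise_sd`` (absolute intensity units).
    """
    M = M_img.M if isinstance(M_img, MuellerImage) else np.asarray(M_img, dtype=float)
    I = np.einsum("ji,...ik,kl->...jl", instrument.A, M, instrument.W)
    if np.any(I < -1e-9):
        raise ValueError("non-physical Mueller input: negative noise-free intensity")
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        I = I + rng.normal(0.0, noise_sd, size=I.shape)
    return I


def reconstruct_mueller(stack, instrument: InstrumentModel) -> MuellerImage:
    """Least-squares per-pixel Mueller estimate from a ``(..., 6, 4)`` stack.

    All pixels are solved in one batched linear-algebra call; the result
    is identical to solving the 24-equation system pixel by pixel.
    """
    G = instrument.design_matrix
    if np.linalg.matrix_rank(G) < 16:
        raise ValueError("instrument forward operator is rank deficient")
    stack = np.asarray(stack, dtype=float)
    if stack.shape[-2:] != (6, 4):
        raise ValueError("stack must have shape (..., 6, 4)")
    flat = stack.reshape(stack.shape[:-2] + (24,))
    Ginv = np.linalg.pinv(G)
    M = (flat @ Ginv.T).reshape(stack.shape[:-2] + (4, 4))
    return MuellerImage(M)


@dataclass
class PolarDecomposition:
    """Result of the polar decomposition ``M ≈ M_Δ · M_R · M_D``.

    Scalar fields are arrays matching the input's leading shape (plain
    floats for a single matrix). ``degenerate`` flags pixels where the
    retarder sub-block required a pseudo-inverse (fully depolarizing
    along at least one axis); scalar outputs remain defined there.
    """

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray
    T_dep: np.ndarray
    A_dep: np.ndarray
    R: np.ndarray
    A_delta: np.ndarray
    D: np.ndarray
    degenerate: np.ndarray


_EIG_TOL = 1e-12


def lu_chipman(M) -> PolarDecomposition:
    """Polar decomposition of (batched) Mueller matrices.

    The input is normalized by ``m00`` (which must be positive). The
    diattenuator is built from the first row; ``M' = M M_D⁻¹`` is split
    into depolarizer and retarder using the symmetric square root of
    ``m' m'ᵀ`` (eigendecomposition) with the sign of ``det m'``;
    eigenvalues below 1e−12 switch that pixel to the pseudo-inverse
    branch and set the ``degenerate`` flag.
    """
    M = np.asarray(M, dtype=float)
    single = M.ndim == 2
    if single:
        M = M[None]
    m00 = M[..., 0, 0]
    if np.any(m00 <= 0):
        raise ValueError("lu_chipman requires m00 > 0")
    Mn = M / m00[..., None, None]

    D_vec = Mn[..., 0, 1:]
    D = np.linalg.norm(D_vec, axis=-1)
    # Diattenuator; |D| clipped just below 1 so M_D stays invertible.
    Dc = np.minimum(D, 1.0 - 1e-12)
    scale = np.where(D > 0, Dc / np.where(D == 0, 1.0, D), 0.0)
    Dv = D_vec * scale[..., None]
    sq = np.sqrt(1.0 - Dc**2)
    dhat = np.where(Dc[..., None] > 0, Dv / np.where(Dc == 0, 1.0, Dc)[..., None], 0.0)
    eye3 = np.eye(3)
    mD = sq[..., None, None] * eye3 + (1 - sq)[..., None, None] * (
        dhat[..., :, None] * dhat[..., None, :]
    )
    M_D = np.zeros_like(Mn)
    M_D[..., 0, 0] = 1.0
    M_D[..., 0, 1:] = Dv
    M_D[..., 1:, 0] = Dv
    M_D[..., 1:, 1:] = mD

    Mp = Mn @ np.linalg.inv(M_D)
    P_delta = Mp[..., 1:, 0]
    mp = Mp[..., 1:, 1:]

    S = mp @ np.swapaxes(mp, -1, -2)
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    sign = np.where(np.linalg.det(mp) < 0, -1.0, 1.0)
    sqrt_w = np.sqrt(w)
    m_delta = sign[..., None, None] * np.einsum(
        "...ik,...k,...jk->...ij", V, sqrt_w, V
    )
    degenerate = w[..., 0] < _EIG_TOL
    inv_sqrt_w = np.where(sqrt_w > np.sqrt(_EIG_TOL), 1.0 / np.maximum(sqrt_w, 1e-300), 0.0)
    m_delta_pinv = sign[..., None, None] * np.einsum(
        "...ik,...k,...jk->...ij", V, inv_sqrt_w, V
    )
    m_R = m_delta_pinv @ mp

    M_delta = np.zeros_like(Mn)
    M_delta[..., 0, 0] = 1.0
    M_delta[..., 1:, 0] = P_delta
    M_delta[..., 1:, 1:] = m_delta
    M_R = np.zeros_like(Mn)
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = m_R

    tr_mdelta = np.trace(m_delta, axis1=-2, axis2=-1)
    T_dep = 1.0 - tr_mdelta / 3.0
    A_dep = 1.0 - np.abs(M_delta[..., 3, 3])
    tr_MR = 1.0 + np.trace(m_R, axis1=-2, axis2=-1)
    R = np.arccos(np.clip(tr_MR / 2.0 - 1.0, -1.0, 1.0))
    A_delta = np.sin(R)

    def _s(x):
        return x[0] if single else x

    return PolarDecomposition(
        M_delta=_s(M_delta),
        M_R=_s(M_R),
        M_D=_s(M_D),
        T_dep=_s(T_dep),
        A_dep=_s(A_dep),
        R=_s(R),
        A_delta=_s(A_delta),
        D=_s(D),
        degenerate=_s(degenerate),
    )


def decomposition_maps(M_img: MuellerImage) -> dict:
    """Per-pixel decomposition scalar maps of a Mueller image.

    Returns ``ParameterMap``s for retardance (``A_δ = sin R``) and
    circular depolarization (``A_dep`` from ``M_Δ(4,4)``), plus the
    total-depolarization ``T_dep`` and diattenuation ``D`` maps. Pixels
    with ``m00 <= 0`` are masked invalid rather than fatal; per-pixel
    degeneracies are likewise only masked in the retardance map.
    """
    from .dofp import ParameterMap

    M = M_img.M
    ok = M[..., 0, 0] > 0
    Msafe = M.copy()
    Msafe[~ok] = np.eye(4)
    dec = lu_chipman(Msafe)
    valid = ok & np.asarray(M_img.valid, dtype=bool)
    return {
        "retardance": ParameterMap(
            np.clip(dec.A_delta, 0, 1), valid & ~dec.degenerate, "A_delta"
        ),
        "depolarization": ParameterMap(np.clip(dec.A_dep, 0, 1), valid, "A_dep"),
        "T_dep": ParameterMap(np.clip(dec.T_dep, 0, 1), valid, "T_dep"),
        "D": ParameterMap(np.clip(dec.D, 0, 1), valid, "D"),
    }
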