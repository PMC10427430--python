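"""Stokes/Mueller algebra for polarized-light imaging.

Conventions used throughout the package
---------------------------------------
* Stokes vectors are arrays whose last axis has length 4 and holds
  ``(S0, S1, S2, S3)``: total intensity, 0°/90° linear difference,
  ±45° linear difference and circular difference.
* ``S3 > 0`` denotes right-circular polarization.
* A linear retarder with fast axis ``theta`` and retardance ``delta``
  rotates the polarization ellipse such that for ``theta = 0`` the
  matrix is ``diag(1, 1, cos δ, sin δ; -sin δ, cos δ)`` acting on
  ``(S2, S3)`` — i.e. right-circular light emerges at +45° linear for
  ``δ = π/2, θ = 0``.
* Angles are radians everywhere inside the library; degrees appear
  only at command-line boundaries.

All element constructors broadcast: scalar arguments give a single
``(4, 4)`` matrix, array arguments of shape ``(...)`` give matrices of
shape ``(..., 4, 4)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PHYSICALITY_TOL",
    "mueller_linear_retarder",
    "mueller_linear_polarizer",
    "mueller_depolarizer",
    "mueller_diattenuator",
    "apply_mueller",
    "polarization_degrees",
    "is_physical_stokes",
]

#: Numeric tolerance for the physicality check sqrt(S1²+S2²+S3²) <= S0 (1+ε)
#: on noise-free algebra. Noisy data needs a looser, caller-supplied value.
PHYSICALITY_TOL = 1e-9


def mueller_linear_retarder(delta, theta=0.0) -> np.ndarray:
    """Mueller matrix of a linear retarder.

    Parameters
    ----------
    delta : float or array
        Retardance (phase delay between fast and slow axis) in radians.
        Wrapped into ``[0, 2π)``.
    theta : float or array
        Fast-axis orientation in radians, wrapped into ``[0, π)``.

    Returns
    -------
    ndarray of shape ``(..., 4, 4)`` with determinant 1 and ``m00 = 1``.
    """
    delta = np.mod(np.asarray(delta, dtype=float), 2 * np.pi)
    theta = np.mod(np.asarray(theta, dtype=float), np.pi)
    delta, theta = np.broadcast_arrays(delta, theta)
    c2 = np.cos(2 * theta)
    s2 = np.sin(2 * theta)
    cd = np.cos(delta)
    sd = np.sin(delta)
    one = np.ones_like(c2)
    zero = np.zeros_like(c2)
    M = np.stack(
        [
            np.stack([one, zero, zero, zero], axis=-1),
            np.stack([zero, c2**2 + s2**2 * cd, c2 * s2 * (1 - cd), -s2 * sd], axis=-1),
            np.stack([zero, c2 * s2 * (1 - cd), s2**2 + c2**2 * cd, c2 * sd], axis=-1),
            np.stack([zero, s2 * sd, -c2 * sd, cd], axis=-1),
        ],
        axis=-2,
    )
    return M


def mueller_linear_polarizer(theta=0.0) -> np.ndarray:
    """Mueller matrix of an ideal linear polarizer with transmission axis
    ``theta`` (radians, wrapped into [0, π)). ``m00 = 1/2``."""
    theta = np.mod(np.asarray(theta, dtype=float), np.pi)
    c2 = np.cos(2 * theta)
    s2 = np.sin(2 * theta)
    one = np.ones_like(c2)
    zero = np.zeros_like(c2)
    M = 0.5 * np.stack(
        [
            np.stack([one, c2, s2, zero], axis=-1),
            np.stack([c2, c2**2, c2 * s2, zero], axis=-1),
            np.stack([s2, c2 * s2, s2**2, zero], axis=-1),
            np.stack([zero, zero, zero, zero], axis=-1),
        ],
        axis=-2,
    )
    return M


def mueller_depolarizer(a, b=None, c=None) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, a, b, c)``.

    ``a`` and ``b`` scale the linear polarization channels, ``c`` the
    circular one; a pure depolarizer with factor ``c`` yields circular
    depolarization ``A_dep = 1 - c`` downstream. Factors must lie in
    ``[0, 1]``. Called with a single argument, ``a = b = c``.
    """
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    c = a if c is None else np.asarray(c, dtype=float)
    a, b, c = np.broadcast_arrays(a, b, c)
    for name, f in (("a", a), ("b", b), ("c", c)):
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError(f"depolarizer factor {name!r} outside [0, 1]")
    one = np.ones_like(a)
    zero = np.zeros_like(a)
    M = np.stack(
        [
            np.stack([one, zero, zero, zero], axis=-1),
            np.stack([zero, a, zero, zero], axis=-1),
            np.stack([zero, zero, b, zero], axis=-1),
            np.stack([zero, zero, zero, c], axis=-1),
        ],
        axis=-2,
    )
    return M


def mueller_diattenuator(D) -> np.ndarray:
    """Mueller matrix of a diattenuator with diattenuation vector ``D``.

    Uses the polar-decomposition form with unit transmittance:
    first row ``(1, Dᵀ)``, first column ``(1, D)`` and 3×3 block
    ``sqrt(1-D²) I + (1 - sqrt(1-D²)) D̂ D̂ᵀ``. Requires ``|D| <= 1``.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-1] != 3:
        raise ValueError("diattenuation vector must have 3 components")
    d = np.linalg.norm(D, axis=-1)
    if np.any(d > 1 + 1e-12):
        raise ValueError("|D| > 1 is unphysical")
    d = np.minimum(d, 1.0)
    sq = np.sqrt(1.0 - d**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dhat = np.where(d[..., None] > 0, D / np.where(d == 0, 1.0, d)[..., None], 0.0)
    eye = np.broadcast_to(np.eye(3), D.shape[:-1] + (3, 3))
    mD = sq[..., None, None] * eye + (1 - sq)[..., None, None] * (
        dhat[..., :, None] * dhat[..., None, :]
    )
    M = np.zeros(D.shape[:-1] + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 0, 1:] = D
    M[..., 1:, 0] = D
    M[..., 1:, 1:] = mD
    return M


def apply_mueller(M, S) -> np.ndarray:
    """Propagate Stokes state(s) ``S`` through Mueller matrix/matrices ``M``.

    Broadcasts: ``M`` has shape ``(..., 4, 4)``, ``S`` shape ``(..., 4)``.
    """
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    return np.einsum("...ij,...j->...i", M, S)


def polarization_degrees(S) -> dict:
    """Degrees of polarization of Stokes state(s) ``S``.

    Returns ``{"dop", "dolp", "docp"}`` where
    ``dolp = sqrt(S1²+S2²)/S0``, ``docp = |S3|/S0`` and
    ``dop = sqrt(S1²+S2²+S3²)/S0``.

    Raises ``ValueError`` if any ``S0 <= 0`` (degree undefined).
    """
    S = np.asarray(S, dtype=float)
    S0 = S[..., 0]
    if np.any(S0 <= 0):
        raise ValueError("degree of polarization undefined for S0 <= 0")
    dolp = np.hypot(S[..., 1], S[..., 2]) / S0
    docp = np.abs(S[..., 3]) / S0
    dop = np.sqrt(S[..., 1] ** 2 + S[..., 2] ** 2 + S[..., 3] ** 2) / S0
    return {"dop": dop, "dolp": dolp, "docp": docp}


def is_physical_stokes(S, tol: float = PHYSICALITY_TOL) -> np.ndarray:
    """True where ``S0 >= 0`` and the polarized part does not exceed ``S0``."""
    S = np.asarray(S, dtype=float)
    S0 = S[..., 0]
    p = np.sqrt(S[..., 1] ** 2 + S[..., 2] ** 2 + S[..., 3] ** 2)
    return (S0 >= -tol) & (p <= S0 * (1 + tol) + tol)
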