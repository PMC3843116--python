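"""Indentation modulus of an anisotropic elastic half-space.

For an axisymmetric frictionless indenter pressed along the surface normal
``r`` of a half-space with stiffness ``C``, the equivalent indentation
modulus M (the quantity that reduces to E/(1-nu^2) for isotropic materials)
follows from the surface Green's function of the anisotropic half-space.
Using the Barnett-Lothe / Stroh integral formalism, the tensor

    L(t) = -(1/pi) * int_0^pi [ R T^-1 R^T - Q ](omega) d omega,

with Q_ik = C_ijkl m_j m_l, R_ik = C_ijkl m_j n_l, T_ik = C_ijkl n_j n_l
evaluated for the rotated pair m = t cos w + r sin w, n = r cos w - t sin w,
is real, symmetric and positive definite for any in-surface direction t.
The normal surface compliance per unit wavenumber is 2 (L^-1)_rr, and the
circular-contact (Vlassak-Nix) equivalent modulus is the angular harmonic
mean

    M = 2 / < r . L(t(phi))^-1 . r >_phi .

This is exact when the surface normal is a symmetry axis of the material
(isotropic; transversely isotropic indented on-axis) and is the standard
equivalent-modulus approximation otherwise. Both angular integrals use
periodic trapezoid quadrature, which converges spectrally for these smooth
pi-periodic integrands.

The fibril axis of the material frame is e3; the out-of-plane fibril angle
theta maps to the indentation direction r(theta) = [0, sin theta, cos theta].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidAngleError, InvalidMaterialError, QuadratureError
from .tensor import StiffnessTensor

__all__ = [
    "IndentDirection",
    "direction_from_theta",
    "indentation_modulus",
    "indentation_modulus_batch",
    "modulus_vs_theta_profile",
]

DEFAULT_QUADRATURE = (360, 180)  # (surface azimuth phi, Stroh angle omega)


@dataclass(frozen=True)
class IndentDirection:
    """An indentation direction given by the out-of-plane fibril angle."""

    theta: float  # degrees
    r: np.ndarray  # unit 3-vector in the material frame

    def __post_init__(self):
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if not np.isclose(np.linalg.norm(self.r), 1.0, atol=1e-10):
            raise InvalidAngleError("indentation direction must be a unit vector")


def direction_from_theta(theta: float) -> IndentDirection:
    """Direction r(theta) = [0, sin(theta), cos(theta)], theta in degrees."""
    if not (0.0 <= theta <= 90.0):
        raise InvalidAngleError(f"fibril angle {theta} outside [0, 90] degrees")
    t = np.radians(theta)
    return IndentDirection(float(theta), np.array([0.0, np.sin(t), np.cos(t)]))


def _surface_frames(rs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two in-surface unit vectors orthogonal to each normal in ``rs`` (B,3)."""
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (len(rs), 1))
    near = np.abs(rs[:, 0]) > 0.9
    ref[near] = np.array([0.0, 1.0, 0.0])
    t0 = np.cross(ref, rs)
    t0 /= np.linalg.norm(t0, axis=1, keepdims=True)
    t1 = np.cross(rs, t0)
    return t0, t1


def indentation_modulus_batch(
    C4s: np.ndarray,
    rs: np.ndarray,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """Vectorized indentation moduli for a batch of stiffness tensors.

    Parameters
    ----------
    C4s : (B, 3, 3, 3, 3) array of fourth-order stiffness tensors (GPa).
    rs : (B, 3) array of unit indentation directions.
    quadrature : (n_phi, n_omega) point counts of the two periodic rules.
    """
    n_phi, n_omega = quadrature
    B = len(C4s)
    rs = np.asarray(rs, dtype=float)
    t0, t1 = _surface_frames(rs)
    # the integrands are pi-periodic in both angles: sample [0, pi)
    phi = (np.arange(n_phi) + 0.5) * np.pi / n_phi
    om = (np.arange(n_omega) + 0.5) * np.pi / n_omega
    # t(phi): (B, n_phi, 3); m,n: (B, n_phi, n_omega, 3)
    t = np.cos(phi)[None, :, None] * t0[:, None, :] + np.sin(phi)[None, :, None] * t1[:, None, :]
    co, so = np.cos(om), np.sin(om)
    m = co[None, None, :, None] * t[:, :, None, :] + so[None, None, :, None] * rs[:, None, None, :]
    n = co[None, None, :, None] * rs[:, None, None, :] - so[None, None, :, None] * t[:, :, None, :]
    Q = np.einsum("bijkl,bpwj,bpwl->bpwik", C4s, m, m, optimize=True)
    R = np.einsum("bijkl,bpwj,bpwl->bpwik", C4s, m, n, optimize=True)
    T = np.einsum("bijkl,bpwj,bpwl->bpwik", C4s, n, n, optimize=True)
    try:
        Tinv = np.linalg.inv(T)
    except np.linalg.LinAlgError as exc:
        raise InvalidMaterialError(f"singular acoustic tensor T(omega): {exc}") from exc
    N3 = np.einsum("bpwij,bpwjk,bpwlk->bpwil", R, Tinv, R, optimize=True) - Q
    L = -N3.mean(axis=2)  # (B, n_phi, 3, 3); trapezoid mean over omega
    ev_min = np.linalg.eigvalsh(L).min()
    if not ev_min > 0:
        raise InvalidMaterialError(
            "Barnett-Lothe tensor not positive definite; material is not stable"
        )
    g = np.einsum("bi,bpij,bj->bp", rs, np.linalg.inv(L), rs)  # normal compliance / 2
    return 2.0 / g.mean(axis=1)


def indentation_modulus(
    C: StiffnessTensor,
    direction: IndentDirection,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
    check_convergence: bool = False,
    rtol: float = 1e-6,
) -> float:
    """Equivalent indentation modulus (GPa) along ``direction``.

    With ``check_convergence=True`` the angular quadrature is repeated at
    twice the resolution and a :class:`QuadratureError` is raised if the two
    results differ by more than ``rtol`` relative.
    """
    if not C.is_positive_definite():
        raise InvalidMaterialError("stiffness tensor must be positive definite")
    C4 = C.to_tensor4()[None]
    r = direction.r[None]
    M = float(indentation_modulus_batch(C4, r, quadrature)[0])
    if check_convergence:
        M2 = float(
            indentation_modulus_batch(C4, r, (2 * quadrature[0], 2 * quadrature[1]))[0]
        )
        if abs(M2 - M) > rtol * abs(M2):
            raise QuadratureError(
                f"quadrature not converged: |dM|/M = {abs(M2 - M) / abs(M2):.2e} > {rtol}"
            )
    return M


def modulus_vs_theta_profile(
    C: StiffnessTensor,
    thetas,
    quadrature: tuple[int, int] = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """Indentation moduli for a sweep of fibril angles (degrees)."""
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if thetas.size == 0:
        return np.array([])
    dirs = np.stack([direction_from_theta(t).r for t in thetas])
    C4s = np.broadcast_to(C.to_tensor4(), (len(dirs), 3, 3, 3, 3))
    return indentation_modulus_batch(C4s, dirs, quadrature)
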