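"""Three-level mean-field model of the mineralized collagen fibril array.

The fibril array is homogenized bottom-up with the Mori-Tanaka scheme
(aligned spheroidal inclusions, symmetry axis e3):

(a) *mineralized fibril* — prolate isotropic mineral spheroids (aspect ratio
    14) unidirectionally embedded in an isotropic collagen matrix;
(b) *extra-fibrillar matrix* — a mineral foam: spherical voids in mineral;
(c) *fibril array* — highly elongated prolate spheroids of fibril material
    (aspect ratio 100) embedded in the extra-fibrillar matrix.

The total mineral volume fraction ``phi`` of the array is split between
fibrils and the extra-fibrillar space by the mineral quota ``q`` and the
fibril volume fraction ``f_fibril``::

    f_min_in_fibril = q * phi / f_fibril
    f_void_in_ef    = 1 - (1 - q) * phi / (1 - f_fibril)

The closed-form Eshelby tensor assumes an isotropic matrix; at level (c) the
matrix may be anisotropic, so the Hill polarization tensor is either computed
for the Frobenius-closest isotropic tensor (default) or by angular
integration for the fully anisotropic matrix (``eshelby_method='numeric'``).
At the default parameters the foam is exactly isotropic and both routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import (
    DegenerateMaterialError,
    InfeasiblePartitionError,
    InvalidParameterError,
    NumericalConditioningError,
)
from .tensor import StiffnessTensor, isotropic_stiffness

__all__ = [
    "FibrilArrayParams",
    "PhasePartition",
    "eshelby_spheroid",
    "hill_polarization_numeric",
    "closest_isotropic",
    "mori_tanaka",
    "partition_phases",
    "fibril_array_stiffness",
]

_I6 = np.eye(6)


@dataclass(frozen=True)
class FibrilArrayParams:
    """Input parameter set of the fibril-array model (literature defaults).

    ``phi_mineral`` is the only site-dependent quantity: the total mineral
    volume fraction of the fibril array from the qBEI calibration.
    """

    E_collagen: float = 5.0  # GPa
    nu_collagen: float = 0.3
    E_mineral: float = 110.5  # GPa
    nu_mineral: float = 0.28
    ar_mineral: float = 14.0  # platelet aspect ratio inside the fibril
    ar_void: float = 1.0  # void aspect ratio in the extra-fibrillar foam
    ar_fibril: float = 100.0  # fibril aspect ratio in the array
    f_fibril: float = 0.53  # fibril volume fraction in the array
    q_mineral: float = 0.25  # quota of total mineral residing inside fibrils
    phi_mineral: float = 0.38  # total mineral volume fraction of the array

    def __post_init__(self):
        for name in ("f_fibril", "q_mineral", "phi_mineral"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        for name in ("ar_mineral", "ar_void", "ar_fibril"):
            v = getattr(self, name)
            if not v >= 1.0:
                raise InvalidParameterError(f"{name}={v} must be >= 1")
        for name in ("E_collagen", "E_mineral"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")

    def with_phi(self, phi: float) -> "FibrilArrayParams":
        return replace(self, phi_mineral=float(phi))

    @classmethod
    def from_yaml(cls, path) -> "FibrilArrayParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass(frozen=True)
class PhasePartition:
    f_min_in_fibril: float
    f_void_in_ef: float


def _spheroid_I_integrals(aspect_ratio: float) -> tuple[float, float, float, float, float]:
    """Mura-type I integrals for a prolate spheroid a1=a2=1, a3=alpha >= 1.

    Returns (I1, I3, I11, I13, I33); I2=I1, I12=I11 by the axial symmetry.
    """
    a = float(aspect_ratio)
    if abs(a - 1.0) < 1e-9:
        I1 = I3 = 4 * np.pi / 3
        I11 = I13 = I33 = 4 * np.pi / 5
        return I1, I3, I11, I13, I33
    e2 = a * a - 1.0
    I1 = 2 * np.pi * a / e2**1.5 * (a * np.sqrt(e2) - np.arccosh(a))
    I3 = 4 * np.pi - 2 * I1
    I13 = (I1 - I3) / (a * a - 1.0)
    I11 = np.pi - I13 / 4.0
    I33 = (4 * np.pi / (a * a) - 2 * I13) / 3.0
    return I1, I3, I11, I13, I33


def eshelby_spheroid(nu_matrix: float, aspect_ratio: float) -> np.ndarray:
    """Closed-form Eshelby tensor of a spheroid in an isotropic matrix.

    Parameters
    ----------
    nu_matrix : Poisson ratio of the (isotropic) matrix.
    aspect_ratio : symmetry-axis over equatorial semi-axis length; 1 is a
        sphere, > 1 a prolate spheroid with axis e3.

    Returns
    -------
    (6, 6) array: the Eshelby tensor in Mandel notation. It has minor but not
    major symmetry, so it is returned as a plain matrix, not a
    ``StiffnessTensor``.
    """
    nu = float(nu_matrix)
    if not (-1.0 < nu < 0.5):
        raise InvalidParameterError(f"matrix Poisson ratio {nu} outside (-1, 0.5)")
    if aspect_ratio < 1.0:
        raise InvalidParameterError("oblate spheroids (aspect ratio < 1) are not supported")
    a2 = float(aspect_ratio) ** 2
    I1, I3, I11, I13, I33 = _spheroid_I_integrals(aspect_ratio)
    c = 1.0 / (8 * np.pi * (1 - nu))
    k = (1 - 2 * nu)
    S = np.zeros((3, 3, 3, 3))

    S1111 = c * (3 * I11 + k * I1)
    S3333 = c * (3 * a2 * I33 + k * I3)
    S1122 = c * (I11 - k * I1)  # I12 = I11, a2^2 = 1
    S1133 = c * (a2 * I13 - k * I1)
    S3311 = c * (I13 - k * I3)
    S1212 = c * (I11 + k * I1)  # (a1^2+a2^2)/2 * I12 + k(I1+I2)/2
    S1313 = c * ((1 + a2) / 2 * I13 + k * (I1 + I3) / 2)

    def put(i, j, k_, l, v):
        for (p, q) in ((i, j), (j, i)):
            for (r, s) in ((k_, l), (l, k_)):
                S[p, q, r, s] = v

    put(0, 0, 0, 0, S1111)
    put(1, 1, 1, 1, S1111)
    put(2, 2, 2, 2, S3333)
    put(0, 0, 1, 1, S1122)
    put(1, 1, 0, 0, S1122)
    put(0, 0, 2, 2, S1133)
    put(1, 1, 2, 2, S1133)
    put(2, 2, 0, 0, S3311)
    put(2, 2, 1, 1, S3311)
    put(0, 1, 0, 1, S1212)
    put(0, 2, 0, 2, S1313)
    put(1, 2, 1, 2, S1313)

    # Mandel 6x6 form of a minor-symmetric fourth-order tensor
    from .tensor import _PAIRS, _W  # internal mapping shared with StiffnessTensor

    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(_PAIRS):
        for J, (p, q) in enumerate(_PAIRS):
            M[I, J] = S[i, j, p, q] * _W[I] * _W[J]
    return M


def hill_polarization_numeric(
    C_matrix: StiffnessTensor,
    aspect_ratio: float,
    n_polar: int = 64,
    n_azimuth: int = 128,
) -> np.ndarray:
    """Hill polarization tensor P of a spheroid in an arbitrary matrix.

    Angular integration over the unit sphere (Gauss-Legendre in the polar
    cosine, periodic trapezoid in azimuth) of the acoustic-tensor inverse:

        P = (a1 a2 a3 / 4 pi) * int  sym[K^-1_ik(x) x_j x_l] / |A x|^3  dS(x)

    with K_ik = C_ijkl x_j x_l and A = diag(a1, a2, a3). Returns P in Mandel
    notation (units 1/GPa). The Eshelby tensor follows as S = P : C_matrix.
    """
    if aspect_ratio < 1.0:
        raise InvalidParameterError("oblate spheroids (aspect ratio < 1) are not supported")
    C4 = C_matrix.to_tensor4()
    a = np.array([1.0, 1.0, float(aspect_ratio)])
    g, wg = np.polynomial.legendre.leggauss(n_polar)
    c = np.sqrt(max(float(aspect_ratio) ** 2 - 1.0, 0.0))
    if c > 1e-6:
        # substitution u = tan(alpha)/c concentrates nodes where the
        # 1/(1 + c^2 u^2)^{3/2} metric factor is peaked (u ~ 1/c)
        alpha_max = np.arctan(c)
        alpha = g * alpha_max
        u = np.tan(alpha) / c
        wu = wg * alpha_max / (c * np.cos(alpha) ** 2)
    else:
        u, wu = g, wg
    phi = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    wphi = 2 * np.pi / n_azimuth
    su = np.sqrt(np.clip(1 - u**2, 0.0, None))
    # grid of unit vectors, shape (n_polar*n_azimuth, 3)
    X = np.stack(
        [
            np.outer(su, np.cos(phi)).ravel(),
            np.outer(su, np.sin(phi)).ravel(),
            np.outer(u, np.ones_like(phi)).ravel(),
        ],
        axis=-1,
    )
    W = (np.outer(wu, np.ones_like(phi)) * wphi).ravel()
    K = np.einsum("ijkl,pj,pl->pik", C4, X, X)
    try:
        Kinv = np.linalg.inv(K)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalConditioningError(f"singular acoustic tensor: {exc}") from exc
    metric = np.einsum("pi,i,pi->p", X, a**2, X) ** 1.5
    H = np.einsum("pik,pj,pl->pijkl", Kinv, X, X)
    P4 = np.einsum("p,pijkl->ijkl", W / metric, H) * np.prod(a) / (4 * np.pi)
    # enforce minor symmetries
    P4 = 0.25 * (
        P4
        + P4.transpose(1, 0, 2, 3)
        + P4.transpose(0, 1, 3, 2)
        + P4.transpose(1, 0, 3, 2)
    )
    from .tensor import _PAIRS, _W

    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(_PAIRS):
        for J, (p, q) in enumerate(_PAIRS):
            M[I, J] = P4[i, j, p, q] * _W[I] * _W[J]
    return M


def closest_isotropic(C: StiffnessTensor) -> StiffnessTensor:
    """Frobenius projection of a stiffness tensor onto the isotropic subspace."""
    kappa, mu = C.isotropic_projection_constants()
    if kappa <= 0 or mu <= 0:
        raise DegenerateMaterialError("isotropic projection is not positive definite")
    E = 9 * kappa * mu / (3 * kappa + mu)
    nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
    return isotropic_stiffness(E, nu)


def _polarization_for(
    C_matrix: StiffnessTensor, aspect_ratio: float, method: str
) -> np.ndarray:
    """Hill polarization P (Mandel) for a spheroid in ``C_matrix``."""
    if method == "numeric":
        return hill_polarization_numeric(C_matrix, aspect_ratio)
    if method in ("closed_form", "isotropized"):
        iso = closest_isotropic(C_matrix)
        _, nu = iso.isotropic_constants()
        S = eshelby_spheroid(nu, aspect_ratio)
        return S @ np.linalg.inv(iso.m)
    raise InvalidParameterError(f"unknown eshelby method {method!r}")


def mori_tanaka(
    C_matrix: StiffnessTensor,
    C_inclusion: StiffnessTensor | None,
    f: float,
    aspect_ratio: float,
    eshelby_method: str = "closed_form",
) -> StiffnessTensor:
    """Mori-Tanaka effective stiffness for aligned spheroidal inclusions.

    ``C_inclusion=None`` (or an all-zero tensor) models voids. The dilute
    concentration tensor is A = [I + P : (C_i - C_m)]^-1 with P the Hill
    polarization of the inclusion shape in the matrix, and

        C_eff = C_m + f (C_i - C_m) : A : [(1-f) I + f A]^-1.
    """
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError(f"volume fraction {f} outside [0, 1]")
    Cm = C_matrix.m
    Ci = np.zeros((6, 6)) if C_inclusion is None else C_inclusion.m
    if f == 0.0:
        return StiffnessTensor(Cm.copy(), C_matrix.symmetry_class)
    if f == 1.0:
        return StiffnessTensor(Ci.copy())
    dC = Ci - Cm
    P = _polarization_for(C_matrix, aspect_ratio, eshelby_method)
    try:
        A = np.linalg.solve(_I6 + P @ dC, _I6)
        mix = (1.0 - f) * _I6 + f * A
        C_eff = Cm + f * dC @ A @ np.linalg.solve(mix, _I6)
    except np.linalg.LinAlgError as exc:
        raise NumericalConditioningError(
            f"singular concentration system (f={f}, ar={aspect_ratio}): {exc}"
        ) from exc
    C_eff = 0.5 * (C_eff + C_eff.T)
    return StiffnessTensor(C_eff)


def partition_phases(p: FibrilArrayParams) -> PhasePartition:
    """Split the total mineral between fibrils and the extra-fibrillar space."""
    phi, q, ff = p.phi_mineral, p.q_mineral, p.f_fibril
    if ff == 1.0:
        if q < 1.0 and phi > 0:
            raise InfeasiblePartitionError(
                "f_fibril=1 leaves no extra-fibrillar space for mineral with q<1"
            )
        return PhasePartition(phi, 0.0)
    if ff == 0.0:
        if q > 0.0 and phi > 0:
            raise InfeasiblePartitionError("f_fibril=0 with q>0 puts mineral in absent fibrils")
        f_void = 1.0 - (1.0 - q) * phi
        return PhasePartition(0.0, f_void)
    f_min = q * phi / ff
    f_void = 1.0 - (1.0 - q) * phi / (1.0 - ff)
    eps = 1e-12
    if not (-eps <= f_min <= 1 + eps) or not (-eps <= f_void <= 1 + eps):
        raise InfeasiblePartitionError(
            f"infeasible partition: f_min_in_fibril={f_min:.4f}, f_void_in_ef={f_void:.4f}"
        )
    return PhasePartition(float(np.clip(f_min, 0, 1)), float(np.clip(f_void, 0, 1)))


def fibril_array_stiffness(
    p: FibrilArrayParams, eshelby_method: str = "closed_form"
) -> StiffnessTensor:
    """Transversely isotropic stiffness of the fibril array (axis e3).

    Chains the three Mori-Tanaka homogenizations (fibril, extra-fibrillar
    foam, array). ``eshelby_method`` selects how the level-(c) polarization
    tensor handles an anisotropic foam: ``'closed_form'`` isotropizes the
    matrix for the Eshelby tensor only, ``'numeric'`` integrates the
    polarization tensor for the full anisotropic matrix.
    """
    part = partition_phases(p)
    collagen = isotropic_stiffness(p.E_collagen, p.nu_collagen)
    mineral = isotropic_stiffness(p.E_mineral, p.nu_mineral)

    C_fibril = mori_tanaka(collagen, mineral, part.f_min_in_fibril, p.ar_mineral)
    if p.f_fibril == 1.0:
        C_fibril.symmetry_class = "transverse_isotropic"
        return C_fibril
    if part.f_void_in_ef >= 1.0 - 1e-9:
        raise DegenerateMaterialError(
            "extra-fibrillar matrix is all void (zero stiffness); "
            f"f_void_in_ef={part.f_void_in_ef:.4f}"
        )
    C_ef = mori_tanaka(mineral, None, part.f_void_in_ef, p.ar_void)
    C_arr = mori_tanaka(C_ef, C_fibril, p.f_fibril, p.ar_fibril, eshelby_method=eshelby_method)
    C_arr.symmetry_class = "transverse_isotropic"
    return C_arr
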