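"""Fourth-order stiffness tensors in orthonormal (Mandel) 6x6 notation.

All stiffness matrices in this package are stored in the orthonormal Mandel
basis, in which the 6x6 matrix of a fourth-order tensor with minor symmetries
behaves exactly like the tensor itself under inversion and composition: no
factor-of-two bookkeeping is needed in the Eshelby / Mori-Tanaka algebra.
Voigt matrices are accepted and emitted only at I/O boundaries.

Conventions
-----------
* Component order 11, 22, 33, 23, 13, 12.
* Mandel scaling: rows/columns 4-6 carry a factor sqrt(2) relative to Voigt.
* Moduli in GPa; the fibril axis of transversely isotropic materials is e3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidMaterialError, InvalidParameterError, InvalidRotationError

__all__ = [
    "StiffnessTensor",
    "isotropic_stiffness",
    "transverse_isotropic_stiffness",
    "rotate_stiffness",
    "check_transverse_isotropy",
    "rotation_about_axis",
    "rotation_aligning_e3",
    "mandel_to_voigt",
    "voigt_to_mandel",
]

# index pairs for Voigt/Mandel slot I -> (i, j)
_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
_SQRT2 = np.sqrt(2.0)
# Mandel weights per 6-slot
_W = np.array([1.0, 1.0, 1.0, _SQRT2, _SQRT2, _SQRT2])


def _check_rotation(R: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol * 10):
        raise InvalidRotationError("matrix is not orthogonal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise InvalidRotationError("matrix is not proper (det != +1)")
    return R


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` degrees about ``axis`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise InvalidRotationError("axis must be nonzero")
    a = a / n
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotation_aligning_e3(r) -> np.ndarray:
    """Smallest proper rotation mapping e3 = [0,0,1] onto the unit vector r."""
    r = np.asarray(r, dtype=float)
    r = r / np.linalg.norm(r)
    e3 = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(e3, r))
    if c > 1 - 1e-14:
        return np.eye(3)
    if c < -1 + 1e-14:  # antipodal: rotate pi about e1
        return rotation_about_axis([1.0, 0.0, 0.0], 180.0)
    axis = np.cross(e3, r)
    angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return rotation_about_axis(axis, angle)


def voigt_to_mandel(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    return V * np.outer(_W, _W)


def mandel_to_voigt(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    return M / np.outer(_W, _W)


def _mandel_to_tensor4(M: np.ndarray) -> np.ndarray:
    C = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(_PAIRS):
        for J, (k, l) in enumerate(_PAIRS):
            v = M[I, J] / (_W[I] * _W[J])
            for (a, b) in ((i, j), (j, i)):
                for (c, d) in ((k, l), (l, k)):
                    C[a, b, c, d] = v
    return C


def _tensor4_to_mandel(C: np.ndarray) -> np.ndarray:
    M = np.zeros((6, 6))
    for I, (i, j) in enumerate(_PAIRS):
        for J, (k, l) in enumerate(_PAIRS):
            M[I, J] = C[i, j, k, l] * _W[I] * _W[J]
    return M


@dataclass
class StiffnessTensor:
    """A fourth-order elasticity tensor, stored as a 6x6 Mandel matrix in GPa.

    Parameters
    ----------
    m : (6, 6) array
        Mandel-notation stiffness matrix.
    symmetry_class : {"isotropic", "transverse_isotropic", "general"}
        Advisory tag; invariants are checked numerically, not from the tag.
    """

    m: np.ndarray
    symmetry_class: str = "general"

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (6, 6):
            raise InvalidParameterError(f"stiffness matrix must be 6x6, got {self.m.shape}")
        nrm = np.linalg.norm(self.m)
        if nrm > 0 and np.linalg.norm(self.m - self.m.T) > 1e-10 * nrm:
            raise InvalidMaterialError("stiffness matrix is not symmetric")
        self.m = 0.5 * (self.m + self.m.T)

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_voigt(cls, V, symmetry_class: str = "general") -> "StiffnessTensor":
        return cls(voigt_to_mandel(V), symmetry_class)

    @classmethod
    def from_tensor4(cls, C4, symmetry_class: str = "general") -> "StiffnessTensor":
        return cls(_tensor4_to_mandel(np.asarray(C4, dtype=float)), symmetry_class)

    # ---- views --------------------------------------------------------
    def to_voigt(self) -> np.ndarray:
        return mandel_to_voigt(self.m)

    def to_tensor4(self) -> np.ndarray:
        return _mandel_to_tensor4(self.m)

    # ---- properties ---------------------------------------------------
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.m)

    def is_positive_definite(self, tol: float = 1e-9) -> bool:
        ev = self.eigenvalues()
        return bool(ev.min() > tol * max(1.0, ev.max()))

    def isotropic_constants(self) -> tuple[float, float]:
        """(E, nu) recovered from the closest isotropic projection.

        Exact for isotropic tensors; for anisotropic input returns the
        constants of the Frobenius-closest isotropic tensor.
        """
        kappa, mu = self.isotropic_projection_constants()
        E = 9 * kappa * mu / (3 * kappa + mu)
        nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
        return E, nu

    def isotropic_projection_constants(self) -> tuple[float, float]:
        """Bulk and shear modulus (kappa, mu) of the Frobenius-closest isotropic tensor."""
        kappa = float(self.m[:3, :3].sum()) / 9.0
        mu = (float(np.trace(self.m)) - 3.0 * kappa) / 10.0
        return kappa, mu

    def young_along(self, r) -> float:
        """Uniaxial Young's modulus in direction ``r`` (unit vector)."""
        r = np.asarray(r, dtype=float)
        r = r / np.linalg.norm(r)
        S4 = _mandel_to_tensor4(np.linalg.inv(self.m))
        return 1.0 / float(np.einsum("ijkl,i,j,k,l->", S4, r, r, r, r))

    # ---- I/O ----------------------------------------------------------
    def to_csv(self, path, notation: str = "mandel") -> None:
        """Write the 6x6 matrix as CSV with a header row declaring notation/units."""
        mat = self.m if notation == "mandel" else self.to_voigt()
        with open(path, "w") as fh:
            fh.write(f"# stiffness,notation={notation},units=GPa,order=11,22,33,23,13,12\n")
            np.savetxt(fh, mat, delimiter=",", fmt="%.12g")

    @classmethod
    def from_csv(cls, path) -> "StiffnessTensor":
        with open(path) as fh:
            header = fh.readline()
            notation = "mandel"
            for tokpart in header.strip("#\n ").split(","):
                if tokpart.startswith("notation="):
                    notation = tokpart.split("=", 1)[1]
            mat = np.loadtxt(io.StringIO(fh.read()), delimiter=",")
        if notation == "voigt":
            return cls.from_voigt(mat)
        return cls(mat)


def isotropic_stiffness(E: float, nu: float) -> StiffnessTensor:
    """Isotropic stiffness tensor from Young's modulus (GPa) and Poisson ratio."""
    if not E > 0:
        raise InvalidParameterError(f"Young's modulus must be positive, got {E}")
    if not (-1.0 < nu < 0.5):
        raise InvalidParameterError(f"Poisson ratio must lie in (-1, 0.5), got {nu}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    V = np.zeros((6, 6))
    V[:3, :3] = lam
    V[np.diag_indices(3)] = lam + 2 * mu
    V[3, 3] = V[4, 4] = V[5, 5] = mu
    return StiffnessTensor(voigt_to_mandel(V), "isotropic")


def transverse_isotropic_stiffness(
    C11: float, C33: float, C12: float, C13: float, C44: float
) -> StiffnessTensor:
    """Transversely isotropic tensor about e3 from its five Voigt constants (GPa)."""
    V = np.zeros((6, 6))
    V[0, 0] = V[1, 1] = C11
    V[2, 2] = C33
    V[0, 1] = V[1, 0] = C12
    V[0, 2] = V[2, 0] = V[1, 2] = V[2, 1] = C13
    V[3, 3] = V[4, 4] = C44
    V[5, 5] = 0.5 * (C11 - C12)
    return StiffnessTensor(voigt_to_mandel(V), "transverse_isotropic")


def _mandel_rotation_operator(R: np.ndarray) -> np.ndarray:
    """6x6 orthogonal matrix acting on Mandel 6-vectors as R does on tensors."""
    Q = np.zeros((6, 6))
    for I, (i, j) in enumerate(_PAIRS):
        for J, (k, l) in enumerate(_PAIRS):
            if k == l:
                Q[I, J] = _W[I] * R[i, k] * R[j, k] / 1.0
            else:
                Q[I, J] = _W[I] * (R[i, k] * R[j, l] + R[i, l] * R[j, k]) / _SQRT2
    return Q


def rotate_stiffness(C: StiffnessTensor, R: np.ndarray) -> StiffnessTensor:
    """Rotate a stiffness tensor: C'_ijkl = R_ip R_jq R_kr R_ls C_pqrs."""
    R = _check_rotation(R)
    Q = _mandel_rotation_operator(R)
    return StiffnessTensor(Q @ C.m @ Q.T, C.symmetry_class if C.symmetry_class == "isotropic" else "general")


def check_transverse_isotropy(C: StiffnessTensor, axis, n_angles: int = 12) -> float:
    """Maximum relative Frobenius deviation of C under rotations about ``axis``.

    Returns 0 for a tensor exactly transversely isotropic about the axis.
    """
    a = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-8):
        raise InvalidParameterError("axis must be a unit vector")
    nrm = np.linalg.norm(C.m)
    if nrm == 0:
        return 0.0
    dev = 0.0
    for ang in np.linspace(0.0, 360.0, n_angles, endpoint=False)[1:]:
        Cr = rotate_stiffness(C, rotation_about_axis(a, ang))
        dev = max(dev, float(np.linalg.norm(Cr.m - C.m)) / nrm)
    return dev
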