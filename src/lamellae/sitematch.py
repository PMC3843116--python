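"""Registration of modality rasters and per-indent covariate extraction.

The measured indentation moduli live in the light-microscope frame; the
mineral and fibril-angle rasters come from different instruments and are
misaligned by small rigid-body movements. This module recovers the rigid
transform between modalities by normalized SSD minimization (coarse grid
search plus local simplex refinement) and extracts, for each indent, the
mean mineral volume fraction and fibril angle over the indenter-tip
interaction zone: a disk of radius 1.75 um (seven times the 500 nm
indentation depth across) centred on the indent position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, optimize

from .errors import (
    NoDataError,
    RegistrationDomainError,
    UninformativeImageError,
)
from .fields import ScalarField

__all__ = [
    "RigidTransform",
    "InteractionZone",
    "IndentSite",
    "register_rigid",
    "disk_average",
    "filter_indents",
    "extract_covariates",
    "sites_to_dataframe",
    "sites_from_dataframe",
]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid map p -> R(alpha) p + (dx, dy), coordinates in um."""

    dx: float = 0.0
    dy: float = 0.0
    alpha: float = 0.0  # degrees, counter-clockwise about the origin

    def matrix(self) -> np.ndarray:
        a = np.radians(self.alpha)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix().T + np.array([self.dx, self.dy])
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "RigidTransform":
        Rinv = self.matrix().T
        t = -Rinv @ np.array([self.dx, self.dy])
        return RigidTransform(float(t[0]), float(t[1]), -self.alpha)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        t = self.apply(np.array([other.dx, other.dy]))
        return RigidTransform(float(t[0]), float(t[1]), self.alpha + other.alpha)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"dx_um": self.dx, "dy_um": self.dy, "alpha_deg": self.alpha}, fh)

    @classmethod
    def from_yaml(cls, path) -> "RigidTransform":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["dx_um"], d["dy_um"], d["alpha_deg"])


@dataclass(frozen=True)
class InteractionZone:
    """Indenter-tip interaction disk; default radius 1.75 um."""

    r_in: float = 1.75  # um

    def __post_init__(self):
        if not self.r_in > 0:
            raise ValueError("interaction-zone radius must be positive")

    @property
    def area(self) -> float:
        return np.pi * self.r_in**2


@dataclass
class IndentSite:
    """One indent: position in the light-microscope frame, measurement,
    quality flag, and (once extracted/predicted) covariates and predictions."""

    id: int
    x: float  # um
    y: float  # um
    E_meas: float | None = None  # GPa
    region: str = "ost"  # {ost, int, mix}
    quality: str = "ok"  # {ok, surface_anomaly, curve_irregular, near_pore}
    phi_avg: float | None = None
    theta_avg: float | None = None  # degrees
    E_pred: float | None = None  # GPa
    E_pred0: float | None = None  # GPa
    pattern: int = 0


def _sample(field_: ScalarField, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear sample of a field at physical points; returns (values, valid)."""
    pts = np.atleast_2d(points)
    col = (pts[:, 0] - field_.origin[0]) / field_.pixel_size - 0.5
    row = (pts[:, 1] - field_.origin[1]) / field_.pixel_size - 0.5
    vals = ndimage.map_coordinates(field_.values, [row, col], order=1, mode="constant", cval=np.nan)
    m = ndimage.map_coordinates(
        field_.mask.astype(float), [row, col], order=1, mode="constant", cval=0.0
    )
    valid = (m > 0.999) & np.isfinite(vals)
    return vals, valid


def register_rigid(
    fixed: ScalarField,
    moving: ScalarField,
    initial: RigidTransform | None = None,
    window: tuple[float, float] = (5.0, 1.0),
    grid_step: float | None = None,
    stride: int | None = None,
) -> tuple[RigidTransform, float]:
    """Recover the rigid transform mapping fixed-frame to moving-frame coords.

    Minimizes the mean squared difference between the z-scored overlap of
    ``fixed`` and ``moving`` resampled at ``g(p)``, over translations within
    ``+-window[0]`` um and rotations within ``+-window[1]`` degrees around
    ``initial``. A coarse exhaustive grid start is refined with Nelder-Mead,
    so the optimization is deterministic.

    Returns (transform, residual) where residual is the final normalized MSD.
    """
    initial = initial or RigidTransform()
    if stride is None:
        # subsample the objective so the SSD uses at most ~4e4 pixels; the
        # optimum location is unchanged for smooth fields and the cost of the
        # exhaustive grid start stays bounded
        stride = max(1, int(np.sqrt(fixed.values.size / 4e4)))
    x, y = fixed.pixel_centers()
    X, Y = np.meshgrid(x[::stride], y[::stride])
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    fvals = fixed.values[::stride, ::stride].ravel()
    fmask = fixed.mask[::stride, ::stride].ravel()

    def objective(params) -> float:
        dx, dy, al = params
        g = RigidTransform(dx, dy, al)
        mvals, mvalid = _sample(moving, g.apply(pts))
        ok = fmask & mvalid
        if ok.sum() < 16:
            return 4.0  # worse than any informative overlap of z-scored images
        a = fvals[ok]
        b = mvals[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 4.0
        a = (a - a.mean()) / sa
        b = (b - b.mean()) / sb
        return float(np.mean((a - b) ** 2))

    # feasibility of the initial guess
    _, mvalid0 = _sample(moving, initial.apply(pts))
    if not np.any(fmask & mvalid0):
        raise RegistrationDomainError("no overlap between images under the initial transform")
    if fvals[fmask].std() == 0:
        raise UninformativeImageError("fixed image has no contrast in its valid region")

    step = grid_step if grid_step is not None else fixed.pixel_size
    dxs = initial.dx + np.arange(-window[0], window[0] + step / 2, step)
    dys = initial.dy + np.arange(-window[0], window[0] + step / 2, step)
    als = (
        initial.alpha + np.arange(-window[1], window[1] + 0.25, 0.5)
        if window[1] > 0
        else np.array([initial.alpha])
    )
    best, best_val = None, np.inf
    for al in als:
        for dx in dxs:
            for dy in dys:
                v = objective((dx, dy, al))
                if v < best_val:
                    best, best_val = (dx, dy, al), v
    if not np.isfinite(best_val) or best_val >= 4.0:
        raise UninformativeImageError("no informative overlap found in the search window")

    res = optimize.minimize(
        objective, best, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-10, "maxiter": 400},
    )
    dx, dy, al = res.x
    return RigidTransform(float(dx), float(dy), float(al)), float(res.fun)


def disk_average(field_: ScalarField, x: float, y: float, zone: InteractionZone) -> float:
    """Mean of the field over masked-in pixels whose centres lie in the disk."""
    xmin, xmax, ymin, ymax = field_.extent()
    r = zone.r_in
    if x + r < xmin or x - r > xmax or y + r < ymin or y - r > ymax:
        raise NoDataError(f"interaction disk at ({x:.2f}, {y:.2f}) lies outside the raster")
    xs, ys = field_.pixel_centers()
    i0 = max(int((y - r - field_.origin[1]) / field_.pixel_size) - 1, 0)
    i1 = int((y + r - field_.origin[1]) / field_.pixel_size) + 2
    j0 = max(int((x - r - field_.origin[0]) / field_.pixel_size) - 1, 0)
    j1 = int((x + r - field_.origin[0]) / field_.pixel_size) + 2
    sub = field_.values[i0:i1, j0:j1]
    subm = field_.mask[i0:i1, j0:j1]
    XX, YY = np.meshgrid(xs[j0:j1], ys[i0:i1])
    inside = (XX - x) ** 2 + (YY - y) ** 2 <= r**2
    sel = inside & subm
    if not np.any(sel):
        raise NoDataError(f"no valid pixels in the interaction disk at ({x:.2f}, {y:.2f})")
    return float(sub[sel].mean())


def filter_indents(sites: list[IndentSite]) -> tuple[list[IndentSite], dict[str, int]]:
    """Retain quality='ok' sites; return (retained, rejection counts by reason)."""
    retained = [s for s in sites if s.quality == "ok"]
    log = Counter(s.quality for s in sites if s.quality != "ok")
    return retained, dict(log)


def extract_covariates(
    sites: list[IndentSite],
    phi_field: ScalarField,
    theta_field: ScalarField,
    transforms: dict[str, RigidTransform] | None = None,
    zone: InteractionZone | None = None,
) -> list[IndentSite]:
    """Fill phi_avg/theta_avg by disk averaging in each registered field.

    ``transforms`` maps modality name ('phi', 'theta') to the rigid transform
    from the indent (light-microscope) frame into that field's frame; missing
    entries default to identity. Sites whose disk has no valid data are
    flagged ``near_pore`` rather than dropped.
    """
    transforms = transforms or {}
    zone = zone or InteractionZone()
    t_phi = transforms.get("phi", RigidTransform())
    t_theta = transforms.get("theta", RigidTransform())
    out = []
    for s in sites:
        s = replace(s) if hasattr(s, "__dataclass_fields__") else s
        try:
            px, py = t_phi.apply(np.array([s.x, s.y]))
            s.phi_avg = disk_average(phi_field, float(px), float(py), zone)
            tx, ty = t_theta.apply(np.array([s.x, s.y]))
            s.theta_avg = disk_average(theta_field, float(tx), float(ty), zone)
        except NoDataError:
            s.quality = "near_pore"
            s.phi_avg = None
            s.theta_avg = None
        out.append(s)
    return out


_COLUMNS = [
    "id", "pattern", "x_um", "y_um", "E_meas_GPa", "region", "quality",
    "phi_avg", "theta_avg_deg", "E_pred_GPa", "E_pred0_GPa",
]


def sites_to_dataframe(sites: list[IndentSite]) -> pd.DataFrame:
    rows = [
        (s.id, s.pattern, s.x, s.y, s.E_meas, s.region, s.quality,
         s.phi_avg, s.theta_avg, s.E_pred, s.E_pred0)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def sites_from_dataframe(df: pd.DataFrame) -> list[IndentSite]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        IndentSite(
            id=int(r["id"]), x=float(r["x_um"]), y=float(r["y_um"]),
            E_meas=_opt(r.get("E_meas_GPa")), region=str(r["region"]),
            quality=str(r["quality"]), phi_avg=_opt(r.get("phi_avg")),
            theta_avg=_opt(r.get("theta_avg_deg")), E_pred=_opt(r.get("E_pred_GPa")),
            E_pred0=_opt(r.get("E_pred0_GPa")), pattern=int(r.get("pattern", 0)),
        )
        for _, r in df.iterrows()
    ]
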