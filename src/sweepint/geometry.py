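"""Experiment models and rotation-method diffraction geometry.

Conventions
-----------
* Laboratory frame: right-handed Cartesian, millimetres, sample at the origin.
* The beam direction ``s0_direction`` is a unit vector pointing from the source
  towards the sample; the wave vector is ``s0 = s0_direction / wavelength`` (1/A).
* Pixels are 0-based; the centre of pixel ``(i, j)`` lies at continuous pixel
  coordinate ``(i + 0.5, j + 0.5)``.  Bounding boxes are half-open.
* Rotation by phi about the goniometer axis ``m`` is right-handed; mapping an
  observation back to the phi = 0 crystal setting applies ``R(-phi)``.
* Angles are degrees at every public interface, radians internally.
* The B matrix follows the standard reciprocal-basis construction with the
  real-space a axis along lab x (PDB orthogonalization convention, via gemmi);
  columns of ``UB = U B`` are the reciprocal basis vectors a*, b*, c* in 1/A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Beam",
    "Panel",
    "Goniometer",
    "Scan",
    "Crystal",
    "Experiment",
    "GeometryError",
    "pixel_to_ray",
    "map_to_rlp",
    "predict_reflections",
    "two_theta",
    "rotation_about_axis",
]

EXPERIMENT_SCHEMA_VERSION = 1


class GeometryError(ValueError):
    """Invalid geometric model or out-of-range request."""


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length vector cannot be normalized")
    return v / n


def rotation_about_axis(axis: np.ndarray, phi_rad: np.ndarray) -> np.ndarray:
    """Right-handed rotation matrices about ``axis`` (Rodrigues), shape (..., 3, 3)."""
    a = _unit(axis)
    phi = np.asarray(phi_rad, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    ax, ay, az = a
    K = np.array([[0, -az, ay], [az, 0, -ax], [-ay, ax, 0]])
    eye = np.eye(3)
    outer = np.outer(a, a)
    # R = c I + s K + (1-c) aa^T, broadcast over phi
    return (
        c[..., None, None] * eye
        + s[..., None, None] * K
        + (1.0 - c)[..., None, None] * outer
    )


@dataclass
class Beam:
    """Monochromatic beam model: direction, wavelength and polarization."""

    s0_direction: np.ndarray
    wavelength: float
    polarization_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0])
    )
    polarization_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.s0_direction = np.asarray(self.s0_direction, dtype=float)
        self.polarization_normal = np.asarray(self.polarization_normal, dtype=float)
        if self.wavelength <= 0:
            raise GeometryError("wavelength must be positive")
        if abs(np.linalg.norm(self.s0_direction) - 1.0) > 1e-10:
            raise GeometryError("s0_direction must be a unit vector")
        if abs(np.linalg.norm(self.polarization_normal) - 1.0) > 1e-8:
            raise GeometryError("polarization_normal must be a unit vector")
        if abs(float(self.polarization_normal @ self.s0_direction)) > 1e-8:
            raise GeometryError("polarization_normal must be orthogonal to the beam")
        if not 0.0 <= self.polarization_fraction <= 1.0:
            raise GeometryError("polarization_fraction must lie in [0, 1]")

    @property
    def s0(self) -> np.ndarray:
        """Incident wave vector in 1/A (|s0| = 1/wavelength)."""
        return self.s0_direction / self.wavelength


@dataclass
class Panel:
    """Flat detector panel: an abstract plane with a pixel raster.

    ``origin`` is the lab position (mm) of the outer corner of pixel (0, 0);
    ``fast_axis``/``slow_axis`` are unit vectors along the two raster
    directions.  ``thickness`` (mm) and ``material`` describe the sensor for
    the oblique-incidence correction; ``gain`` is counts per photon.
    """

    origin: np.ndarray
    fast_axis: np.ndarray
    slow_axis: np.ndarray
    pixel_size: tuple[float, float]
    image_size: tuple[int, int]
    thickness: float = 0.32
    material: str = "Si"
    gain: float = 1.0
    trusted_range: tuple[float, float] = (0.0, 2**31 - 1)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.fast_axis = _unit(self.fast_axis)
        self.slow_axis = _unit(self.slow_axis)
        if abs(float(self.fast_axis @ self.slow_axis)) > 1e-8:
            raise GeometryError("fast_axis and slow_axis must be orthogonal")
        if min(self.pixel_size) <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.thickness < 0:
            raise GeometryError("sensor thickness must be non-negative")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.fast_axis, self.slow_axis)

    def pixel_to_lab(self, fast: np.ndarray, slow: np.ndarray) -> np.ndarray:
        """Lab coordinates (mm) of continuous pixel coordinates (fast, slow)."""
        fast = np.asarray(fast, dtype=float)
        slow = np.asarray(slow, dtype=float)
        return (
            self.origin
            + fast[..., None] * self.pixel_size[0] * self.fast_axis
            + slow[..., None] * self.pixel_size[1] * self.slow_axis
        )

    def lab_to_pixel(self, points: np.ndarray) -> np.ndarray:
        """Continuous pixel coordinates of lab points assumed on the panel plane."""
        rel = np.asarray(points, dtype=float) - self.origin
        return np.stack(
            [rel @ self.fast_axis / self.pixel_size[0],
             rel @ self.slow_axis / self.pixel_size[1]],
            axis=-1,
        )

    def intersect_rays(self, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Intersect unit rays from the sample with the panel plane.

        Returns (pixel_xy, hit) where ``pixel_xy[..., 0]`` is the fast
        coordinate; ``hit`` is False for rays parallel to the panel, travelling
        away from it, or striking outside the raster.
        """
        d = np.asarray(directions, dtype=float)
        n = self.normal
        denom = d @ n
        dist = float(self.origin @ n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 1e-12, dist / denom, np.nan)
        pts = d * t[..., None]
        px = self.lab_to_pixel(pts)
        hit = (
            np.isfinite(t)
            & (t > 0)
            & (px[..., 0] >= 0)
            & (px[..., 0] < self.image_size[0])
            & (px[..., 1] >= 0)
            & (px[..., 1] < self.image_size[1])
        )
        return px, hit


@dataclass
class Goniometer:
    """Single fixed rotation axis."""

    rotation_axis: np.ndarray

    def __post_init__(self) -> None:
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        if abs(np.linalg.norm(self.rotation_axis) - 1.0) > 1e-10:
            raise GeometryError("rotation_axis must be a unit vector")


@dataclass
class Scan:
    """Contiguous rotation scan: images ``image_range[0]..image_range[1]``
    (0-based inclusive), image z covering phi in
    ``[phi_start + (z - first) dphi, phi_start + (z - first + 1) dphi)``."""

    image_range: tuple[int, int]
    phi_start: float
    oscillation: float

    def __post_init__(self) -> None:
        if self.oscillation <= 0:
            raise GeometryError("oscillation must be positive")
        if self.image_range[1] < self.image_range[0]:
            raise GeometryError("empty image range")

    @property
    def n_images(self) -> int:
        return self.image_range[1] - self.image_range[0] + 1

    @property
    def phi_end(self) -> float:
        return self.phi_start + self.n_images * self.oscillation

    def image_centre_phi(self, z: np.ndarray) -> np.ndarray:
        """Centre angle (deg) of integer image index z."""
        z = np.asarray(z, dtype=float)
        return self.phi_start + (z - self.image_range[0] + 0.5) * self.oscillation

    def frame_to_phi(self, z: np.ndarray) -> np.ndarray:
        """Angle (deg) of continuous frame coordinate z (z = first maps to phi_start)."""
        z = np.asarray(z, dtype=float)
        return self.phi_start + (z - self.image_range[0]) * self.oscillation

    def phi_to_frame(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        return self.image_range[0] + (phi - self.phi_start) / self.oscillation


def _b_matrix(cell: Sequence[float]) -> np.ndarray:
    uc = gemmi.UnitCell(*cell)
    if uc.volume <= 0:
        raise GeometryError("degenerate unit cell")
    A = np.array(uc.orth.mat.tolist())  # columns are a, b, c (a along x)
    return np.linalg.inv(A).T  # columns are a*, b*, c*


@dataclass
class Crystal:
    """Crystal lattice: unit cell plus orientation.

    ``u`` is the orthonormal setting matrix; ``ub = u @ b`` has the reciprocal
    basis vectors as columns (1/A) in the lab frame at phi = 0.
    """

    cell: tuple[float, float, float, float, float, float]
    u: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.cell = tuple(float(x) for x in self.cell)
        self.u = np.asarray(self.u, dtype=float)
        if abs(np.linalg.det(self.u) - 1.0) > 1e-8 or not np.allclose(
            self.u @ self.u.T, np.eye(3), atol=1e-8
        ):
            raise GeometryError("U must be a proper rotation matrix")
        self.b = _b_matrix(self.cell)

    @property
    def ub(self) -> np.ndarray:
        return self.u @ self.b

    @property
    def volume(self) -> float:
        return 1.0 / abs(np.linalg.det(self.b))

    @classmethod
    def from_real_basis(cls, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> "Crystal":
        """Build from three real-space lattice vectors (A) in the lab frame."""
        M = np.column_stack([a, b, c]).astype(float)
        if abs(np.linalg.det(M)) < 1e-9:
            raise GeometryError("coplanar basis vectors")
        if np.linalg.det(M) < 0:  # enforce right-handed cell
            M[:, 2] = -M[:, 2]
        va, vb, vc = M[:, 0], M[:, 1], M[:, 2]
        la, lb, lc = (np.linalg.norm(v) for v in (va, vb, vc))
        cell = (
            la, lb, lc,
            np.degrees(np.arccos(np.clip(vb @ vc / (lb * lc), -1, 1))),
            np.degrees(np.arccos(np.clip(va @ vc / (la * lc), -1, 1))),
            np.degrees(np.arccos(np.clip(va @ vb / (la * lb), -1, 1))),
        )
        B = _b_matrix(cell)
        UB = np.linalg.inv(M).T
        U = UB @ np.linalg.inv(B)
        # project to the nearest proper rotation (polar decomposition)
        w, _, vt = np.linalg.svd(U)
        U = w @ vt
        if np.linalg.det(U) < 0:
            U = w @ np.diag([1.0, 1.0, -1.0]) @ vt
        return cls(cell=cell, u=U)

    @classmethod
    def from_ub(cls, ub: np.ndarray) -> "Crystal":
        """Build from a UB matrix (columns a*, b*, c*)."""
        A = np.linalg.inv(np.asarray(ub, dtype=float)).T  # columns a, b, c
        return cls.from_real_basis(A[:, 0], A[:, 1], A[:, 2])

    def real_basis(self) -> np.ndarray:
        """Real-space lattice vectors as columns (A), lab frame."""
        return np.linalg.inv(self.ub).T


@dataclass
class Experiment:
    """One sweep: exactly one beam, detector, goniometer and scan, with an
    optional crystal.  Models may be shared between experiments by passing the
    same object (reference identity is the sharing tag)."""

    beam: Beam
    detector: list[Panel]
    goniometer: Goniometer
    scan: Scan
    crystal: Optional[Crystal] = None

    # ---- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": EXPERIMENT_SCHEMA_VERSION,
            "beam": {
                "s0_direction": list(self.beam.s0_direction),
                "wavelength": self.beam.wavelength,
                "polarization_normal": list(self.beam.polarization_normal),
                "polarization_fraction": self.beam.polarization_fraction,
            },
            "detector": [
                {
                    "origin": list(p.origin),
                    "fast_axis": list(p.fast_axis),
                    "slow_axis": list(p.slow_axis),
                    "pixel_size": list(p.pixel_size),
                    "image_size": list(p.image_size),
                    "thickness": p.thickness,
                    "material": p.material,
                    "gain": p.gain,
                    "trusted_range": list(p.trusted_range),
                }
                for p in self.detector
            ],
            "goniometer": {"rotation_axis": list(self.goniometer.rotation_axis)},
            "scan": {
                "image_range": list(self.scan.image_range),
                "phi_start": self.scan.phi_start,
                "oscillation": self.scan.oscillation,
            },
        }
        if self.crystal is not None:
            d["crystal"] = {
                "cell": list(self.crystal.cell),
                "u": self.crystal.u.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Experiment":
        try:
            beam = Beam(
                s0_direction=d["beam"]["s0_direction"],
                wavelength=d["beam"]["wavelength"],
                polarization_normal=d["beam"].get(
                    "polarization_normal", [0.0, 1.0, 0.0]
                ),
                polarization_fraction=d["beam"].get("polarization_fraction", 0.5),
            )
            detector = [
                Panel(
                    origin=p["origin"],
                    fast_axis=p["fast_axis"],
                    slow_axis=p["slow_axis"],
                    pixel_size=tuple(p["pixel_size"]),
                    image_size=tuple(int(x) for x in p["image_size"]),
                    thickness=p.get("thickness", 0.32),
                    material=p.get("material", "Si"),
                    gain=p.get("gain", 1.0),
                    trusted_range=tuple(p.get("trusted_range", (0.0, 2**31 - 1))),
                )
                for p in d["detector"]
            ]
            goniometer = Goniometer(rotation_axis=d["goniometer"]["rotation_axis"])
            scan = Scan(
                image_range=tuple(int(x) for x in d["scan"]["image_range"]),
                phi_start=float(d["scan"]["phi_start"]),
                oscillation=float(d["scan"]["oscillation"]),
            )
        except KeyError as exc:
            raise GeometryError(f"experiment JSON missing field: {exc}") from exc
        crystal = None
        if "crystal" in d and d["crystal"] is not None:
            crystal = Crystal(cell=tuple(d["crystal"]["cell"]), u=d["crystal"]["u"])
        return cls(beam, detector, goniometer, scan, crystal)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Experiment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---- core ray / reciprocal-space operations ---------------------------------


def pixel_to_ray(
    panel: Panel, px: tuple[float, float], beam: Beam
) -> tuple[np.ndarray, np.ndarray]:
    """Unit diffracted-ray direction and scattered wave vector s1 (1/A) for the
    centre of integer pixel ``px = (fast, slow)``.

    ``|s1| = 1/wavelength`` exactly (elastic scattering).
    """
    f, s = float(px[0]), float(px[1])
    if not (0 <= f < panel.image_size[0] and 0 <= s < panel.image_size[1]):
        raise GeometryError(
            f"pixel {px} outside panel raster {panel.image_size}"
        )
    lab = panel.pixel_to_lab(np.array(f + 0.5), np.array(s + 0.5))
    ray = _unit(lab)
    return ray, ray / beam.wavelength


def map_to_rlp(centroids: np.ndarray, experiment: Experiment, panel_id: int = 0) -> np.ndarray:
    """Map observed centroids (x px, y px, phi deg) to reciprocal-lattice
    points r = R(-phi) (s1 - s0) in 1/A.  Accepts shape (3,) or (N, 3)."""
    c = np.atleast_2d(np.asarray(centroids, dtype=float))
    panel = experiment.detector[panel_id]
    beam = experiment.beam
    lab = panel.pixel_to_lab(c[:, 0], c[:, 1])
    norms = np.linalg.norm(lab, axis=1)
    s1 = lab / norms[:, None] / beam.wavelength
    diff = s1 - beam.s0
    R = rotation_about_axis(
        experiment.goniometer.rotation_axis, -np.radians(c[:, 2])
    )
    out = np.einsum("nij,nj->ni", R, diff)
    return out[0] if np.asarray(centroids).ndim == 1 else out


def two_theta(beam: Beam, r: np.ndarray = None, s1: np.ndarray = None) -> np.ndarray:
    """Scattering angle 2-theta in degrees, in [0, 180].

    Provide either reciprocal-lattice points ``r`` (uses 2 asin(|r| lambda / 2))
    or scattered wave vectors ``s1`` (angle between s1 and s0).
    """
    if (r is None) == (s1 is None):
        raise ValueError("provide exactly one of r or s1")
    scalar_input = np.asarray(r if r is not None else s1).ndim == 1
    if r is not None:
        r = np.asarray(r, dtype=float)
        mag = np.linalg.norm(np.atleast_2d(r), axis=1)
        x = mag * beam.wavelength / 2.0
        if np.any(x > 1.0 + 1e-12):
            raise GeometryError("|r| * lambda / 2 exceeds 1: beyond back-scattering")
        tt = np.degrees(2.0 * np.arcsin(np.clip(x, 0.0, 1.0)))
    else:
        s1 = np.atleast_2d(np.asarray(s1, dtype=float))
        cosang = (s1 / np.linalg.norm(s1, axis=1)[:, None]) @ beam.s0_direction
        tt = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(tt[0]) if scalar_input else tt


def _hkl_sphere(crystal: Crystal, dmin: float) -> np.ndarray:
    """All Miller indices with d >= dmin (excluding 000)."""
    # bound each index by the real-cell edge over dmin
    a, b, c = crystal.cell[:3]
    hmax = int(np.ceil(a / dmin)) + 1
    kmax = int(np.ceil(b / dmin)) + 1
    lmax = int(np.ceil(c / dmin)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = 1.0 / np.maximum(np.linalg.norm(hkl @ crystal.b.T, axis=1), 1e-12)
    return hkl[d >= dmin]


def predict_reflections(
    experiment: Experiment, dmin: float, hkl: np.ndarray = None
) -> pd.DataFrame:
    """Predict rotation-method Ewald-sphere crossings for every hkl with
    d >= dmin within the scan, with detector impact positions.

    The crossing condition |R(phi) UB h + s0| = 1/lambda reduces to
    A + B cos(phi) + C sin(phi) = 0 per reflection, solved in closed form;
    up to two crossings per 360 deg.  Reflections in the blind region (rlp
    nearly parallel to the rotation axis) or missing all panels are excluded.

    Returns a reflection table with columns h,k,l, panel, x,y (px), phi (deg),
    z (continuous frame), d, zeta, s1x..s1z.
    """
    if experiment.crystal is None:
        raise GeometryError("prediction requires a crystal model")
    if dmin is not None and dmin <= 0:
        raise GeometryError("dmin must be positive")
    crystal, beam = experiment.crystal, experiment.beam
    gonio, scan = experiment.goniometer, experiment.scan
    if hkl is None:
        hkl = _hkl_sphere(crystal, dmin)
    hkl = np.asarray(hkl, dtype=int)
    r0 = hkl @ crystal.ub.T  # (N, 3) rlp at phi = 0
    m = _unit(gonio.rotation_axis)
    s0 = beam.s0

    r_par = (r0 @ m)[:, None] * m
    r_perp = r0 - r_par
    t2v = np.cross(np.broadcast_to(m, r_perp.shape), r_perp)
    A = 0.5 * np.einsum("ni,ni->n", r0, r0) + r_par @ s0
    B = r_perp @ s0
    C = t2v @ s0
    rho = np.hypot(B, C)

    with np.errstate(divide="ignore", invalid="ignore"):
        cosarg = -A / rho
    ok = rho > 1e-12  # otherwise blind region (rlp parallel to axis)
    ok &= np.abs(cosarg) <= 1.0  # otherwise never crosses the sphere
    phi0 = np.arctan2(C, B)
    dphi = np.arccos(np.clip(cosarg, -1.0, 1.0))

    rows = []
    phi_lo, phi_hi = scan.phi_start, scan.phi_end
    for sign in (+1.0, -1.0):
        phi = np.degrees(phi0 + sign * dphi)
        # bring each solution into [phi_lo, phi_lo + 360), then enumerate turns
        phi = phi_lo + np.mod(phi - phi_lo, 360.0)
        n_turns = int(np.ceil((phi_hi - phi_lo) / 360.0))
        for turn in range(max(n_turns, 1)):
            p = phi + 360.0 * turn
            sel = ok & (p >= phi_lo) & (p < phi_hi)
            if sign > 0:
                sel &= dphi > 1e-12  # avoid duplicating tangential solutions
            if not np.any(sel):
                continue
            idx = np.nonzero(sel)[0]
            R = rotation_about_axis(m, np.radians(p[idx]))
            s1 = np.einsum("nij,nj->ni", R, r0[idx]) + s0
            ray = s1 * beam.wavelength  # unit vectors
            for panel_id, panel in enumerate(experiment.detector):
                px, hit = panel.intersect_rays(ray)
                if not np.any(hit):
                    continue
                j = np.nonzero(hit)[0]
                e1 = np.cross(s1[j], np.broadcast_to(s0, s1[j].shape))
                e1 /= np.linalg.norm(e1, axis=1)[:, None]
                zeta = e1 @ m
                rows.append(
                    pd.DataFrame(
                        {
                            "h": hkl[idx[j], 0],
                            "k": hkl[idx[j], 1],
                            "l": hkl[idx[j], 2],
                            "panel": panel_id,
                            "x": px[j, 0],
                            "y": px[j, 1],
                            "phi": p[idx[j]],
                            "z": scan.phi_to_frame(p[idx[j]]),
                            "d": 1.0 / np.linalg.norm(r0[idx[j]], axis=1),
                            "zeta": zeta,
                            "s1x": s1[j, 0],
                            "s1y": s1[j, 1],
                            "s1z": s1[j, 2],
                        }
                    )
                )
                # first panel hit wins; mask those rays out for later panels
                ray = ray.copy()
                ray[j] = 0.0
    if not rows:
        cols = ["h", "k", "l", "panel", "x", "y", "phi", "z", "d", "zeta",
                "s1x", "s1y", "s1z"]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["z", "h", "k", "l"], kind="stable").reset_index(drop=True)
    return out
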