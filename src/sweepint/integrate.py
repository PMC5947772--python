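"""Background estimation, summation and reciprocal-space profile fitting.

The reflection profile is modelled as a 3D Gaussian in a local reciprocal
coordinate frame attached to each reflection:

    e1 = s1 x s0 / |s1 x s0|      (perpendicular to the diffraction plane)
    e2 = s1 x e1 / |s1 x e1|      (in-plane, perpendicular to s1)
    e3 = (s1 + s0) / |s1 + s0|

with coordinates eps1, eps2 the angular offsets of an observed ray about s1
along e1, e2 (degrees) and eps3 = zeta (phi - phi_c), zeta = m . e1, the
Lorentz-scaled rotation offset.  Two widths describe the profile: sigma_d
(extent on the detector face, per axis) and sigma_m (extent over rotation).

Shoebox pixel counts are resampled onto a fixed odd grid over
+/- n_sigma (sigma_d, sigma_d, sigma_m) by mapping each pixel's corners to
(eps1, eps2) and distributing its counts over grid cells in proportion to
polygon-overlap areas (Sutherland-Hodgman clipping); the rotation axis uses
the analytic Gaussian mass fraction per frame.  Intensity is then either the
background-subtracted foreground sum (with Poisson error propagation after
Leslie 1999) or the fitted scale of an empirical reference profile, which is
the better estimator for weak reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .geometry import Experiment, GeometryError

__all__ = [
    "ProfileModel",
    "Shoebox",
    "GridProfile",
    "ReferenceLocator",
    "MASK_VALID",
    "MASK_FOREGROUND",
    "MASK_BACKGROUND",
    "MASK_OVERLAP",
    "estimate_profile_params",
    "extract_shoeboxes",
    "estimate_background",
    "integrate_summation",
    "polygon_clip",
    "polygon_area",
    "kabsch_transform",
    "build_reference_profiles",
    "fit_profile",
    "block_schedule",
    "integrate_reflections",
]

MASK_VALID = 1
MASK_FOREGROUND = 2
MASK_BACKGROUND = 4
MASK_OVERLAP = 8


@dataclass
class ProfileModel:
    """Gaussian reflection-profile widths, in degrees."""

    sigma_d: float
    sigma_m: float
    n_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_m <= 0:
            raise ValueError("profile widths must be positive")


@dataclass
class Shoebox:
    """Per-reflection pixel block with bit-coded masks.

    ``bbox`` is half-open (x0, x1, y0, y1, z0, z1) in pixels/frames; ``data``
    has shape (z1-z0, y1-y0, x1-x0).
    """

    bbox: tuple[int, int, int, int, int, int]
    data: np.ndarray
    mask: np.ndarray
    panel: int = 0
    partial: bool = False
    # prediction this shoebox belongs to
    hkl: tuple[int, int, int] = (0, 0, 0)
    xcal: float = 0.0
    ycal: float = 0.0
    phical: float = 0.0
    zcal: float = 0.0
    s1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    zeta: float = 0.0

    def counts(self, code: int) -> int:
        return int(np.count_nonzero(self.mask & code))


@dataclass
class GridProfile:
    """Counts resampled onto the (eps1, eps2, eps3) grid.

    ``values`` is indexed [eps3, eps2, eps1]; ``clipped`` is the mass that
    fell outside the grid.
    """

    values: np.ndarray
    background: np.ndarray
    clipped: float = 0.0


class IntegrationError(RuntimeError):
    pass


# ---- profile-parameter estimation -------------------------------------------


def _kabsch_frame(s1: np.ndarray, s0: np.ndarray, m: np.ndarray):
    e1 = np.cross(s1, s0)
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise GeometryError("reflection on the incident beam axis")
    e1 /= n1
    e2 = np.cross(s1, e1)
    e2 /= np.linalg.norm(e2)
    e3 = s1 / np.linalg.norm(s1) + s0 / np.linalg.norm(s0)
    e3 /= np.linalg.norm(e3)
    zeta = float(m @ e1)
    return e1, e2, e3, zeta


def estimate_profile_params(
    table: pd.DataFrame,
    pixel_groups: list,
    experiment: Experiment,
    min_spots: int = 20,
    n_sigma: float = 3.0,
    images: Optional[np.ndarray] = None,
    expand_px: int = 4,
    expand_frames: int = 2,
) -> ProfileModel:
    """Estimate (sigma_d, sigma_m) from indexed strong spots.

    For each spot, sigma_d^2 is the per-axis intensity-weighted variance of
    the angular offsets of its pixel rays from the centroid ray (the isotropic
    2D variance halved), and sigma_m^2 the intensity-weighted variance of the
    Lorentz-scaled rotation offsets zeta (phi - phi_c); both are averaged over
    spots (zeta applied per spot).

    When ``images`` is given, each spot's pixel block is expanded by
    ``expand_px`` pixels and ``expand_frames`` frames beyond its strong-pixel
    bounding box and a local background (median over the expansion shell) is
    subtracted, because the thresholded footprint alone truncates the profile
    tails and biases the widths low.
    """
    if "indexed" in table:
        sel = table["indexed"].fillna(False).to_numpy(bool)
    else:
        sel = np.ones(len(table), dtype=bool)
    idx = np.nonzero(sel)[0]
    if len(idx) < min_spots:
        raise IntegrationError(
            f"need at least {min_spots} indexed strong spots, got {len(idx)};"
            " collect more images or lower the spot-finding thresholds"
        )
    beam = experiment.beam
    panel = experiment.detector[0]
    scan = experiment.scan
    m = experiment.goniometer.rotation_axis
    s0 = beam.s0
    nf, ns = panel.image_size
    first = scan.image_range[0]
    n_img = scan.n_images
    var_d, var_m = [], []
    for i in idx:
        g = pixel_groups[i]
        z, y, x, c = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
        if images is not None:
            # expanded, background-subtracted pixel block
            x0 = max(int(x.min()) - expand_px, 0)
            x1 = min(int(x.max()) + 1 + expand_px, nf)
            y0 = max(int(y.min()) - expand_px, 0)
            y1 = min(int(y.max()) + 1 + expand_px, ns)
            z0 = max(int(z.min()) - expand_frames, first)
            z1 = min(int(z.max()) + 1 + expand_frames, first + n_img)
            block = images[z0 - first : z1 - first, y0:y1, x0:x1].astype(float)
            shell = np.ones(block.shape, dtype=bool)
            shell[
                int(z.min()) - z0 : int(z.max()) + 1 - z0,
                int(y.min()) - y0 : int(y.max()) + 1 - y0,
                int(x.min()) - x0 : int(x.max()) + 1 - x0,
            ] = False
            bg = float(np.mean(block[shell])) if shell.any() else 0.0
            w3 = np.clip(block - bg, 0.0, None)
            # suppress pure-noise weight far from the peak: pixels compatible
            # with background at ~3 Poisson sigma carry no profile information
            w3[block < bg + 3.0 * math.sqrt(bg + 0.5)] = 0.0
            zz, yy, xx = np.meshgrid(
                np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1),
                indexing="ij",
            )
            z, y, x = zz.ravel().astype(float), yy.ravel().astype(float), xx.ravel().astype(float)
            c = w3.ravel()
        total = c.sum()
        if total <= 0:
            continue
        row = table.iloc[i]
        lab_c = panel.pixel_to_lab(np.asarray(row["x"]), np.asarray(row["y"]))
        s1_c = lab_c / np.linalg.norm(lab_c) / beam.wavelength
        try:
            e1, e2, _, zeta = _kabsch_frame(s1_c, s0, m)
        except GeometryError:
            continue
        lab = panel.pixel_to_lab(x + 0.5, y + 0.5)
        rays = lab / np.linalg.norm(lab, axis=1)[:, None]
        ray_c = s1_c * beam.wavelength
        eps1 = np.degrees((rays - ray_c) @ e1)
        eps2 = np.degrees((rays - ray_c) @ e2)
        w = c / total
        v2d = w @ (eps1 - w @ eps1) ** 2 + w @ (eps2 - w @ eps2) ** 2
        # Sheppard's correction: counts are lumped at pixel centres, which
        # inflates the variance by (pixel subtense)^2 / 12 per axis
        r_mm = float(np.linalg.norm(lab_c))
        cos_inc = abs(float(lab_c / r_mm @ panel.normal))
        subtense = np.degrees(
            np.array(panel.pixel_size) * cos_inc / r_mm
        )
        v2d = max(v2d - (subtense @ subtense) / 12.0, 1e-12)
        var_d.append(v2d / 2.0)
        phi = scan.image_centre_phi(z)
        eps3 = zeta * (phi - row["phi"])
        v3 = w @ (eps3 - w @ eps3) ** 2
        v3 = max(v3 - (zeta * scan.oscillation) ** 2 / 12.0, 1e-12)
        var_m.append(v3)
    if len(var_d) < min_spots:
        raise IntegrationError("too few usable spots for profile estimation")
    sigma_d = float(np.sqrt(np.mean(var_d)))
    sigma_m = float(np.sqrt(np.mean(var_m)))
    return ProfileModel(sigma_d=max(sigma_d, 1e-6), sigma_m=max(sigma_m, 1e-6),
                        n_sigma=n_sigma)


# ---- shoebox extraction -----------------------------------------------------


def _pixel_sigma_px(panel, x, y, sigma_deg):
    lab = panel.pixel_to_lab(np.asarray(x), np.asarray(y))
    r = float(np.linalg.norm(lab))
    cos_inc = abs(float(lab / r @ panel.normal))
    s = math.radians(sigma_deg) * r / cos_inc
    return s / panel.pixel_size[0], s / panel.pixel_size[1]


def extract_shoeboxes(
    predictions: pd.DataFrame,
    images: np.ndarray,
    experiment: Experiment,
    profile: ProfileModel,
    valid_mask: Optional[np.ndarray] = None,
) -> tuple[list[Shoebox], int]:
    """Cut a pixel block around every prediction and classify pixels.

    The bounding box spans the projection of +/- n_sigma sigma_d about the
    predicted ray (plus a 1-pixel margin) and +/- n_sigma sigma_m / |zeta| in
    rotation.  Foreground: |eps1|, |eps2| <= n_sigma sigma_d and
    |eps3| <= n_sigma sigma_m; background: remaining valid pixels.
    Foreground pixels claimed by two reflections are flagged
    ``MASK_OVERLAP`` and dropped from both.  Returns (shoeboxes, n_dropped).
    """
    panel = experiment.detector[0]
    beam = experiment.beam
    scan = experiment.scan
    m = experiment.goniometer.rotation_axis
    s0 = beam.s0
    nf, ns = panel.image_size
    n_img = scan.n_images
    first = scan.image_range[0]
    ns_sig = profile.n_sigma

    boxes: list[Shoebox] = []
    n_dropped = 0
    fg_claims = np.zeros(images.shape, dtype=np.uint8)

    for row in predictions.itertuples(index=False):
        sx, sy = _pixel_sigma_px(panel, row.x, row.y, profile.sigma_d)
        if abs(row.zeta) < 1e-6:
            n_dropped += 1
            continue
        sz = profile.sigma_m / (abs(row.zeta) * scan.oscillation)
        x0 = int(np.floor(row.x - ns_sig * sx - 1))
        x1 = int(np.ceil(row.x + ns_sig * sx + 1))
        y0 = int(np.floor(row.y - ns_sig * sy - 1))
        y1 = int(np.ceil(row.y + ns_sig * sy + 1))
        z0 = int(np.floor(row.z - ns_sig * sz))
        z1 = int(np.ceil(row.z + ns_sig * sz))
        partial = x0 < 0 or y0 < 0 or x1 > nf or y1 > ns or z0 < first or z1 > first + n_img
        cx0, cx1 = max(x0, 0), min(x1, nf)
        cy0, cy1 = max(y0, 0), min(y1, ns)
        cz0, cz1 = max(z0, first), min(z1, first + n_img)
        if cx1 <= cx0 or cy1 <= cy0 or cz1 <= cz0:
            n_dropped += 1
            continue
        data = images[cz0 - first : cz1 - first, cy0:cy1, cx0:cx1].astype(np.float64)
        mask = np.full(data.shape, MASK_VALID, dtype=np.uint8)
        if valid_mask is not None:
            mask[~valid_mask[cy0:cy1, cx0:cx1][None, :, :].repeat(data.shape[0], 0)] = 0

        s1_c = np.array([row.s1x, row.s1y, row.s1z])
        e1, e2, _, _ = _kabsch_frame(s1_c, s0, m)
        ray_c = s1_c * beam.wavelength

        xs = np.arange(cx0, cx1) + 0.5
        ys = np.arange(cy0, cy1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        lab = panel.pixel_to_lab(gx.ravel(), gy.ravel())
        rays = lab / np.linalg.norm(lab, axis=1)[:, None]
        eps1 = np.degrees((rays - ray_c) @ e1).reshape(gy.shape)
        eps2 = np.degrees((rays - ray_c) @ e2).reshape(gy.shape)
        in_d = (np.abs(eps1) <= ns_sig * profile.sigma_d) & (
            np.abs(eps2) <= ns_sig * profile.sigma_d
        )
        # a frame is foreground when its rotation interval, mapped to eps3,
        # overlaps the +/- n_sigma sigma_m rocking window (centre distance
        # would wrongly reject frames holding most of a finely peaked curve)
        phi_lo = scan.frame_to_phi(np.arange(cz0, cz1, dtype=float))
        phi_hi = scan.frame_to_phi(np.arange(cz0 + 1, cz1 + 1, dtype=float))
        a3 = row.zeta * (phi_lo - row.phi)
        b3 = row.zeta * (phi_hi - row.phi)
        e3_lo, e3_hi = np.minimum(a3, b3), np.maximum(a3, b3)
        in_m = (e3_hi >= -ns_sig * profile.sigma_m) & (e3_lo <= ns_sig * profile.sigma_m)
        fg = in_d[None, :, :] & in_m[:, None, None]
        mask[fg & (mask > 0)] |= MASK_FOREGROUND
        mask[(~fg) & (mask > 0)] |= MASK_BACKGROUND
        fg_claims[cz0 - first : cz1 - first, cy0:cy1, cx0:cx1] += fg.astype(np.uint8)

        boxes.append(
            Shoebox(
                bbox=(cx0, cx1, cy0, cy1, cz0, cz1),
                data=data,
                mask=mask,
                panel=int(row.panel),
                partial=bool(partial),
                hkl=(int(row.h), int(row.k), int(row.l)),
                xcal=float(row.x),
                ycal=float(row.y),
                phical=float(row.phi),
                zcal=float(row.z),
                s1=s1_c,
                zeta=float(row.zeta),
            )
        )

    # reject foreground voxels claimed by more than one reflection
    overlapped = fg_claims > 1
    if overlapped.any():
        for box in boxes:
            x0, x1, y0, y1, z0, z1 = box.bbox
            ov = overlapped[z0 - first : z1 - first, y0:y1, x0:x1]
            shared = ov & ((box.mask & MASK_FOREGROUND) > 0)
            box.mask[shared] = (
                box.mask[shared] & np.uint8(0xFF ^ MASK_FOREGROUND)
            ) | np.uint8(MASK_OVERLAP)
    return boxes, n_dropped


# ---- background estimation --------------------------------------------------


def _huber_psi(r: np.ndarray, c: float) -> np.ndarray:
    return np.clip(r, -c, c)


def _expected_psi(mu: float, c: float) -> float:
    """E[psi_c((X - mu)/sqrt(mu))] for X ~ Poisson(mu): the Fisher-consistency
    correction of the robust quasi-likelihood score."""
    if mu <= 0:
        return 0.0
    hi = int(mu + 10.0 * math.sqrt(mu) + 20)
    k = np.arange(0, hi + 1)
    pmf = sstats.poisson.pmf(k, mu)
    r = (k - mu) / math.sqrt(mu)
    return float(_huber_psi(r, c) @ pmf)


def estimate_background(
    shoebox: Shoebox,
    method: str = "glm",
    huber_c: float = 1.345,
    max_iterations: int = 50,
    tol: float = 1e-6,
    min_pixels: int = 10,
):
    """Estimate the background level under the peak from background pixels.

    Methods:

    ``glm``
        Robust Poisson regression for a constant level: solves the
        Huber-scored quasi-likelihood equation
        ``sum_i psi_c((c_i - mu)/sqrt(mu)) - n E_mu[psi_c] = 0``
        (the expectation term makes the estimator consistent for Poisson data
        even below one count per pixel), initialized at the background median
        floored at a small positive value.  Falls back to the median on
        non-convergence.
    ``mean``
        Mean after iterated +/-3 sigma rejection (normal-theory outlier
        handling, appropriate for pedestal-subtracted CCD data).
    ``plane``
        Least-squares inclined plane with the same rejection, evaluated per
        pixel.

    Returns ``(levels, variance, info)`` with ``levels`` broadcast over the
    shoebox shape and ``variance`` the variance of the estimated level.
    """
    bg_sel = (shoebox.mask & MASK_BACKGROUND) > 0
    c = shoebox.data[bg_sel]
    n = c.size
    if n < min_pixels:
        raise IntegrationError(f"only {n} background pixels, need {min_pixels}")
    info = {"method": method, "n_background": int(n), "converged": True}
    shape = shoebox.data.shape

    if method == "glm":
        if np.all(c == c.flat[0]):
            level = float(c.flat[0])
            return np.full(shape, level), max(level, 0.0) / n, info
        mu = max(float(np.median(c)), 0.05)
        # gross-outlier cut: a monotone bounded score still leaves a bias
        # proportional to the contamination fraction, so pixels tens of
        # Poisson sigmas from the median (zinger scale, never genuine
        # background) are excluded outright; the influence function is
        # thereby redescending at gross outliers while the Huber score
        # handles the moderate tail.
        gross = np.abs(c - mu) / math.sqrt(mu) > 30.0
        if gross.any():
            c = c[~gross]
            info["n_gross_outliers"] = int(gross.sum())
            if c.size < min_pixels:
                raise IntegrationError("background dominated by gross outliers")

        def score(m_):
            r = (c - m_) / math.sqrt(m_)
            return float(np.mean(_huber_psi(r, huber_c))) - _expected_psi(m_, huber_c)

        lo = 1e-4
        hi = max(float(np.mean(c)), mu) + 5.0 * math.sqrt(max(float(np.mean(c)), 1.0))
        f_lo, f_hi = score(lo), score(hi)
        level = None
        if f_lo > 0 >= f_hi or f_lo >= 0 > f_hi:
            from scipy.optimize import brentq

            level = float(brentq(score, lo, hi, xtol=tol, maxiter=max_iterations))
        if level is None:
            info["converged"] = False
            level = float(np.median(c))
        return np.full(shape, level), max(level, 0.0) / n, info

    if method == "mean":
        sel = np.ones(n, dtype=bool)
        for _ in range(10):
            m_, s_ = float(c[sel].mean()), float(c[sel].std())
            if s_ <= 1e-9 * max(1.0, abs(m_)):  # numerically constant
                break
            new = np.abs(c - m_) <= 3.0 * s_
            if new.sum() == sel.sum():
                break
            sel = new
        level = float(c[sel].mean())
        return np.full(shape, level), max(level, 0.0) / max(int(sel.sum()), 1), info

    if method == "plane":
        zz, yy, xx = np.nonzero(bg_sel)
        A = np.column_stack([np.ones(n), xx.astype(float), yy.astype(float)])
        sel = np.ones(n, dtype=bool)
        coef = None
        for _ in range(10):
            coef, *_ = np.linalg.lstsq(A[sel], c[sel], rcond=None)
            resid = c - A @ coef
            s_ = float(resid[sel].std())
            if s_ <= 1e-9 * max(1.0, abs(float(c[sel].mean()))):
                break
            new = np.abs(resid) <= 3.0 * s_
            if new.sum() == sel.sum():
                break
            sel = new
        gz, gy, gx = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
            indexing="ij",
        )
        levels = coef[0] + coef[1] * gx + coef[2] * gy
        resid = c[sel] - (A @ coef)[sel]
        var = float(resid @ resid) / max(sel.sum() - 3, 1) / max(sel.sum(), 1)
        return levels, var, info

    raise ValueError(f"unknown background method {method!r}")


# ---- summation integration --------------------------------------------------


def integrate_summation(shoebox: Shoebox, background: np.ndarray):
    """Background-subtracted foreground sum with Poisson error propagation.

    var(I) = sum_fg c_i + (m^2 / n) b_bar  (Leslie 1999), with m foreground
    and n background pixels and b_bar the background level.  Also returns the
    per-frame partial sums.  A shoebox with no foreground pixels yields a
    null intensity with ``flag = "no_foreground"``.
    """
    fg = (shoebox.mask & MASK_FOREGROUND) > 0
    bg = (shoebox.mask & MASK_BACKGROUND) > 0
    m = int(fg.sum())
    n = int(bg.sum())
    if m == 0:
        return {"intensity": np.nan, "variance": np.nan,
                "partials": {}, "flag": "no_foreground"}
    background = np.broadcast_to(background, shoebox.data.shape)
    i_sum = float((shoebox.data[fg] - background[fg]).sum())
    b_bar = float(background[fg].mean())
    raw = float(shoebox.data[fg].sum())
    var = raw + (m * m / max(n, 1)) * b_bar
    partials = {}
    z0 = shoebox.bbox[4]
    for iz in range(shoebox.data.shape[0]):
        sel = fg[iz]
        if sel.any():
            partials[z0 + iz] = float((shoebox.data[iz][sel] - background[iz][sel]).sum())
    return {"intensity": i_sum, "variance": var, "partials": partials, "flag": ""}


# ---- polygon clipping -------------------------------------------------------


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a polygon given as (n, 2) vertices; 0 if degenerate."""
    p = np.asarray(poly, dtype=float)
    if len(p) < 3:
        return 0.0
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(x @ np.roll(y, -1) - y @ np.roll(x, -1)))


def polygon_clip(subject: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex ``subject`` polygon by a convex
    ``clip`` polygon (both counter-clockwise).  Returns the (possibly empty)
    intersection polygon."""
    subject = [tuple(p) for p in np.asarray(subject, dtype=float)]
    clip_pts = np.asarray(clip, dtype=float)
    if polygon_area(clip_pts) == 0.0 or len(subject) < 3:
        return np.zeros((0, 2))
    # force counter-clockwise clip polygon
    x, y = clip_pts[:, 0], clip_pts[:, 1]
    if float(x @ np.roll(y, -1) - y @ np.roll(x, -1)) < 0:
        clip_pts = clip_pts[::-1]
    out = subject
    nc = len(clip_pts)
    for i in range(nc):
        ax, ay = clip_pts[i]
        bx, by = clip_pts[(i + 1) % nc]
        ex, ey = bx - ax, by - ay
        inp = out
        out = []
        if not inp:
            break
        for j in range(len(inp)):
            px, py = inp[j]
            qx, qy = inp[(j + 1) % len(inp)]
            p_in = ex * (py - ay) - ey * (px - ax) >= 0
            q_in = ex * (qy - ay) - ey * (qx - ax) >= 0
            if p_in:
                out.append((px, py))
            if p_in != q_in:
                den = ex * (qy - py) - ey * (qx - px)
                if den != 0:
                    t = (ey * (px - ax) - ex * (py - ay)) / den
                    out.append((px + t * (qx - px), py + t * (qy - py)))
    return np.asarray(out) if out else np.zeros((0, 2))


# ---- Kabsch transform -------------------------------------------------------


def kabsch_transform(
    shoebox: Shoebox,
    experiment: Experiment,
    profile: ProfileModel,
    background: np.ndarray,
    grid_size: int = 9,
) -> GridProfile:
    """Resample foreground counts (and background model) onto the profile grid.

    Each foreground pixel's four corners are mapped to (eps1, eps2); counts
    are distributed over grid cells in proportion to Sutherland-Hodgman
    overlap areas, and along eps3 by the analytic Gaussian mass fraction of
    each frame falling in each grid slab.  Total counts are conserved up to
    the mass clipped outside the grid, which is reported.
    """
    if grid_size % 2 == 0:
        raise ValueError("grid size must be odd")
    panel = experiment.detector[0]
    beam = experiment.beam
    scan = experiment.scan
    m = experiment.goniometer.rotation_axis
    s0 = beam.s0
    ns_sig = profile.n_sigma
    half1 = ns_sig * profile.sigma_d  # grid half-extent, eps1/eps2, degrees
    half3 = ns_sig * profile.sigma_m
    step12 = 2.0 * half1 / grid_size
    step3 = 2.0 * half3 / grid_size

    e1, e2, _, _ = _kabsch_frame(shoebox.s1, s0, m)
    ray_c = shoebox.s1 * beam.wavelength

    x0, x1, y0, y1, z0, z1 = shoebox.bbox
    # corner coordinates: (ny+1, nx+1)
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    lab = panel.pixel_to_lab(gx.ravel(), gy.ravel())
    rays = lab / np.linalg.norm(lab, axis=1)[:, None]
    ce1 = np.degrees((rays - ray_c) @ e1).reshape(gy.shape)
    ce2 = np.degrees((rays - ray_c) @ e2).reshape(gy.shape)
    # grid coordinates (cell units, 0..grid_size)
    ge1 = (ce1 + half1) / step12
    ge2 = (ce2 + half1) / step12

    # eps3 mass fractions per (frame, grid slab)
    from scipy.special import ndtr

    phis_edges_lo = scan.frame_to_phi(np.arange(z0, z1, dtype=float))
    phis_edges_hi = scan.frame_to_phi(np.arange(z0 + 1, z1 + 1, dtype=float))
    zeta = shoebox.zeta
    sgn = 1.0 if zeta >= 0 else -1.0
    eps3_lo = zeta * (np.minimum(phis_edges_lo, phis_edges_hi) - shoebox.phical)
    eps3_hi = zeta * (np.maximum(phis_edges_lo, phis_edges_hi) - shoebox.phical)
    lo = np.minimum(eps3_lo, eps3_hi)
    hi = np.maximum(eps3_lo, eps3_hi)
    edges3 = -half3 + step3 * np.arange(grid_size + 1)
    sig_m = profile.sigma_m
    nz = z1 - z0
    frac3 = np.zeros((nz, grid_size))
    for iz in range(nz):
        a, b = lo[iz], hi[iz]
        denom = ndtr(b / sig_m) - ndtr(a / sig_m)
        if denom <= 1e-15:
            # frame carries negligible Gaussian mass: nearest slab
            centre = 0.5 * (a + b)
            v = int(np.clip((centre + half3) / step3, 0, grid_size - 1))
            frac3[iz, v] = 1.0
            continue
        seg_lo = np.clip(edges3[:-1], a, b)
        seg_hi = np.clip(edges3[1:], a, b)
        frac3[iz] = (ndtr(seg_hi / sig_m) - ndtr(seg_lo / sig_m)) / denom

    fg = (shoebox.mask & MASK_FOREGROUND) > 0
    data_grid = np.zeros((grid_size, grid_size, grid_size))
    bg_grid = np.zeros_like(data_grid)
    background = np.broadcast_to(background, shoebox.data.shape)
    clipped = 0.0
    total_in = 0.0

    zz, yy, xx = np.nonzero(fg)
    for iz, iy, ix in zip(zz, yy, xx):
        c = shoebox.data[iz, iy, ix]
        b = background[iz, iy, ix]
        corners = np.array(
            [
                (ge1[iy, ix], ge2[iy, ix]),
                (ge1[iy, ix + 1], ge2[iy, ix + 1]),
                (ge1[iy + 1, ix + 1], ge2[iy + 1, ix + 1]),
                (ge1[iy + 1, ix], ge2[iy + 1, ix]),
            ]
        )
        area = polygon_area(corners)
        f3 = frac3[iz]
        total_in += c
        if area <= 1e-12:
            # degenerate mapping: nearest cell
            u = int(np.clip(corners[:, 0].mean(), 0, grid_size - 1))
            v = int(np.clip(corners[:, 1].mean(), 0, grid_size - 1))
            data_grid[:, v, u] += c * f3
            bg_grid[:, v, u] += b * f3
            clipped += c * (1.0 - f3.sum())
            continue
        u0 = max(int(np.floor(corners[:, 0].min())), 0)
        u1 = min(int(np.ceil(corners[:, 0].max())), grid_size)
        v0 = max(int(np.floor(corners[:, 1].min())), 0)
        v1 = min(int(np.ceil(corners[:, 1].max())), grid_size)
        assigned = 0.0
        for v in range(v0, v1):
            for u in range(u0, u1):
                cell = np.array(
                    [(u, v), (u + 1, v), (u + 1, v + 1), (u, v + 1)], dtype=float
                )
                inter = polygon_clip(corners, cell)
                a = polygon_area(inter)
                if a <= 0:
                    continue
                frac = a / area
                data_grid[:, v, u] += c * frac * f3
                bg_grid[:, v, u] += b * frac * f3
                assigned += frac * f3.sum()
        clipped += c * (1.0 - assigned)

    return GridProfile(values=data_grid, background=bg_grid, clipped=clipped)


# ---- reference profiles -----------------------------------------------------


class ReferenceLocator:
    """Gaussian-weighted average profiles on a coarse detector raster.

    Reference positions form an ``nx x ny`` grid over the panel; each strong
    profile contributes to every reference of its block with weight
    exp(-d^2 / (2 sigma_w^2)), sigma_w = spacing / (2 sqrt(2 ln 2)), so a
    spot exactly halfway between two references contributes exactly half its
    on-site weight to each.  Accumulated profiles are normalized to unit sum.
    """

    def __init__(self, image_size, n_grid: int = 3):
        nf, ns = image_size
        self.nx = self.ny = n_grid
        self.dx = nf / n_grid
        self.dy = ns / n_grid
        self.positions = np.array(
            [
                ((i + 0.5) * self.dx, (j + 0.5) * self.dy)
                for j in range(n_grid)
                for i in range(n_grid)
            ]
        )
        spacing = 0.5 * (self.dx + self.dy)
        self.sigma_w = spacing / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def weights(self, x: float, y: float) -> np.ndarray:
        d2 = ((self.positions[:, 0] - x) ** 2 + (self.positions[:, 1] - y) ** 2)
        return np.exp(-d2 / (2.0 * self.sigma_w**2))

    def nearest(self, x: float, y: float) -> int:
        d2 = ((self.positions[:, 0] - x) ** 2 + (self.positions[:, 1] - y) ** 2)
        return int(np.argmin(d2))


def build_reference_profiles(
    profiles: list[np.ndarray],
    positions: np.ndarray,
    locator: ReferenceLocator,
):
    """Accumulate normalized background-subtracted strong-spot profiles into
    per-position references.

    Returns ``(references, usable)``: references[i] sums to 1 where usable;
    positions with zero accumulated weight are flagged unusable and fall back
    to the global mean profile at lookup time.
    """
    if len(profiles) == 0:
        raise IntegrationError("no strong profiles to build references from")
    shape = profiles[0].shape
    n_ref = len(locator.positions)
    acc = np.zeros((n_ref,) + shape)
    wsum = np.zeros(n_ref)
    for prof, (x, y) in zip(profiles, positions):
        p = np.clip(prof, 0.0, None)
        s = p.sum()
        if s <= 0:
            continue
        p = p / s
        w = locator.weights(x, y)
        acc += w[:, None, None, None] * p
        wsum += w
    usable = wsum > 1e-12
    refs = np.zeros_like(acc)
    for i in range(n_ref):
        if usable[i]:
            total = acc[i].sum()
            if total > 0:
                refs[i] = acc[i] / total
            else:
                usable[i] = False
    return refs, usable


# ---- profile fitting --------------------------------------------------------


def fit_profile(
    data_grid: np.ndarray,
    background_grid: np.ndarray,
    reference: np.ndarray,
    max_iterations: int = 10,
    rel_tol: float = 1e-4,
):
    """Fit I such that data ~ background + I * reference (Poisson weights).

    Iterates I <- sum(p (d - b) / v) / sum(p^2 / v) with v = b + I p,
    initialized from the plain sum.  Returns a dict with the fitted
    intensity, its variance 1 / sum(p^2 / v) and the Pearson correlation
    between (d - b) and I p over the grid.
    """
    p = np.asarray(reference, dtype=float).ravel()
    d = np.asarray(data_grid, dtype=float).ravel()
    b = np.asarray(background_grid, dtype=float).ravel()
    if p.sum() <= 0:
        return {"intensity": np.nan, "variance": np.nan,
                "correlation": np.nan, "flag": "null_reference"}
    use = (p > 0) | (b > 0)
    if not use.any():
        return {"intensity": np.nan, "variance": np.nan,
                "correlation": np.nan, "flag": "empty_grid"}
    i_val = float((d - b).sum())
    for _ in range(max_iterations):
        v = b[use] + max(i_val, 0.0) * p[use]
        v = np.maximum(v, 1e-10)
        num = float((p[use] * (d[use] - b[use]) / v).sum())
        den = float((p[use] ** 2 / v).sum())
        if den <= 0:
            return {"intensity": np.nan, "variance": np.nan,
                    "correlation": np.nan, "flag": "null_reference"}
        i_new = num / den
        if abs(i_new - i_val) <= rel_tol * max(abs(i_new), 1.0):
            i_val = i_new
            break
        i_val = i_new
    v = np.maximum(b[use] + max(i_val, 0.0) * p[use], 1e-10)
    var = 1.0 / float((p[use] ** 2 / v).sum())
    model = i_val * p
    resid = d - b
    if np.std(model) > 0 and np.std(resid) > 0:
        corr = float(np.corrcoef(resid, model)[0, 1])
    else:
        corr = np.nan
    return {"intensity": i_val, "variance": var, "correlation": corr, "flag": ""}


# ---- block scheduling -------------------------------------------------------


def block_schedule(scan, block_size_images: int) -> list[tuple[int, int]]:
    """Half-overlapping image blocks covering the scan.

    The start of each block is aligned with the centre of the preceding one;
    every image is covered by at least one block.  A block size exceeding the
    scan yields a single block.
    """
    first, last = scan.image_range
    n = last - first + 1
    if block_size_images >= n:
        return [(first, last + 1)]
    step = max(block_size_images // 2, 1)
    starts = list(range(first, first + n - block_size_images + 1, step))
    if starts[-1] + block_size_images < first + n:
        starts.append(first + n - block_size_images)
    return [(s, s + block_size_images) for s in starts]


def assign_blocks(z: np.ndarray, blocks: list[tuple[int, int]]) -> np.ndarray:
    """Block index whose centre is closest to each reflection's frame centroid."""
    centres = np.array([(a + b) / 2.0 for a, b in blocks])
    return np.argmin(np.abs(np.asarray(z, dtype=float)[:, None] - centres[None, :]), axis=1)


# ---- orchestration ----------------------------------------------------------


def integrate_reflections(
    experiment: Experiment,
    images: np.ndarray,
    predictions: pd.DataFrame,
    profile: ProfileModel,
    background_method: str = "glm",
    grid_size: int = 9,
    block_size: int = 16,
    strong_i_over_sigma: float = 10.0,
    reference_grid: int = 3,
) -> pd.DataFrame:
    """Full integration pass: shoeboxes, background, summation, transform,
    reference profiles per block, profile fitting.

    Returns the predictions table extended with intensity and diagnostic
    columns; reflections whose shoebox left the detector are dropped.
    """
    boxes, n_dropped = extract_shoeboxes(predictions, images, experiment, profile)
    blocks = block_schedule(experiment.scan, block_size)
    z = np.array([b.zcal for b in boxes])
    block_of = assign_blocks(z, blocks) if len(boxes) else np.zeros(0, int)

    rows = []
    grids = []
    conservation = []
    for box in boxes:
        try:
            bg, bg_var, bg_info = estimate_background(box, method=background_method)
        except IntegrationError:
            rows.append(None)
            grids.append(None)
            continue
        summ = integrate_summation(box, bg)
        grid = kabsch_transform(box, experiment, profile, bg, grid_size=grid_size)
        fg_sum = float(box.data[(box.mask & MASK_FOREGROUND) > 0].sum())
        conservation.append(
            abs(grid.values.sum() + grid.clipped - fg_sum) / max(fg_sum, 1.0)
        )
        rows.append(
            {
                "h": box.hkl[0], "k": box.hkl[1], "l": box.hkl[2],
                "panel": box.panel,
                "x_pred": box.xcal, "y_pred": box.ycal,
                "phi_pred": box.phical, "z_pred": box.zcal,
                "background": float(np.mean(bg)),
                "intensity_sum": summ["intensity"],
                "variance_sum": summ["variance"],
                "partial": box.partial,
                "flags": summ["flag"],
            }
        )
        grids.append(grid)

    # reference profiles per block from strong reflections
    locators = {}
    references = {}
    for bi in range(len(blocks)):
        locators[bi] = ReferenceLocator(experiment.detector[0].image_size, reference_grid)
    for bi in range(len(blocks)):
        profs, poss = [], []
        for i, (row, grid) in enumerate(zip(rows, grids)):
            if row is None or grid is None or block_of[i] != bi:
                continue
            ivar = row["variance_sum"]
            if not np.isfinite(row["intensity_sum"]) or not np.isfinite(ivar) or ivar <= 0:
                continue
            if row["intensity_sum"] / math.sqrt(ivar) < strong_i_over_sigma:
                continue
            profs.append(grid.values - grid.background)
            poss.append((row["x_pred"], row["y_pred"]))
        if profs:
            refs, usable = build_reference_profiles(profs, np.asarray(poss), locators[bi])
            # global mean profile as fallback
            mean_prof = np.clip(sum(np.clip(p, 0, None) for p in profs), 0, None)
            if mean_prof.sum() > 0:
                mean_prof = mean_prof / mean_prof.sum()
            references[bi] = (refs, usable, mean_prof)
        else:
            references[bi] = None

    out_rows = []
    for i, (row, grid) in enumerate(zip(rows, grids)):
        if row is None:
            continue
        ref_entry = references.get(int(block_of[i]))
        if ref_entry is None:
            row.update({"intensity_prf": np.nan, "variance_prf": np.nan,
                        "profile_corr": np.nan})
        else:
            refs, usable, mean_prof = ref_entry
            loc = locators[int(block_of[i])]
            j = loc.nearest(row["x_pred"], row["y_pred"])
            ref = refs[j] if usable[j] else mean_prof
            fit = fit_profile(grid.values, grid.background, ref)
            row.update(
                {
                    "intensity_prf": fit["intensity"],
                    "variance_prf": fit["variance"],
                    "profile_corr": fit["correlation"],
                }
            )
            if fit["flag"]:
                row["flags"] = (row["flags"] + ";" + fit["flag"]).strip(";")
        row["integrated"] = np.isfinite(row.get("intensity_prf", np.nan)) or np.isfinite(
            row["intensity_sum"]
        )
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    # per-reflection count-conservation residual of the grid transform
    out.attrs["conservation_rel_err"] = conservation
    return out
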