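"""Synthetic rotation-series diffraction images with known ground truth.

Each predicted reflection is rendered as a separable 3D Gaussian: angular
widths (sigma_d, sigma_d) on the detector face, converted to pixel widths via
the local pixel angular subtense, and sigma_m along rotation scaled by the
Lorentz factor 1/|zeta| (the apparent rocking width of a reflection whose
reciprocal-lattice point crosses the Ewald sphere obliquely).  Pixel values
are Poisson draws of the accumulated expectation plus a flat background, so
photon statistics are exact by construction.

The generator deliberately emits only *measurable* reflections: those far
from the blind region (|zeta| >= min_zeta), away from panel edges, and whose
rocking curve lies inside the scan.  Reflections failing these cuts are not
physically integrable by any rotation-method pipeline and would contaminate
recovery statistics with geometry rather than algorithm failures.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .geometry import (
    Beam,
    Crystal,
    Experiment,
    Goniometer,
    Panel,
    Scan,
    predict_reflections,
    rotation_about_axis,
    two_theta,
)
from .integrate import ProfileModel

__all__ = [
    "default_experiment",
    "simulate_rotation_series",
    "inject_artifacts",
    "crop_experiment",
    "expectation_spot",
]


def default_experiment(
    cell=(30.0, 30.0, 30.0, 90.0, 90.0, 90.0),
    wavelength: float = 1.0,
    distance: float = 120.0,
    image_size=(450, 450),
    pixel_size=(0.15, 0.15),
    n_images: int = 90,
    oscillation: float = 1.0,
    phi_start: float = 0.0,
    misset_deg: float = 25.0,
) -> Experiment:
    """A single-panel beam-normal experiment used throughout the test suite.

    The crystal is deliberately missettled by ``misset_deg`` about a skew axis
    so that no lattice vector is aligned with the beam or rotation axis.
    """
    beam = Beam(
        s0_direction=np.array([0.0, 0.0, 1.0]),
        wavelength=wavelength,
        polarization_normal=np.array([0.0, 1.0, 0.0]),
        polarization_fraction=0.95,
    )
    nf, ns = image_size
    panel = Panel(
        origin=np.array(
            [-0.5 * nf * pixel_size[0], -0.5 * ns * pixel_size[1], distance]
        ),
        fast_axis=np.array([1.0, 0.0, 0.0]),
        slow_axis=np.array([0.0, 1.0, 0.0]),
        pixel_size=pixel_size,
        image_size=image_size,
    )
    gonio = Goniometer(rotation_axis=np.array([1.0, 0.0, 0.0]))
    scan = Scan(image_range=(0, n_images - 1), phi_start=phi_start, oscillation=oscillation)
    axis = np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)
    u = rotation_about_axis(axis, np.radians(np.asarray(misset_deg)))
    crystal = Crystal(cell=cell, u=u)
    return Experiment(beam, [panel], gonio, scan, crystal)


def crop_experiment(
    experiment: Experiment, x0: int, y0: int, nx: int, ny: int, z0: int, z1: int
) -> Experiment:
    """Sub-experiment covering pixels [x0, x0+nx) x [y0, y0+ny) and frames
    [z0, z1) of the original; shares beam, goniometer and crystal.  Useful for
    rendering many replicates of a single reflection cheaply."""
    p = experiment.detector[0]
    panel = Panel(
        origin=p.origin
        + x0 * p.pixel_size[0] * p.fast_axis
        + y0 * p.pixel_size[1] * p.slow_axis,
        fast_axis=p.fast_axis,
        slow_axis=p.slow_axis,
        pixel_size=p.pixel_size,
        image_size=(nx, ny),
        thickness=p.thickness,
        material=p.material,
        gain=p.gain,
        trusted_range=p.trusted_range,
    )
    scan = Scan(
        image_range=(z0, z1 - 1),
        phi_start=float(experiment.scan.frame_to_phi(np.asarray(float(z0)))),
        oscillation=experiment.scan.oscillation,
    )
    return Experiment(experiment.beam, [panel], experiment.goniometer, scan,
                      experiment.crystal)


def expectation_spot(
    experiment: Experiment,
    x: float,
    y: float,
    z: float,
    zeta: float,
    profile: ProfileModel,
) -> np.ndarray:
    """Unit-intensity expectation image stack of a single reflection rendered
    over the experiment's full raster and scan (sums to 1)."""
    panel = experiment.detector[0]
    scan = experiment.scan
    nf, ns = panel.image_size
    first = scan.image_range[0]
    sx, sy = _pixel_sigma(panel, x, y, profile.sigma_d)
    sz = profile.sigma_m / (abs(zeta) * scan.oscillation)
    mx = _interval_mass(0, nf, x, sx)
    my = _interval_mass(0, ns, y, sy)
    mz = _interval_mass(first, first + scan.n_images, z, sz)
    out = mz[:, None, None] * my[None, :, None] * mx[None, None, :]
    total = out.sum()
    if total <= 0:
        raise ValueError("reflection lies outside the cropped raster/scan")
    return out / total


def _pixel_sigma(panel: Panel, x: float, y: float, sigma_deg: float) -> tuple[float, float]:
    """Gaussian width in pixels equivalent to an angular width at impact (x, y)."""
    lab = panel.pixel_to_lab(np.asarray(x), np.asarray(y))
    r = float(np.linalg.norm(lab))
    cos_inc = abs(float(lab / r @ panel.normal))
    s = np.radians(sigma_deg) * r / cos_inc
    return s / panel.pixel_size[0], s / panel.pixel_size[1]


def _interval_mass(lo: int, hi: int, mu: float, sigma: float) -> np.ndarray:
    """Gaussian mass over unit intervals [i, i+1) for i in [lo, hi)."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = ndtr((edges - mu) / sigma)
    return np.diff(cdf)


def draw_intensities(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw true intensities from a named law.

    ``("loguniform", lo, hi)`` spans the 3-4 orders of magnitude typical of a
    single sweep; ``("constant", c)`` and ``("uniform", lo, hi)`` are provided
    for controlled tests; a callable ``law(n, rng)`` is passed through.
    """
    if callable(law):
        return np.asarray(law(n, rng), dtype=float)
    name = law[0]
    if name == "loguniform":
        lo, hi = law[1], law[2]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if name == "constant":
        return np.full(n, float(law[1]))
    if name == "uniform":
        return rng.uniform(law[1], law[2], size=n)
    raise ValueError(f"unknown intensity law {law!r}")


def simulate_rotation_series(
    experiment: Experiment,
    profile: Optional[ProfileModel] = None,
    intensity_law=("loguniform", 10.0, 1e5),
    background: float = 1.0,
    seed: int = 0,
    n_spots: Optional[int] = None,
    dmin: Optional[float] = None,
    min_zeta: float = 0.15,
    edge_margin_px: float = 8.0,
    decay_tau: Optional[float] = None,
    truncation_nsigma: float = 4.0,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Render an image stack and its ground truth.

    Returns ``(images, truth, info)``: ``images`` is (n_images, slow, fast)
    uint32; ``truth`` one row per rendered reflection with the true intensity
    and centroid; ``info`` records the background level, seed and saturation
    count.  The Gaussian is truncated at ``truncation_nsigma`` and
    renormalized so each reflection's recorded expectation sums to I_true.
    Bit-identical output for identical seeds.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    if profile is None:
        profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
    rng = np.random.default_rng(seed)
    scan = experiment.scan
    panel = experiment.detector[0]
    nf, ns = panel.image_size
    n_img = scan.n_images
    first = scan.image_range[0]

    if experiment.crystal is not None and (n_spots is None or n_spots > 0):
        if dmin is None:
            # default: resolution at ~95% of the panel half-width
            half = 0.475 * min(nf * panel.pixel_size[0], ns * panel.pixel_size[1])
            dist = abs(float(panel.origin @ panel.normal))
            tt = np.arctan2(half, dist)
            dmin = experiment.beam.wavelength / (2.0 * np.sin(tt / 2.0))
        pred = predict_reflections(experiment, dmin)
    else:
        pred = pd.DataFrame()

    truth_rows = []
    expect = np.zeros((n_img, ns, nf), dtype=np.float64)

    if len(pred):
        sig_z = profile.sigma_m / (np.abs(pred["zeta"]) * scan.oscillation)
        keep = (
            (np.abs(pred["zeta"]) >= min_zeta)
            & (pred["x"] >= edge_margin_px)
            & (pred["x"] < nf - edge_margin_px)
            & (pred["y"] >= edge_margin_px)
            & (pred["y"] < ns - edge_margin_px)
            & (pred["z"] - truncation_nsigma * sig_z >= first)
            & (pred["z"] + truncation_nsigma * sig_z <= first + n_img)
        )
        pool = pred[keep].reset_index(drop=True)
        if n_spots is not None:
            if n_spots > len(pool):
                raise ValueError(
                    f"requested {n_spots} spots but only {len(pool)} measurable "
                    "reflections are predicted; open the resolution limit"
                )
            pool = pool.iloc[
                np.sort(rng.choice(len(pool), size=n_spots, replace=False))
            ].reset_index(drop=True)
        intensities = draw_intensities(intensity_law, len(pool), rng)
        if decay_tau is not None:
            intensities = intensities * np.exp(-(pool["z"].to_numpy() - first) / decay_tau)

        for row, i_true in zip(pool.itertuples(index=False), intensities):
            sx, sy = _pixel_sigma(panel, row.x, row.y, profile.sigma_d)
            sz = profile.sigma_m / (abs(row.zeta) * scan.oscillation)
            t = truncation_nsigma
            x0 = max(int(np.floor(row.x - t * sx)), 0)
            x1 = min(int(np.ceil(row.x + t * sx)), nf)
            y0 = max(int(np.floor(row.y - t * sy)), 0)
            y1 = min(int(np.ceil(row.y + t * sy)), ns)
            z0 = max(int(np.floor(row.z - t * sz)), first) - first
            z1 = min(int(np.ceil(row.z + t * sz)), first + n_img) - first
            if x1 <= x0 or y1 <= y0 or z1 <= z0:
                continue
            mx = _interval_mass(x0, x1, row.x, sx)
            my = _interval_mass(y0, y1, row.y, sy)
            mz = _interval_mass(z0 + first, z1 + first, row.z, sz)
            total = mx.sum() * my.sum() * mz.sum()
            if total <= 0:
                continue
            expect[z0:z1, y0:y1, x0:x1] += (
                i_true / total
            ) * mz[:, None, None] * my[None, :, None] * mx[None, None, :]
            truth_rows.append(
                {
                    "h": row.h, "k": row.k, "l": row.l, "panel": row.panel,
                    "x": row.x, "y": row.y, "z": row.z, "phi": row.phi,
                    "d": row.d, "zeta": row.zeta, "I_true": float(i_true),
                    "sigma_d": profile.sigma_d, "sigma_m": profile.sigma_m,
                }
            )

    expect += background
    images = rng.poisson(expect)
    sat_max = panel.trusted_range[1]
    n_saturated = int(np.count_nonzero(images > sat_max))
    images = np.minimum(images, sat_max).astype(np.uint32)
    truth = pd.DataFrame(
        truth_rows,
        columns=["h", "k", "l", "panel", "x", "y", "z", "phi", "d", "zeta",
                 "I_true", "sigma_d", "sigma_m"],
    )
    info = {"background": background, "seed": seed, "n_saturated": n_saturated}
    return images, truth, info


def inject_artifacts(
    images: np.ndarray,
    experiment: Experiment,
    zinger_rate: float = 0.0,
    zinger_counts: int = 10000,
    ice_ring_d=(),
    ice_ring_strength: float = 0.0,
    ring_width: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Add isolated single-pixel outliers and azimuthally uniform powder rings.

    Zingers arrive as Poisson(``zinger_rate``) per image at uniform positions;
    each ice ring adds Poisson(``ice_ring_strength``) extra counts per pixel
    wherever the pixel's scattering angle maps to d within
    ``d0 +/- ring_width`` (A).  With zero rates the input is returned
    unchanged (same object).
    """
    if zinger_rate < 0 or ice_ring_strength < 0:
        raise ValueError("artifact rates must be non-negative")
    if zinger_rate == 0 and (ice_ring_strength == 0 or not len(ice_ring_d)):
        return images
    rng = np.random.default_rng(seed)
    out = images.astype(np.int64, copy=True)
    n_img, ns, nf = out.shape

    if ice_ring_strength > 0 and len(ice_ring_d):
        panel = experiment.detector[0]
        beam = experiment.beam
        xs, ys = np.meshgrid(
            np.arange(nf) + 0.5, np.arange(ns) + 0.5
        )
        lab = panel.pixel_to_lab(xs.ravel(), ys.ravel())
        tt = np.radians(two_theta(beam, s1=lab))
        with np.errstate(divide="ignore"):
            d_map = beam.wavelength / (2.0 * np.sin(np.maximum(tt / 2.0, 1e-9)))
        ring_mask = np.zeros(nf * ns, dtype=bool)
        for d0 in ice_ring_d:
            ring_mask |= np.abs(d_map - d0) <= ring_width
        ring_mask = ring_mask.reshape(ns, nf)
        for i in range(n_img):
            out[i][ring_mask] += rng.poisson(ice_ring_strength, size=int(ring_mask.sum()))

    if zinger_rate > 0:
        for i in range(n_img):
            n_z = rng.poisson(zinger_rate)
            if n_z == 0:
                continue
            yy = rng.integers(0, ns, size=n_z)
            xx = rng.integers(0, nf, size=n_z)
            out[i, yy, xx] += zinger_counts

    return np.minimum(out, np.iinfo(np.uint32).max).astype(np.uint32)
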