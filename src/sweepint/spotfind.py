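"""Dispersion-threshold spot finding.

Strong pixels are those whose local neighbourhood is incompatible with a flat
Poisson field: the local index of dispersion D = s^2 / mu (variance over mean
in a (2k+1) x (2k+1) window) equals the gain G for background, and
D (N - 1) is approximately chi^2 with N - 1 degrees of freedom, giving the
significance threshold used here.  Three sequential tests select a pixel c:

1. c > T (global threshold, default 0),
2. D > G (1 + sigma_b sqrt(2 / (N - 1))),
3. c > mu + sigma_s sqrt(G mu).

Local moments use summed-area (box-filter) accumulation so the cost is
independent of the kernel size; the window includes the central pixel (the
exclude-centre variant changes thresholds negligibly for N ~ 49 and is not
implemented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Experiment

__all__ = [
    "ThresholdParams",
    "dispersion_map",
    "dispersion_threshold",
    "label_connected",
    "summarize_and_filter_spots",
    "find_spots",
]


@dataclass
class ThresholdParams:
    """Spot-finding thresholds.  Defaults suit photon-counting detectors."""

    kernel_half_size: tuple[int, int] = (3, 3)  # (fast, slow)
    gain: float = 1.0
    sigma_b: float = 6.0
    sigma_s: float = 3.0
    global_threshold: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kernel_half_size) < 1:
            raise ValueError("kernel half-size must be >= 1")
        if self.sigma_b < 0 or self.sigma_s < 0:
            raise ValueError("sigma_b and sigma_s must be non-negative")

    @property
    def window_pixels(self) -> int:
        kf, ks = self.kernel_half_size
        return (2 * kf + 1) * (2 * ks + 1)


def _local_moments(image: np.ndarray, mask: np.ndarray, params: ThresholdParams):
    """Count, mean and unbiased variance of valid pixels in each window."""
    kf, ks = params.kernel_half_size
    size = (2 * ks + 1, 2 * kf + 1)  # ndimage order: (slow, fast)
    npix = float(size[0] * size[1])
    m = mask.astype(np.float64)
    img = image.astype(np.float64) * m

    def boxsum(a):
        return ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0) * npix

    cnt = np.rint(boxsum(m))
    s1 = boxsum(img)
    s2 = boxsum(img * image.astype(np.float64))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(cnt > 0, s1 / cnt, 0.0)
        mu = np.maximum(mu, 0.0)  # guard against box-filter rounding
        var = np.where(cnt > 1, (s2 - cnt * mu * mu) / (cnt - 1.0), 0.0)
    return cnt, mu, np.maximum(var, 0.0)


def dispersion_map(image: np.ndarray, mask: np.ndarray = None,
                   params: ThresholdParams = None) -> np.ndarray:
    """Per-pixel local index of dispersion D = s^2 / mu (0 where mu = 0)."""
    params = params or ThresholdParams()
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    _, mu, var = _local_moments(image, mask, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mu > 0, var / mu, 0.0)


def dispersion_threshold(image: np.ndarray, mask: np.ndarray = None,
                         params: ThresholdParams = None) -> np.ndarray:
    """Boolean strong-pixel mask from the three sequential threshold tests.

    Windows containing fewer than two valid pixels are never strong.
    """
    params = params or ThresholdParams()
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = mask.astype(bool)
    cnt, mu, var = _local_moments(image, mask, params)
    img = image.astype(np.float64)
    g = params.gain
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    threshold_b = g * (1.0 + params.sigma_b * np.sqrt(2.0 / np.maximum(cnt - 1.0, 1.0)))
    strong = (
        mask
        & (cnt >= 2)
        & (img > params.global_threshold)
        & (disp > threshold_b)
        & (img > mu + params.sigma_s * np.sqrt(g * mu))
    )
    return strong


def label_connected(strong_stack: np.ndarray, connectivity: int = 6):
    """Label maximal connected sets of strong pixels in 3D (frames, slow, fast).

    ``connectivity`` is 6 (face neighbours, the default for rotation data) or
    26 (face+edge+corner).  Labels are assigned in scan order, so the result
    is deterministic.  Returns (labels, n_labels).
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    return ndimage.label(strong_stack, structure=structure)


def summarize_and_filter_spots(
    labels: np.ndarray,
    images: np.ndarray,
    experiment: Experiment,
    min_pixels: int = 3,
    max_pixels: int = 10000,
    reject_border: bool = True,
    d_limits: tuple = (None, None),
    panel_id: int = 0,
):
    """Summarize labelled pixel groups into a strong-spot reflection table.

    Centroids are intensity-weighted centres of mass with the pixel-centre
    (+0.5) convention; centroid variances are the intensity-weighted
    coordinate variances divided by the summed counts, floored at 1/12 px^2
    (the variance of a uniform distribution over one pixel) and the
    equivalent (dphi)^2/12 for the rotation axis.

    Returns ``(table, pixel_groups)`` where ``pixel_groups[i]`` is an
    ``(n_i, 4)`` array of (z, y, x, counts) rows for spot i (used later for
    profile-parameter estimation).
    """
    scan = experiment.scan
    panel = experiment.detector[panel_id]
    n_labels = int(labels.max())
    if n_labels == 0:
        return pd.DataFrame(), []

    coords = np.argwhere(labels > 0)
    lab = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    vals = images[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.float64)
    order = np.argsort(lab, kind="stable")
    coords, lab, vals = coords[order], lab[order], vals[order]
    splits = np.searchsorted(lab, np.arange(2, n_labels + 1))
    groups_c = np.split(coords, splits)
    groups_v = np.split(vals, splits)

    first = scan.image_range[0]
    dphi = scan.oscillation
    nf, ns = panel.image_size
    rows = []
    pixel_groups = []
    for gc, gv in zip(groups_c, groups_v):
        n_pix = len(gv)
        total = gv.sum()
        if n_pix < min_pixels or n_pix > max_pixels or total <= 0:
            continue
        # continuous coordinates: pixel/frame centre at index + 0.5
        zc = gc[:, 0] + 0.5 + first
        yc = gc[:, 1] + 0.5
        xc = gc[:, 2] + 0.5
        w = gv / total
        cx, cy, cz = w @ xc, w @ yc, w @ zc
        vx = max(w @ (xc - cx) ** 2 / total, 1.0 / 12.0)
        vy = max(w @ (yc - cy) ** 2 / total, 1.0 / 12.0)
        vz = max(w @ (zc - cz) ** 2 / total, 1.0 / 12.0)
        bbox = (
            int(gc[:, 2].min()), int(gc[:, 2].max()) + 1,
            int(gc[:, 1].min()), int(gc[:, 1].max()) + 1,
            int(gc[:, 0].min()) + first, int(gc[:, 0].max()) + 1 + first,
        )
        if reject_border and (
            bbox[0] == 0 or bbox[1] == nf or bbox[2] == 0 or bbox[3] == ns
        ):
            continue
        rows.append(
            {
                "panel": panel_id,
                "x": cx, "y": cy, "z": cz,
                "phi": scan.frame_to_phi(cz),
                "var_x": vx, "var_y": vy, "var_phi": vz * dphi * dphi,
                "intensity_sum": total,
                "n_pixels": n_pix,
                "bbox_x0": bbox[0], "bbox_x1": bbox[1],
                "bbox_y0": bbox[2], "bbox_y1": bbox[3],
                "bbox_z0": bbox[4], "bbox_z1": bbox[5],
                "strong": True,
            }
        )
        pixel_groups.append(
            np.column_stack([gc[:, 0] + first, gc[:, 1], gc[:, 2], gv])
        )

    table = pd.DataFrame(rows)
    if len(table) and (d_limits[0] is not None or d_limits[1] is not None):
        from .geometry import map_to_rlp

        rlp = map_to_rlp(table[["x", "y", "phi"]].to_numpy(float), experiment)
        d = 1.0 / np.maximum(np.linalg.norm(rlp, axis=1), 1e-12)
        keep = np.ones(len(table), dtype=bool)
        if d_limits[0] is not None:  # dmin
            keep &= d >= d_limits[0]
        if d_limits[1] is not None:  # dmax
            keep &= d <= d_limits[1]
        table = table[keep].reset_index(drop=True)
        pixel_groups = [g for g, k in zip(pixel_groups, keep) if k]
    return table, pixel_groups


def find_spots(
    images: np.ndarray,
    experiment: Experiment,
    params: ThresholdParams = None,
    mask: np.ndarray = None,
    connectivity: int = 6,
    **filter_kwargs,
):
    """Threshold every image, link strong pixels in 3D and summarize spots.

    Returns ``(table, pixel_groups)`` as in
    :func:`summarize_and_filter_spots`.
    """
    params = params or ThresholdParams()
    strong = np.zeros(images.shape, dtype=bool)
    for i in range(images.shape[0]):
        m = None if mask is None else mask[i] if mask.ndim == 3 else mask
        strong[i] = dispersion_threshold(images[i], m, params)
    labels, _ = label_connected(strong, connectivity)
    return summarize_and_filter_spots(labels, images, experiment, **filter_kwargs)
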