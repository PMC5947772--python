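"""Crystal-health and processing diagnostics.

Machine-readable (JSON) reports with an optional static HTML rendering:
spot-counts-per-image series with radiation-damage / blank-region flags,
observed-minus-predicted residual histograms, profile-correlation
distributions and RMSD summaries.  Reports are deterministic given their
inputs; wall-clock timestamps appear only in the metadata section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpotCountSeries",
    "spot_counts_per_image",
    "generate_report",
    "write_report",
]


@dataclass
class SpotCountSeries:
    counts: np.ndarray
    decaying: bool
    blank_regions: list = field(default_factory=list)

    @property
    def stable(self) -> bool:
        return not self.decaying and not self.blank_regions

    def to_dict(self) -> dict:
        return {
            "counts": [int(c) for c in self.counts],
            "stable": bool(self.stable),
            "decaying": bool(self.decaying),
            "blank_regions": [[int(a), int(b)] for a, b in self.blank_regions],
        }


def spot_counts_per_image(
    table: pd.DataFrame,
    scan,
    decay_drop: float = 0.5,
    decay_nsigma: float = 3.0,
    blank_run: int = 5,
    blank_fraction: float = 0.1,
) -> SpotCountSeries:
    """Count strong spots on every image of the scan.

    A spot counts on every frame its bounding box touches.  The series is
    flagged ``decaying`` when a linear trend drops by more than
    ``decay_drop`` of its starting value over the scan with a negative slope
    significant at ``decay_nsigma``; maximal runs of at least ``blank_run``
    images with counts below ``blank_fraction`` of the series median are
    reported as blank regions.
    """
    first, last = scan.image_range
    n = last - first + 1
    counts = np.zeros(n, dtype=int)
    if len(table):
        if "bbox_z0" in table and table["bbox_z0"].notna().all():
            z0 = table["bbox_z0"].to_numpy(int)
            z1 = table["bbox_z1"].to_numpy(int)
        else:
            z0 = np.floor(table["z"].to_numpy(float)).astype(int)
            z1 = z0 + 1
        for a, b in zip(z0, z1):
            a = max(a, first)
            b = min(b, last + 1)
            if b > a:
                counts[a - first : b - first] += 1

    if counts.sum() == 0:
        return SpotCountSeries(counts=counts, decaying=False,
                               blank_regions=[[first, last]])

    decaying = False
    if n >= 3:
        x = np.arange(n, dtype=float)
        # least-squares line with slope standard error
        A = np.column_stack([np.ones(n), x])
        coef, res, *_ = np.linalg.lstsq(A, counts.astype(float), rcond=None)
        fit = A @ coef
        dof = max(n - 2, 1)
        s2 = float(((counts - fit) ** 2).sum()) / dof
        sxx = float(((x - x.mean()) ** 2).sum())
        slope_se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
        start, end = fit[0], fit[-1]
        if (
            coef[1] < 0
            and slope_se > 0
            and abs(coef[1]) / slope_se > decay_nsigma
            and start > 0
            and (start - end) / start > decay_drop
        ):
            decaying = True

    median = float(np.median(counts))
    low = counts < blank_fraction * max(median, 1.0)
    blank_regions = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= blank_run:
                blank_regions.append([first + i, first + j - 1])
            i = j
        else:
            i += 1
    return SpotCountSeries(counts=counts, decaying=decaying,
                           blank_regions=blank_regions)


def _histogram(values: np.ndarray, bins) -> dict:
    counts, edges = np.histogram(values, bins=bins)
    return {"counts": [int(c) for c in counts], "edges": [float(e) for e in edges]}


def generate_report(experiment, table: pd.DataFrame, scan=None) -> dict:
    """Assemble the diagnostics document.

    Sections are omitted (with a notice) when the reflection table lacks the
    required columns; nothing raises.  Histogram bin edges are always
    recorded alongside counts.
    """
    report: dict = {"sections": {}, "notices": [], "metadata": {}}
    scan = scan or experiment.scan

    have = set(c for c in table.columns if table[c].notna().any()) if len(table) else set()

    if {"x", "y", "x_pred", "y_pred"} <= have:
        dx = (table["x"] - table["x_pred"]).to_numpy(float)
        dy = (table["y"] - table["y_pred"]).to_numpy(float)
        ok = np.isfinite(dx) & np.isfinite(dy)
        lim = max(np.abs(np.concatenate([dx[ok], dy[ok]])).max(), 0.5) if ok.any() else 0.5
        edges = np.linspace(-lim, lim, 41)
        h2, ex, ey = np.histogram2d(dx[ok], dy[ok], bins=[edges, edges])
        report["sections"]["xy_residuals"] = {
            "counts": h2.astype(int).tolist(),
            "x_edges": [float(e) for e in ex],
            "y_edges": [float(e) for e in ey],
            "rmsd_x_px": float(np.sqrt(np.mean(dx[ok] ** 2))) if ok.any() else None,
            "rmsd_y_px": float(np.sqrt(np.mean(dy[ok] ** 2))) if ok.any() else None,
        }
    else:
        report["notices"].append("xy_residuals omitted: no observed+predicted centroids")

    if {"phi", "phi_pred"} <= have:
        dphi = (table["phi"] - table["phi_pred"]).to_numpy(float)
        ok = np.isfinite(dphi)
        report["sections"]["phi_residuals"] = {
            **_histogram(dphi[ok], 41),
            "rmsd_phi_deg": float(np.sqrt(np.mean(dphi[ok] ** 2))) if ok.any() else None,
        }
    else:
        report["notices"].append("phi_residuals omitted: no phi observations/predictions")

    if "profile_corr" in have:
        cc = table["profile_corr"].to_numpy(float)
        cc = cc[np.isfinite(cc)]
        report["sections"]["profile_correlation"] = _histogram(
            cc, np.linspace(-1.0, 1.0, 41)
        )
        report["sections"]["profile_correlation"]["mean"] = (
            float(cc.mean()) if len(cc) else None
        )
    else:
        report["notices"].append("profile_correlation omitted: not integrated")

    if len(table) and ("bbox_z0" in have or "z" in have):
        series = spot_counts_per_image(table, scan)
        report["sections"]["spot_counts"] = series.to_dict()
    else:
        report["notices"].append("spot_counts omitted: no frame assignments")

    if experiment.crystal is not None:
        report["sections"]["crystal"] = {
            "cell": [float(x) for x in experiment.crystal.cell],
            "u": experiment.crystal.u.tolist(),
        }
    return report


def write_report(report: dict, json_path, html_path=None, timestamp: str = None) -> None:
    """Write report.json (and a minimal static report.html)."""
    doc = dict(report)
    if timestamp is not None:
        doc = dict(report)
        doc["metadata"] = dict(report.get("metadata", {}), timestamp=timestamp)
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if html_path is not None:
        parts = ["<html><head><title>sweepint report</title></head><body>"]
        parts.append("<h1>Processing report</h1>")
        for name, section in sorted(doc.get("sections", {}).items()):
            parts.append(f"<h2>{name}</h2><pre>{json.dumps(section, indent=1)}</pre>")
        if doc.get("notices"):
            parts.append("<h2>notices</h2><ul>")
            parts += [f"<li>{n}</li>" for n in doc["notices"]]
            parts.append("</ul>")
        parts.append("</body></html>")
        with open(html_path, "w") as fh:
            fh.write("\n".join(parts) + "\n")
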