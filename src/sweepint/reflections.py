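"""Column-centric reflection tables.

A reflection table is a :class:`pandas.DataFrame` whose columns are drawn from
a documented registry; every processing stage reads and writes this one
artefact (as CSV).  Missing values are empty fields in the CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# name -> (dtype, description)
COLUMNS = {
    "h": ("Int64", "Miller index h"),
    "k": ("Int64", "Miller index k"),
    "l": ("Int64", "Miller index l"),
    "panel": ("Int64", "panel id"),
    "x": ("float64", "observed centroid, fast pixel coordinate"),
    "y": ("float64", "observed centroid, slow pixel coordinate"),
    "z": ("float64", "observed centroid, continuous frame coordinate"),
    "phi": ("float64", "observed centroid rotation angle (deg)"),
    "var_x": ("float64", "centroid variance, fast (px^2)"),
    "var_y": ("float64", "centroid variance, slow (px^2)"),
    "var_phi": ("float64", "centroid variance, rotation (deg^2)"),
    "x_pred": ("float64", "predicted centroid, fast pixel coordinate"),
    "y_pred": ("float64", "predicted centroid, slow pixel coordinate"),
    "phi_pred": ("float64", "predicted centroid rotation angle (deg)"),
    "z_pred": ("float64", "predicted centroid, continuous frame coordinate"),
    "d": ("float64", "resolution (A)"),
    "zeta": ("float64", "Lorentz zeta factor m . e1"),
    "bbox_x0": ("Int64", "bounding box, fast start (half-open)"),
    "bbox_x1": ("Int64", "bounding box, fast end"),
    "bbox_y0": ("Int64", "bounding box, slow start"),
    "bbox_y1": ("Int64", "bounding box, slow end"),
    "bbox_z0": ("Int64", "bounding box, frame start"),
    "bbox_z1": ("Int64", "bounding box, frame end"),
    "n_pixels": ("Int64", "number of strong pixels in the spot"),
    "intensity_sum": ("float64", "summation intensity (counts)"),
    "variance_sum": ("float64", "summation intensity variance"),
    "intensity_prf": ("float64", "profile-fitted intensity (counts)"),
    "variance_prf": ("float64", "profile-fitted intensity variance"),
    "profile_corr": ("float64", "Pearson correlation data vs fitted profile"),
    "background": ("float64", "estimated background level (counts/pixel)"),
    "lp_correction": ("float64", "multiplicative Lorentz-polarization correction"),
    "qe_correction": ("float64", "multiplicative sensor-absorption correction"),
    "partial": ("boolean", "shoebox clipped at a panel/scan edge"),
    "strong": ("boolean", "found by spot finding"),
    "indexed": ("boolean", "assigned a Miller index"),
    "integrated": ("boolean", "intensity successfully measured"),
    "flags": ("object", "semicolon-separated status notes"),
}


def validate(table: pd.DataFrame) -> pd.DataFrame:
    """Check column names and basic invariants; returns the table."""
    unknown = set(table.columns) - set(COLUMNS)
    if unknown:
        raise ValueError(f"unknown reflection-table columns: {sorted(unknown)}")
    for col in ("var_x", "var_y", "var_phi", "variance_sum", "variance_prf"):
        if col in table and len(table):
            vals = table[col].dropna()
            if len(vals) and (vals < 0).any():
                raise ValueError(f"negative values in variance column {col!r}")
    return table


def write_csv(table: pd.DataFrame, path) -> None:
    validate(table)
    table.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in table.columns:
        if col in COLUMNS:
            dtype = COLUMNS[col][0]
            if dtype == "Int64":
                table[col] = table[col].round().astype("Int64")
            elif dtype == "boolean":
                table[col] = table[col].astype("boolean")
    return validate(table)


def match_by_position(
    found: pd.DataFrame,
    truth: pd.DataFrame,
    max_px: float = 2.0,
    max_frames: float = 2.0,
) -> np.ndarray:
    """For each truth row, index of a found spot within ``max_px`` in x/y and
    ``max_frames`` in z, else -1.  Used for recovery scoring against simulator
    ground truth."""
    from scipy.spatial import cKDTree

    if len(found) == 0:
        return np.full(len(truth), -1)
    scale = np.array([1.0, 1.0, max_px / max_frames])
    pts_f = found[["x", "y", "z"]].to_numpy(float) * scale
    pts_t = truth[["x", "y", "z"]].to_numpy(float) * scale
    tree = cKDTree(pts_f)
    dist, idx = tree.query(pts_t, distance_upper_bound=max_px * np.sqrt(3))
    out = np.where(np.isfinite(dist), idx, -1)
    # enforce the per-axis tolerances exactly
    for i, j in enumerate(out):
        if j < 0 or j >= len(found):
            out[i] = -1
            continue
        dx = abs(found["x"].iloc[j] - truth["x"].iloc[i])
        dy = abs(found["y"].iloc[j] - truth["y"].iloc[i])
        dz = abs(found["z"].iloc[j] - truth["z"].iloc[i])
        if dx > max_px or dy > max_px or dz > max_frames:
            out[i] = -1
    return out
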