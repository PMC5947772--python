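"""Autoindexing: 1D-FFT basis-vector search and Miller-index assignment.

The direction search projects the reciprocal-lattice points (rlps) onto a
quasi-uniform set of hemisphere directions; for a direction parallel to a
real-space lattice vector of length d the projections form a comb of spacing
1/d, which appears as a peak at frequency d in the power spectrum of the
gridded projections.  Candidate real-space vectors are local spectral maxima,
merged over directions; a basis is chosen as the non-coplanar candidate
triple indexing the largest fraction of rlps, then Niggli-reduced (via gemmi)
and refined by a linear least-squares fit of UB to the indexed rlps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import gemmi
import numpy as np
import pandas as pd

from .geometry import Crystal, Experiment, map_to_rlp

__all__ = [
    "IndexingError",
    "BasisCandidate",
    "hemisphere_directions",
    "fft1d_candidates",
    "select_basis",
    "assign_indices",
    "fit_ub",
    "index_reflections",
    "basis_misorientation",
]


class IndexingError(RuntimeError):
    """The basis search could not produce a usable lattice."""


@dataclass
class BasisCandidate:
    """A putative real-space lattice vector with its spectral score."""

    vector: np.ndarray  # A, lab frame
    score: float
    d: float  # |vector| in A

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)


def hemisphere_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the z >= 0 hemisphere (golden spiral)."""
    i = np.arange(n) + 0.5
    z = i / n  # uniform in cos(polar angle) over the hemisphere
    theta = np.arccos(z)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), z])


def fft1d_candidates(
    rlps: np.ndarray,
    d_max: float = 200.0,
    n_directions: int = 16384,
    grid_points: int = 256,
    d_min_cell: float = 3.0,
    max_candidates: int = 30,
    peaks_per_direction: int = 3,
    chunk: int = 2048,
    return_stats: bool = False,
):
    """Search hemisphere directions for periodicities in the projected rlps.

    Duplicates (closer than 2 deg as lines, with |delta d|/d < 1 %) are merged
    keeping the higher score.  Raises :class:`IndexingError` when fewer than
    three distinct candidates emerge.
    """
    rlps = np.asarray(rlps, dtype=float)
    if len(rlps) < 20:
        raise IndexingError(f"need at least ~20 rlps to index, got {len(rlps)}")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    dirs = hemisphere_directions(n_directions)
    half_range = float(np.max(np.linalg.norm(rlps, axis=1))) * 1.001
    length = 2.0 * half_range  # grid spans [-half_range, half_range]
    n = grid_points
    k_min = max(3, int(np.ceil(d_min_cell * length)))
    k_max = min(n // 2, int(np.floor(d_max * length)))
    if k_max <= k_min:
        raise IndexingError("resolution range leaves no usable frequency band")

    pool_dir, pool_k, pool_power = [], [], []
    for start in range(0, n_directions, chunk):
        d = dirs[start : start + chunk]
        proj = d @ rlps.T  # (m, N)
        idx = np.clip(((proj + half_range) / length * n).astype(int), 0, n - 1)
        hist = np.zeros((len(d), n))
        np.add.at(hist, (np.repeat(np.arange(len(d)), len(rlps)), idx.ravel()), 1.0)
        power = np.abs(np.fft.rfft(hist, axis=1)) ** 2
        band = power[:, k_min : k_max + 1]
        # local maxima within the band
        interior = np.zeros_like(band, dtype=bool)
        interior[:, 1:-1] = (band[:, 1:-1] >= band[:, :-2]) & (
            band[:, 1:-1] >= band[:, 2:]
        )
        for row in range(len(d)):
            ks = np.nonzero(interior[row])[0]
            if len(ks) == 0:
                continue
            top = ks[np.argsort(band[row, ks])[::-1][:peaks_per_direction]]
            for kk in top:
                pool_dir.append(start + row)
                pool_k.append(kk + k_min)
                pool_power.append(band[row, kk])
        # keep the full spectra of pooled rows? recompute below instead
    if not pool_dir:
        raise IndexingError("no spectral peaks found")

    pool_power = np.asarray(pool_power)
    order = np.argsort(pool_power)[::-1]
    noise_floor = np.median(pool_power)

    candidates: list[BasisCandidate] = []
    for j in order:
        if pool_power[j] <= noise_floor:
            break
        direction = dirs[pool_dir[j]]
        k = pool_k[j]
        # refine the peak frequency by centre of mass over (k-1, k, k+1)
        proj = rlps @ direction
        idx = np.clip(((proj + half_range) / length * n).astype(int), 0, n - 1)
        hist = np.bincount(idx, minlength=n)
        spec = np.abs(np.fft.rfft(hist)) ** 2
        lo, hi = max(k - 1, 1), min(k + 1, n // 2)
        kk = np.arange(lo, hi + 1)
        k_ref = float((spec[lo : hi + 1] @ kk) / spec[lo : hi + 1].sum())
        d_val = k_ref / length
        if not (d_min_cell <= d_val <= d_max):
            continue
        vec = direction * d_val
        dup = False
        for c in candidates:
            cosang = abs(vec @ c.vector) / (np.linalg.norm(vec) * c.d)
            if cosang > np.cos(np.radians(2.0)) and abs(d_val - c.d) / c.d < 0.01:
                dup = True
                break
        if not dup:
            candidates.append(BasisCandidate(vector=vec, score=float(pool_power[j]), d=d_val))
        if len(candidates) >= max_candidates:
            break
    if len(candidates) < 3 and not return_stats:
        raise IndexingError(
            f"only {len(candidates)} non-duplicate basis candidates found"
        )
    if return_stats:
        return candidates, {"median_peak_power": float(noise_floor)}
    return candidates


def _indexed_fraction(M: np.ndarray, rlps: np.ndarray, tolerance: float) -> float:
    """Fraction of rlps integer-indexed by the real basis matrix M (columns)."""
    h = rlps @ M  # since UB^-1 = M^T, h = M^T r
    return float(np.mean(np.all(np.abs(h - np.round(h)) < tolerance, axis=1)))


def _niggli_reduce_basis(M: np.ndarray) -> np.ndarray:
    """Niggli-reduce the real-space basis (columns of M) via gemmi, applying
    the tracked change of basis to the vectors themselves."""
    va, vb, vc = M[:, 0], M[:, 1], M[:, 2]
    la, lb, lc = (np.linalg.norm(v) for v in (va, vb, vc))
    cell = gemmi.UnitCell(
        la, lb, lc,
        np.degrees(np.arccos(np.clip(vb @ vc / (lb * lc), -1, 1))),
        np.degrees(np.arccos(np.clip(va @ vc / (la * lc), -1, 1))),
        np.degrees(np.arccos(np.clip(va @ vb / (la * lb), -1, 1))),
    )
    gv = gemmi.GruberVector(cell, None, True)
    gv.niggli_reduce()
    cob = gv.change_of_basis
    if cob is None:
        return M
    T = np.array(cob.rot, dtype=float) / cob.DEN
    # columns transform directly: new basis vectors are M @ T
    return M @ T


def select_basis(
    candidates: list[BasisCandidate],
    rlps: np.ndarray,
    tolerance: float = 0.3,
    min_angle_deg: float = 20.0,
    volume_floor: float = 100.0,
    max_tested: int = 25,
) -> Crystal:
    """Choose the candidate triple maximizing the indexed fraction of rlps.

    Triples with any pairwise angle outside [min_angle, 180 - min_angle] deg
    or cell volume below ``volume_floor`` (A^3) are skipped; ties are broken
    by the smaller cell volume.  The winner is made right-handed,
    Niggli-reduced and returned as a Crystal.
    """
    if len(candidates) < 3:
        raise IndexingError("need at least three basis candidates")
    cands = sorted(candidates, key=lambda c: -c.score)[:max_tested]
    best = None
    cos_lim = np.cos(np.radians(min_angle_deg))
    for i, j, k in combinations(range(len(cands)), 3):
        vi, vj, vk = cands[i].vector, cands[j].vector, cands[k].vector
        ok = True
        for a, b in ((vi, vj), (vi, vk), (vj, vk)):
            c = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            if c > cos_lim:
                ok = False
                break
        if not ok:
            continue
        M = np.column_stack([vi, vj, vk])
        vol = abs(np.linalg.det(M))
        if vol < volume_floor:
            continue
        # genuine non-coplanarity: scalar triple product of the unit vectors
        unit_triple = vol / (
            np.linalg.norm(vi) * np.linalg.norm(vj) * np.linalg.norm(vk)
        )
        if unit_triple < 0.1:
            continue
        frac = _indexed_fraction(M, np.asarray(rlps, dtype=float), tolerance)
        key = (frac, -vol)
        if best is None or key > best[0]:
            best = (key, M)
    if best is None:
        raise IndexingError("all candidate triples are coplanar or too small")
    M = best[1]
    if np.linalg.det(M) < 0:
        M = M.copy()
        M[:, 2] = -M[:, 2]
    M = _niggli_reduce_basis(M)
    if np.linalg.det(M) < 0:
        M = M.copy()
        M[:, 2] = -M[:, 2]
    return Crystal.from_real_basis(M[:, 0], M[:, 1], M[:, 2])


def assign_indices(
    rlps: np.ndarray, crystal: Crystal, tolerance: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Assign Miller indices: h = round(UB^-1 r); a point is indexed iff every
    fractional residual is below ``tolerance``.  Returns (hkl, indexed)."""
    if not 0 < tolerance <= 0.5:
        raise ValueError("tolerance must lie in (0, 0.5]")
    ub = crystal.ub
    if abs(np.linalg.det(ub)) < 1e-12:
        raise ValueError("singular UB matrix")
    h_frac = np.asarray(rlps, dtype=float) @ np.linalg.inv(ub).T
    hkl = np.round(h_frac).astype(int)
    indexed = np.all(np.abs(h_frac - hkl) < tolerance, axis=1)
    return hkl, indexed


def fit_ub(rlps: np.ndarray, hkl: np.ndarray, mask: np.ndarray = None) -> np.ndarray:
    """Linear least-squares UB from indexed rlps: minimizes |UB h - r|^2."""
    r = np.asarray(rlps, dtype=float)
    h = np.asarray(hkl, dtype=float)
    if mask is not None:
        r, h = r[mask], h[mask]
    if len(r) < 6:
        raise IndexingError("too few indexed rlps to fit UB")
    ub, *_ = np.linalg.lstsq(h, r, rcond=None)
    return ub.T


def index_reflections(
    table: pd.DataFrame,
    experiment: Experiment,
    tolerance: float = 0.3,
    refit_cycles: int = 2,
    **search_kwargs,
) -> tuple[Crystal, pd.DataFrame, dict]:
    """Full indexing pass on a strong-spot table.

    Maps centroids to reciprocal space, runs the FFT direction search, picks
    a basis, then alternates index assignment with a linear UB refit (the
    geometric refinement of the full experiment happens downstream, in a
    triclinic cell).  Returns (crystal, table-with-hkl, stats).
    """
    rlps = map_to_rlp(table[["x", "y", "phi"]].to_numpy(float), experiment)
    candidates = fft1d_candidates(rlps, **search_kwargs)
    crystal = select_basis(candidates, rlps, tolerance=tolerance)
    hkl, indexed = assign_indices(rlps, crystal, tolerance)
    for _ in range(refit_cycles):
        ub = fit_ub(rlps, hkl, indexed)
        crystal = Crystal.from_ub(ub)
        hkl, indexed = assign_indices(rlps, crystal, tolerance)
    out = table.copy()
    out["h"], out["k"], out["l"] = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    out["indexed"] = indexed
    stats = {
        "n_rlps": len(rlps),
        "n_indexed": int(indexed.sum()),
        "fraction_indexed": float(indexed.mean()),
        "n_candidates": len(candidates),
        "cell": list(crystal.cell),
    }
    return crystal, out, stats


def basis_misorientation(ub_a: np.ndarray, ub_b: np.ndarray) -> float:
    """Smallest rotation angle (deg) relating two descriptions of one lattice.

    Accounts for the change of basis: finds the integer matrix M with
    ub_a ~ ub_b M, removes it, and returns the residual rotation angle of the
    polar factor.  Raises if the bases do not describe commensurate lattices.
    """
    M = np.linalg.inv(ub_b) @ ub_a
    Mi = np.round(M)
    if abs(abs(np.linalg.det(Mi)) - 1.0) > 0.1 or np.max(np.abs(M - Mi)) > 0.2:
        raise ValueError("bases are not related by a unimodular transform")
    R = ub_a @ np.linalg.inv(ub_b @ Mi)
    w, _, vt = np.linalg.svd(R)
    Q = w @ vt
    if np.linalg.det(Q) < 0:
        Q = w @ np.diag([1.0, 1.0, -1.0]) @ vt
    ang = np.arccos(np.clip((np.trace(Q) - 1.0) / 2.0, -1.0, 1.0))
    return float(np.degrees(ang))
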