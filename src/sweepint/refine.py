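"""Global static-model geometry refinement against spot centroids.

A single static model (beam direction, crystal orientation and cell, detector
position and orientation) is refined for the whole scan by minimizing the
dimensionless weighted least-squares target

    sum_i [ w_x dx_i^2 + w_y dy_i^2 + w_phi dphi_i^2 ]

where the residuals are observed minus predicted centroid positions (mm on
the detector, degrees in rotation) and the weights are inverse centroid
variances from spot finding.  Only central impacts are used; no profile
information enters at this stage.

The minimizer is a small Levenberg-Marquardt implementation with a central
finite-difference Jacobian; it records the accepted-step cost history so the
monotonicity of the target is observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Crystal, Experiment, rotation_about_axis, two_theta

__all__ = [
    "RefinementError",
    "Parameterization",
    "RefinementStats",
    "predict_centroids",
    "residuals_and_weights",
    "refine_geometry",
    "refine_cell_from_two_theta",
    "levenberg_marquardt",
]


class RefinementError(RuntimeError):
    pass


@dataclass
class RefinementStats:
    rmsd_x_mm: float = np.nan
    rmsd_y_mm: float = np.nan
    rmsd_phi_deg: float = np.nan
    n_reflections: int = 0
    n_excluded: int = 0
    iterations: int = 0
    converged: bool = False
    cost_history: list = field(default_factory=list)
    null_space: list = field(default_factory=list)


# ---- parameterization -------------------------------------------------------

BLOCKS = ("beam", "crystal_orientation", "crystal_cell", "detector")


def _orthonormal_pair(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to v."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(v, e1)


class Parameterization:
    """Perturbational parameter vector over a reference experiment.

    All parameters are deviations from the reference model, so x = 0
    reproduces it exactly; applying then inverting a perturbation returns the
    starting models to machine precision.  Parameter units: degrees for all
    angles, mm for detector shifts, A/deg for cell edges/angles.
    """

    def __init__(self, experiment: Experiment, free_blocks=BLOCKS):
        if experiment.crystal is None and (
            "crystal_orientation" in free_blocks or "crystal_cell" in free_blocks
        ):
            raise RefinementError("crystal blocks requested without a crystal model")
        unknown = set(free_blocks) - set(BLOCKS)
        if unknown:
            raise RefinementError(f"unknown parameter blocks: {sorted(unknown)}")
        self.reference = experiment
        self.free_blocks = tuple(b for b in BLOCKS if b in free_blocks)
        self._beam_axes = _orthonormal_pair(experiment.beam.s0_direction)
        names = []
        for block in self.free_blocks:
            if block == "beam":
                names += ["beam_tilt_1_deg", "beam_tilt_2_deg"]
            elif block == "crystal_orientation":
                names += ["crystal_rot_x_deg", "crystal_rot_y_deg", "crystal_rot_z_deg"]
            elif block == "crystal_cell":
                names += ["cell_a", "cell_b", "cell_c",
                          "cell_alpha", "cell_beta", "cell_gamma"]
            elif block == "detector":
                names += ["det_shift_x_mm", "det_shift_y_mm", "det_shift_z_mm",
                          "det_rot_x_deg", "det_rot_y_deg", "det_rot_z_deg"]
        self.names = names

    @property
    def n_parameters(self) -> int:
        return len(self.names)

    def x0(self) -> np.ndarray:
        return np.zeros(self.n_parameters)

    def apply(self, x: np.ndarray) -> Experiment:
        """Experiment obtained by perturbing the reference by x."""
        x = np.asarray(x, dtype=float)
        exp = self.reference
        beam, detector, crystal = exp.beam, exp.detector, exp.crystal
        i = 0
        for block in self.free_blocks:
            if block == "beam":
                t1, t2 = np.radians(x[i : i + 2])
                i += 2
                rot = t1 * self._beam_axes[0] + t2 * self._beam_axes[1]
                d = _rotvec_matrix(rot) @ beam.s0_direction
                beam = Beam_copy(beam, d)
            elif block == "crystal_orientation":
                rot = np.radians(x[i : i + 3])
                i += 3
                R = _rotvec_matrix(rot)
                crystal = Crystal(cell=crystal.cell, u=R @ crystal.u)
            elif block == "crystal_cell":
                dc = x[i : i + 6]
                i += 6
                cell = tuple(np.asarray(crystal.cell) + dc)
                crystal = Crystal(cell=cell, u=crystal.u)
            elif block == "detector":
                shift = x[i : i + 3]
                rot = np.radians(x[i + 3 : i + 6])
                i += 6
                detector = [
                    _perturb_panel(p, shift, rot) for p in detector
                ]
        return Experiment(beam, list(detector), exp.goniometer, exp.scan, crystal)


def Beam_copy(beam, new_direction):
    from .geometry import Beam

    # re-orthogonalize the polarization normal against the tilted beam
    n = beam.polarization_normal
    n = n - (n @ new_direction) * new_direction
    n /= np.linalg.norm(n)
    return Beam(
        s0_direction=new_direction / np.linalg.norm(new_direction),
        wavelength=beam.wavelength,
        polarization_normal=n,
        polarization_fraction=beam.polarization_fraction,
    )


def _rotvec_matrix(rot: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(rot)
    if angle < 1e-15:
        return np.eye(3)
    return rotation_about_axis(rot / angle, np.asarray(angle))


def _perturb_panel(panel, shift, rot):
    from .geometry import Panel

    R = _rotvec_matrix(rot)
    centre = panel.pixel_to_lab(
        np.asarray(panel.image_size[0] / 2.0), np.asarray(panel.image_size[1] / 2.0)
    )
    origin = centre + R @ (panel.origin - centre) + np.asarray(shift, dtype=float)
    return Panel(
        origin=origin,
        fast_axis=R @ panel.fast_axis,
        slow_axis=R @ panel.slow_axis,
        pixel_size=panel.pixel_size,
        image_size=panel.image_size,
        thickness=panel.thickness,
        material=panel.material,
        gain=panel.gain,
        trusted_range=panel.trusted_range,
    )


# ---- prediction for observed reflections ------------------------------------


def predict_centroids(
    experiment: Experiment, hkl: np.ndarray, phi_obs: np.ndarray, panel_id=None
):
    """Predicted (x px, y px, phi deg) for given hkl, choosing for each
    reflection the Ewald crossing nearest its observed phi.

    Returns (pred (N, 3), valid) where invalid rows are blind-region
    reflections or rays missing every panel.
    """
    crystal, beam = experiment.crystal, experiment.beam
    m = experiment.goniometer.rotation_axis
    s0 = beam.s0
    hkl = np.asarray(hkl, dtype=float)
    r0 = hkl @ crystal.ub.T
    r_par = (r0 @ m)[:, None] * m
    r_perp = r0 - r_par
    t2v = np.cross(np.broadcast_to(m, r_perp.shape), r_perp)
    A = 0.5 * np.einsum("ni,ni->n", r0, r0) + r_par @ s0
    B = r_perp @ s0
    C = t2v @ s0
    rho = np.hypot(B, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosarg = np.where(rho > 0, -A / rho, 2.0)
    valid = (rho > 1e-12) & (np.abs(cosarg) <= 1.0)
    phi0 = np.arctan2(C, B)
    dphi = np.arccos(np.clip(cosarg, -1.0, 1.0))
    cand = np.degrees(np.stack([phi0 + dphi, phi0 - dphi], axis=1))
    # choose the solution closest to the observation (mod 360)
    diff = np.abs((cand - np.asarray(phi_obs, dtype=float)[:, None] + 180.0) % 360.0 - 180.0)
    pick = np.argmin(diff, axis=1)
    phi = cand[np.arange(len(cand)), pick]
    phi = np.asarray(phi_obs, dtype=float) + ((phi - phi_obs + 180.0) % 360.0 - 180.0)

    R = rotation_about_axis(m, np.radians(phi))
    s1 = np.einsum("nij,nj->ni", R, r0) + s0
    ray = s1 * beam.wavelength
    pred = np.full((len(hkl), 3), np.nan)
    pred[:, 2] = phi
    hit_any = np.zeros(len(hkl), dtype=bool)
    for pid, panel in enumerate(experiment.detector):
        px, hit = panel.intersect_rays(ray)
        sel = hit & ~hit_any & valid
        pred[sel, 0] = px[sel, 0]
        pred[sel, 1] = px[sel, 1]
        hit_any |= hit
    return pred, valid & hit_any


def residuals_and_weights(
    table: pd.DataFrame, experiment: Experiment
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-reflection residuals (dx mm, dy mm, dphi deg) and inverse-variance
    weights; rows that cannot be predicted are excluded via the returned mask."""
    hkl = table[["h", "k", "l"]].to_numpy(float)
    phi_obs = table["phi"].to_numpy(float)
    pred, valid = predict_centroids(experiment, hkl, phi_obs)
    panel = experiment.detector[0]
    psf, pss = panel.pixel_size
    dx = (table["x"].to_numpy(float) - pred[:, 0]) * psf
    dy = (table["y"].to_numpy(float) - pred[:, 1]) * pss
    dp = phi_obs - pred[:, 2]
    resid = np.column_stack([dx, dy, dp])
    wx = 1.0 / (table["var_x"].to_numpy(float) * psf * psf)
    wy = 1.0 / (table["var_y"].to_numpy(float) * pss * pss)
    wp = 1.0 / table["var_phi"].to_numpy(float)
    weights = np.column_stack([wx, wy, wp])
    return resid, weights, valid


# ---- Levenberg-Marquardt ----------------------------------------------------


def levenberg_marquardt(
    fun,
    x0: np.ndarray,
    max_iterations: int = 50,
    rel_tol: float = 1e-6,
    fd_step: float = 1e-6,
    lam0: float = 1e-3,
):
    """Minimize |f(x)|^2 with damped Gauss-Newton steps and a central
    finite-difference Jacobian.

    Returns (x, cost_history, n_iterations, converged, null_space_indices).
    The cost history contains only accepted steps, so it is non-increasing.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    cost = float(f @ f)
    history = [cost]
    lam = lam0
    converged = False
    null_idx: list[int] = []
    n_par = len(x)
    it = 0
    for it in range(1, max_iterations + 1):
        J = np.empty((len(f), n_par))
        for j in range(n_par):
            h = fd_step * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (fun(xp) - fun(xm)) / (2.0 * h)
        JtJ = J.T @ J
        g = J.T @ f
        diag = np.diag(JtJ).copy()
        null_idx = [j for j in range(n_par) if diag[j] <= 1e-20 * max(diag.max(), 1.0)]
        diag[diag <= 0] = 1.0
        accepted = False
        for _ in range(12):
            A = JtJ + lam * np.diag(diag)
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(A, -g, rcond=None)[0]
            f_new = fun(x + step)
            cost_new = float(f_new @ f_new)
            if cost_new <= cost:
                x = x + step
                f = f_new
                rel = (cost - cost_new) / max(cost, 1e-300)
                cost = cost_new
                history.append(cost)
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                if rel < rel_tol:
                    converged = True
                break
            lam *= 10.0
        if not accepted or converged:
            converged = converged or not accepted and cost == history[0]
            if not accepted:
                converged = True  # no descent direction left
            break
    return x, history, it, converged, null_idx


def refine_geometry(
    table: pd.DataFrame,
    experiment: Experiment,
    free_blocks=("beam", "crystal_orientation", "crystal_cell", "detector"),
    max_iterations: int = 50,
    rel_tol: float = 1e-6,
    outlier_cycles: int = 2,
    outlier_nrmsd: float = 4.0,
) -> tuple[Experiment, RefinementStats]:
    """Refine the selected model blocks against observed centroids.

    Performs up to ``outlier_cycles`` macro-cycles, rejecting reflections with
    any residual beyond ``outlier_nrmsd`` times the per-component RMSD
    between cycles.  Returns the refined experiment and statistics.
    """
    par = Parameterization(experiment, free_blocks)
    n_free = par.n_parameters
    work = table[table["indexed"].fillna(False)] if "indexed" in table else table
    work = work.reset_index(drop=True)
    if 3 * len(work) < 3 * n_free:
        raise RefinementError(
            f"{len(work)} reflections cannot constrain {n_free} parameters"
        )

    keep = np.ones(len(work), dtype=bool)
    stats = RefinementStats()
    x = par.x0()
    result_exp = experiment
    for cycle in range(outlier_cycles + 1):
        sub = work[keep].reset_index(drop=True)
        if 3 * len(sub) < 3 * n_free or len(sub) < n_free:
            raise RefinementError("too few reflections after outlier rejection")

        par = Parameterization(result_exp, free_blocks)

        def target(xv):
            exp = par.apply(xv)
            resid, weights, valid = residuals_and_weights(sub, exp)
            f = (resid * np.sqrt(weights))[valid].ravel()
            # excluded (unpredictable) reflections contribute nothing
            if not np.any(valid):
                return np.full(3, 1e6)
            return f

        x, history, n_iter, converged, null_idx = levenberg_marquardt(
            target, par.x0(), max_iterations=max_iterations, rel_tol=rel_tol
        )
        result_exp = par.apply(x)
        stats.iterations += n_iter
        stats.converged = converged
        stats.cost_history.extend(history)
        stats.null_space = [par.names[j] for j in null_idx]

        resid, weights, valid = residuals_and_weights(sub, result_exp)
        r = resid[valid]
        rmsd = np.sqrt(np.mean(r**2, axis=0))
        stats.rmsd_x_mm, stats.rmsd_y_mm, stats.rmsd_phi_deg = rmsd
        stats.n_reflections = int(valid.sum())
        stats.n_excluded = int(len(work) - valid.sum() - (~keep).sum())
        if cycle == outlier_cycles:
            break
        # outlier rejection for the next macro-cycle
        bad_local = np.any(np.abs(resid) > outlier_nrmsd * np.maximum(rmsd, 1e-12), axis=1)
        bad_local |= ~valid
        if not bad_local.any():
            break
        idx = np.nonzero(keep)[0]
        keep[idx[bad_local]] = False
    return result_exp, stats


# ---- post-integration unit-cell refinement from 2-theta ---------------------


def refine_cell_from_two_theta(
    table: pd.DataFrame,
    crystal: Crystal,
    experiment: Experiment,
) -> tuple[tuple, np.ndarray, RefinementStats]:
    """Re-refine the six cell parameters from observed 2-theta angles.

    2theta_calc(cell; hkl) = 2 asin(lambda |B(cell) h| / 2) is orientation
    free.  The observed 2-theta comes from a ``two_theta_obs`` column when
    present, otherwise from the observed centroid position on the detector.
    Returns (cell, esds, stats) with esds from the inverse normal matrix
    scaled by the residual variance; raises on fewer than 6 usable
    reflections and flags rank-deficient directions in ``stats.null_space``.
    """
    beam = experiment.beam
    if "two_theta_obs" in table:
        tt_obs = table["two_theta_obs"].to_numpy(float)
    else:
        panel = experiment.detector[0]
        lab = panel.pixel_to_lab(
            table["x"].to_numpy(float), table["y"].to_numpy(float)
        )
        tt_obs = two_theta(beam, s1=lab)
    hkl = table[["h", "k", "l"]].to_numpy(float)
    ok = np.isfinite(tt_obs)
    hkl, tt_obs = hkl[ok], tt_obs[ok]
    if len(tt_obs) < 6:
        raise RefinementError("need at least 6 reflections with observed 2-theta")
    lam = beam.wavelength
    cell0 = np.asarray(crystal.cell, dtype=float)

    from .geometry import _b_matrix

    def tt_calc(cell):
        B = _b_matrix(tuple(cell))
        q = np.linalg.norm(hkl @ B.T, axis=1)
        return np.degrees(2.0 * np.arcsin(np.clip(q * lam / 2.0, 0.0, 1.0)))

    def fun(x):
        return tt_obs - tt_calc(cell0 + x)

    x, history, n_iter, converged, _ = levenberg_marquardt(fun, np.zeros(6))
    cell = tuple(cell0 + x)
    f = fun(x)
    dof = max(len(f) - 6, 1)
    s2 = float(f @ f) / dof
    # esds from the inverse normal matrix at the solution
    J = np.empty((len(f), 6))
    for j in range(6):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (fun(xp) - fun(xm)) / (2 * h)
    JtJ = J.T @ J
    w, v = np.linalg.eigh(JtJ)
    stats = RefinementStats(iterations=n_iter, converged=converged,
                            cost_history=history, n_reflections=len(f))
    names = ["a", "b", "c", "alpha", "beta", "gamma"]
    tiny = w < 1e-10 * max(w.max(), 1.0)
    if tiny.any():
        for col in np.nonzero(tiny)[0]:
            main = int(np.argmax(np.abs(v[:, col])))
            stats.null_space.append(names[main])
        w = np.where(tiny, np.inf, w)
    cov = (v * (1.0 / w)) @ v.T * s2
    esds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rms = np.sqrt(np.mean(f**2))
    stats.rmsd_phi_deg = rms  # RMS 2-theta residual, degrees
    return cell, esds, stats
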