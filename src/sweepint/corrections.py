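"""Sample-independent intensity corrections.

Three known, geometry-driven factors modulate measured rotation-method
intensities:

* the Lorentz factor ``L = 1 / |m . (s1_hat x s0_hat)|`` — the inverse speed
  at which the reciprocal-lattice point traverses the Ewald sphere;
* the polarization factor ``P`` of the (partially polarized) incident beam;
* the sensor absorption probability ``p = 1 - exp(-mu(lambda) t / cos
  theta)`` — the chance that a photon traversing a sensor of thickness ``t``
  at incidence angle ``theta`` is actually recorded (the oblique-incidence
  correction is ``1/p``).

Corrections are returned as multiplicative factors for the intensities
(``corrected = raw * factor``); they are stored as reflection-table columns
and applied only on request, since downstream scaling programs may prefer to
absorb them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import Beam, Goniometer, Panel

__all__ = [
    "AttenuationTable",
    "load_attenuation_table",
    "lp_correction",
    "sensor_absorption",
    "CorrectionError",
]

KEV_ANGSTROM = 12.398419843320026  # h c / e in keV * Angstrom


class CorrectionError(ValueError):
    pass


@dataclass
class AttenuationTable:
    """Tabulated linear attenuation coefficient mu(E) with log-log
    interpolation between grid points."""

    material: str
    energy_kev: np.ndarray
    mu_per_mm: np.ndarray

    def __post_init__(self) -> None:
        self.energy_kev = np.asarray(self.energy_kev, dtype=float)
        self.mu_per_mm = np.asarray(self.mu_per_mm, dtype=float)
        if np.any(np.diff(self.energy_kev) <= 0):
            raise CorrectionError("energy grid must be strictly increasing")
        if np.any(self.mu_per_mm <= 0):
            raise CorrectionError("attenuation coefficients must be positive")

    def mu(self, energy_kev: float) -> float:
        """Linear attenuation (1/mm) at the given photon energy."""
        e = float(energy_kev)
        if not (self.energy_kev[0] <= e <= self.energy_kev[-1]):
            raise CorrectionError(
                f"energy {e} keV outside table range "
                f"[{self.energy_kev[0]}, {self.energy_kev[-1]}]"
            )
        return float(
            np.exp(
                np.interp(np.log(e), np.log(self.energy_kev), np.log(self.mu_per_mm))
            )
        )

    def mu_at_wavelength(self, wavelength_angstrom: float) -> float:
        return self.mu(KEV_ANGSTROM / wavelength_angstrom)


def load_attenuation_table(material: str = "Si") -> AttenuationTable:
    """Load a packaged attenuation table (currently silicon only)."""
    if material != "Si":
        raise CorrectionError(f"no attenuation table packaged for {material!r}")
    text = resources.files("sweepint.data").joinpath("si_attenuation.csv").read_text()
    energies, mus = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("energy"):
            continue
        e, mu = line.split(",")
        energies.append(float(e))
        mus.append(float(mu))
    return AttenuationTable(material=material, energy_kev=np.array(energies),
                            mu_per_mm=np.array(mus))


def lp_correction(
    beam: Beam, goniometer: Goniometer, s1: np.ndarray, zeta_min: float = 1e-6
):
    """Lorentz-polarization correction factors for scattered wave vectors s1.

    ``factor = 1 / (L P)`` with ``L = 1/|zeta'|``, ``zeta' = m . (s1_hat x
    s0_hat)``, and the Kahn polarization factor

        P = [1 + cos^2(2 theta) - p' cos(2 psi) sin^2(2 theta)] / 2

    where ``p' = 2 f - 1`` (f = fraction of intensity with electric vector
    along ``t = s0 x n``, i.e. in the plane perpendicular to the polarization
    normal n) and psi is the azimuth of s1 about s0 measured from ``t``.

    Returns ``(factor, valid)``; reflections with |zeta'| < ``zeta_min`` are
    flagged invalid (too close to the rotation axis to integrate).
    """
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    s1_hat = s1 / np.linalg.norm(s1, axis=1)[:, None]
    s0_hat = beam.s0_direction
    m = goniometer.rotation_axis
    n = beam.polarization_normal

    cross = np.cross(s1_hat, np.broadcast_to(s0_hat, s1_hat.shape))
    zeta_p = cross @ m
    valid = np.abs(zeta_p) >= zeta_min
    with np.errstate(divide="ignore"):
        lorentz = 1.0 / np.abs(zeta_p)

    cos_tt = s1_hat @ s0_hat
    cos2 = cos_tt**2
    sin2 = 1.0 - cos2
    t_hat = np.cross(s0_hat, n)
    t_hat = t_hat / np.linalg.norm(t_hat)
    u = s1_hat - cos_tt[:, None] * s0_hat  # projection perpendicular to s0
    un = np.linalg.norm(u, axis=1)
    # forward scattering: psi undefined but sin^2(2theta) = 0
    safe = un > 1e-12
    cos_psi = np.where(safe, (u @ t_hat) / np.where(safe, un, 1.0), 1.0)
    sin_psi = np.where(safe, (u @ n) / np.where(safe, un, 1.0), 0.0)
    cos_2psi = cos_psi**2 - sin_psi**2
    p_prime = 2.0 * beam.polarization_fraction - 1.0
    P = 0.5 * (1.0 + cos2 - p_prime * cos_2psi * sin2)
    factor = np.where(valid, 1.0 / (lorentz * P), np.nan)
    if np.asarray(s1).ndim == 1:
        return float(factor[0]), bool(valid[0])
    return factor, valid


def sensor_absorption(
    theta_incidence_deg,
    energy_kev: float,
    panel: Panel,
    table: AttenuationTable = None,
):
    """Photon detection probability p and oblique-incidence correction 1/p.

    ``p = 1 - exp(-mu(E) t / cos theta)`` with theta the angle between the
    incoming ray and the detector normal.  p increases with theta and t (the
    path length through the sensor grows), so the correction 1/p decreases
    with obliquity.  Returns ``(p, correction)``.
    """
    if table is None:
        table = load_attenuation_table(panel.material)
    theta = np.radians(np.asarray(theta_incidence_deg, dtype=float))
    if np.any(theta >= np.pi / 2) or np.any(theta < 0):
        raise CorrectionError("incidence angle must lie in [0, 90) degrees")
    mu = table.mu(energy_kev)
    p = 1.0 - np.exp(-mu * panel.thickness / np.cos(theta))
    if np.any(p < 1e-6):
        raise CorrectionError("detection probability underflow (p < 1e-6)")
    correction = 1.0 / p
    if np.isscalar(theta_incidence_deg) or np.asarray(theta_incidence_deg).ndim == 0:
        return float(p), float(correction)
    return p, correction


def append_correction_columns(table, experiment):
    """Compute lp_correction and qe_correction columns for a reflection table
    carrying predicted centroids (uses the predicted ray per reflection)."""
    panel = experiment.detector[0]
    beam = experiment.beam
    x = table["x_pred" if "x_pred" in table else "x"].to_numpy(float)
    y = table["y_pred" if "y_pred" in table else "y"].to_numpy(float)
    lab = panel.pixel_to_lab(x, y)
    s1 = lab / np.linalg.norm(lab, axis=1)[:, None] / beam.wavelength
    lp, valid = lp_correction(beam, experiment.goniometer, s1)
    rays = lab / np.linalg.norm(lab, axis=1)[:, None]
    cos_inc = np.abs(rays @ panel.normal)
    theta_inc = np.degrees(np.arccos(np.clip(cos_inc, -1.0, 1.0)))
    energy = KEV_ANGSTROM / beam.wavelength
    att = load_attenuation_table(panel.material)
    p, qe = sensor_absorption(theta_inc, energy, panel, att)
    out = table.copy()
    out["lp_correction"] = np.where(valid, lp, np.nan)
    out["qe_correction"] = qe
    return out
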