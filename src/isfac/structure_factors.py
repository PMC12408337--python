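"""Kinematical structure factors with per-atom neutral/ionic mixing.

Every non-hydrogen site scatters with a linear superposition of its neutral
and ionic electron scattering factor,

    f_j(s) = nu_j * f_ionic(s) + (1 - nu_j) * f_neutral(s),

while hydrogens contribute only through the bare-proton curve scaled by
their fraction, nu_k * f_H+(s) — the neutral-H electron scattering factor is
too weak to support a stable superposition.  With all fractions zero the
expression reduces to a conventional neutral independent-atom model (IAM) in
which hydrogens contribute nothing.

Intensities follow the kinematical (single-scattering) approximation,
I_calc = scale * |F_calc|^2.
"""

from __future__ import annotations

import numpy as np

from .crystal import AtomSite, CrystalModel, UnitCell, s_magnitude
from .scattering import IonSpec, ScatteringLibrary

TWO_PI = 2.0 * np.pi


class MissingCurveError(KeyError):
    """A site lacks the scattering curve its mixing rule needs."""


def debye_waller(site: AtomSite, hkl, cell: UnitCell) -> float | np.ndarray:
    """Debye-Waller attenuation for a site: exp(-8 pi^2 U_iso s^2) for
    isotropic ADPs, exp(-2 pi^2 sum_ij U_ij h_i h_j a*_i a*_j) for
    anisotropic ones (CIF U_ij convention, reciprocal-basis referenced)."""
    scalar = np.ndim(hkl) == 1
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    if site.is_isotropic:
        s = s_magnitude(cell, h)
        out = np.exp(-8.0 * np.pi**2 * float(site.adp) * s**2)
    else:
        u = site.u_matrix
        eig = np.linalg.eigvalsh(u)
        if eig[0] < -1e-10:
            import warnings
            warnings.warn(f"ADP tensor of {site.label} is not positive semidefinite")
        astar = np.sqrt(np.diag(cell.reciprocal_metric))
        hstar = h * astar[None, :]
        out = np.exp(-2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", hstar, u, hstar))
    return float(out[0]) if scalar else out


class SFCalculator:
    """Structure factors and their analytic parameter derivatives for a fixed
    reflection list.

    Scattering curves and the per-op transformed indices are precomputed;
    site coordinates, ADPs and fractions are read from the model at call
    time, so the same calculator serves every refinement cycle.
    """

    def __init__(self, model: CrystalModel, library: ScatteringLibrary,
                 hkl: np.ndarray):
        self.model = model
        self.library = library
        self.hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        self.s = s_magnitude(model.cell, self.hkl)
        self.s2 = self.s**2
        ops = model.all_ops()
        self._hp = [self.hkl.astype(float) @ op.rot_array for op in ops]
        self._ht = [self.hkl.astype(float) @ op.tran_array for op in ops]
        self._astar = np.sqrt(np.diag(model.cell.reciprocal_metric))
        self._curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for site in model.sites:
            self._curves[site.label] = self._site_curves(site)

    def _site_curves(self, site: AtomSite) -> tuple[np.ndarray, np.ndarray]:
        """(f_neutral, f_ionic) sampled on the reflection s values; for H the
        neutral channel is zero and the ionic channel is the proton curve."""
        try:
            if site.is_hydrogen:
                f_ion = self.library.get(IonSpec("H", 1, +1)).evaluate(self.s)
                return np.zeros_like(self.s), np.asarray(f_ion)
            f_neu = self.library.get(site.ion.neutral_partner()).evaluate(self.s)
            if site.ion.dZ != 0:
                f_ion = self.library.get(site.ion).evaluate(self.s)
            else:
                f_ion = f_neu
            return np.asarray(f_neu), np.asarray(f_ion)
        except Exception as exc:
            raise MissingCurveError(
                f"no scattering curve available for site {site.label!r}: {exc}"
            ) from exc

    def refresh_curves(self, site: AtomSite) -> None:
        """Re-sample curves for one site (after a sign flip changed its ion)."""
        self._curves[site.label] = self._site_curves(site)

    # -- per-site geometric sums --------------------------------------------

    def _site_sums(self, site: AtomSite):
        """Returns (G, Gx, dw_terms) where
        G  = sum_ops DW * exp(2 pi i (h' . x + h . t))          (n,)
        Gx = sum_ops DW * 2 pi i h'_m * exp(...)                (n, 3)
        dw = isotropic: -8 pi^2 s^2 * G;
             anisotropic: (n, 6) per-U_ij derivative factors * G-like sums.
        """
        x = np.asarray(site.xyz, dtype=float)
        n = len(self.s)
        G = np.zeros(n, dtype=complex)
        Gx = np.zeros((n, 3), dtype=complex)
        iso = site.is_isotropic
        if iso:
            dw_all = np.exp(-8.0 * np.pi**2 * float(site.adp) * self.s2)
            Gu = None
        else:
            u = site.u_matrix
            Gu = np.zeros((n, 6), dtype=complex)
        for hp, ht in zip(self._hp, self._ht):
            phase = np.exp(TWO_PI * 1j * (hp @ x + ht))
            if iso:
                dw = dw_all
            else:
                hstar = hp * self._astar[None, :]
                dw = np.exp(-2.0 * np.pi**2 *
                            np.einsum("ni,ij,nj->n", hstar, u, hstar))
            term = dw * phase
            G += term
            Gx += (TWO_PI * 1j) * hp * term[:, None]
            if not iso:
                # dDW/dU11,U22,U33,U23,U13,U12 (off-diagonals count twice)
                c = -2.0 * np.pi**2
                Gu[:, 0] += c * hstar[:, 0] ** 2 * term
                Gu[:, 1] += c * hstar[:, 1] ** 2 * term
                Gu[:, 2] += c * hstar[:, 2] ** 2 * term
                Gu[:, 3] += 2 * c * hstar[:, 1] * hstar[:, 2] * term
                Gu[:, 4] += 2 * c * hstar[:, 0] * hstar[:, 2] * term
                Gu[:, 5] += 2 * c * hstar[:, 0] * hstar[:, 1] * term
        if iso:
            Gu = (-8.0 * np.pi**2 * self.s2) * G
        return G, Gx, Gu

    def _mixed_f(self, site: AtomSite) -> np.ndarray:
        f_neu, f_ion = self._curves[site.label]
        if site.is_hydrogen:
            return site.nu * f_ion
        return site.nu * f_ion + (1.0 - site.nu) * f_neu

    def f(self) -> np.ndarray:
        """Complex F_calc for every reflection."""
        F = np.zeros(len(self.s), dtype=complex)
        for site in self.model.sites:
            G, _, _ = self._site_sums(site)
            F += site.occupancy * self._mixed_f(site) * G
        return F

    def f_and_derivs(self, want: dict[str, set[str]]):
        """F plus requested analytic derivatives.

        ``want`` maps site label -> subset of {"nu", "xyz", "adp"}; returns
        (F, derivs) with derivs[label]["nu"] (n,), ["xyz"] (n,3),
        ["adp"] (n,) isotropic or (n,6) anisotropic.
        """
        F = np.zeros(len(self.s), dtype=complex)
        derivs: dict[str, dict[str, np.ndarray]] = {}
        for site in self.model.sites:
            G, Gx, Gu = self._site_sums(site)
            fmix = self._mixed_f(site)
            occ = site.occupancy
            F += occ * fmix * G
            req = want.get(site.label)
            if not req:
                continue
            d: dict[str, np.ndarray] = {}
            f_neu, f_ion = self._curves[site.label]
            if "nu" in req:
                d["nu"] = occ * (f_ion - f_neu) * G
            if "xyz" in req:
                d["xyz"] = occ * (fmix[:, None] * Gx)
            if "adp" in req:
                if site.is_isotropic:
                    d["adp"] = occ * fmix * Gu
                else:
                    d["adp"] = occ * (fmix[:, None] * Gu)
            derivs[site.label] = d
        return F, derivs


def f_calc(model: CrystalModel, library: ScatteringLibrary,
           hkl: np.ndarray) -> np.ndarray:
    """Complex structure factors for ``hkl`` under the mixing rule."""
    return SFCalculator(model, library, hkl).f()


def iam_f_calc(model: CrystalModel, library: ScatteringLibrary,
               hkl: np.ndarray) -> np.ndarray:
    """Conventional neutral-atom IAM structure factors over non-H sites
    (hydrogens carry no neutral electron-scattering term in this scheme)."""
    stripped = model.copy()
    stripped.sites = [s for s in stripped.sites if not s.is_hydrogen]
    for s in stripped.sites:
        s.nu = 0.0
    return SFCalculator(stripped, library, hkl).f()


def intensities(model: CrystalModel, library: ScatteringLibrary,
                hkl: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Kinematical intensities scale * |F|^2."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * np.abs(f_calc(model, library, hkl)) ** 2


def phases(F: np.ndarray) -> np.ndarray:
    """Phase angles in radians."""
    return np.angle(F)
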