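"""Electron scattering factors for neutral atoms and (possibly nonphysical) ions.

Electrons scatter from the Coulomb potential of an atom, so an electron
scattering factor can be obtained from an X-ray form factor through the
Mott-Bethe relation.  The variant used here adds an integer charge offset
``dZ`` to the neutral atomic number, which lets the same X-ray form factor
(always that of the *neutral* atom) generate scattering curves for cations,
anions and exotic species such as C+ or O+ for which tabulated ionic X-ray
form factors may not exist:

    f_e(s) = K * (Z0 + dZ - f_X(s)) / s**2,   K = 1 / (8 pi^2 a0)

with ``s = sin(theta)/lambda`` in 1/Angstrom and ``a0`` the Bohr radius in
Angstrom.  For charged species the curve diverges as s -> 0 with the sign of
``dZ``; fitting and evaluation are therefore restricted to a resolution
window that excludes s = 0.

The curves are parametrized for refinement in the conventional
four-Gaussian-plus-constant (Cromer-Mann) form

    f(s) = c + sum_i a_i * exp(-b_i * s**2)

fitted over the window by damped least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import least_squares

BOHR_RADIUS_A = 0.529177210903
#: Mott-Bethe prefactor 1/(8 pi^2 a0) in 1/Angstrom.
MOTT_BETHE_K = 1.0 / (8.0 * math.pi**2 * BOHR_RADIUS_A)


class UnsupportedElementError(KeyError):
    """Element has no entry in the embedded X-ray form-factor table."""


class FitFailureError(RuntimeError):
    """Cromer-Mann fit did not converge; carries best-so-far residuals."""

    def __init__(self, message: str, max_abs: float, max_rel: float):
        super().__init__(message)
        self.max_abs = max_abs
        self.max_rel = max_rel


@dataclass(frozen=True)
class CromerMann9:
    """Four decaying Gaussians plus a constant: f(s) = c + sum a_i exp(-b_i s^2)."""

    c: float
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]

    def __post_init__(self):
        if len(self.a) != 4 or len(self.b) != 4:
            raise ValueError("need exactly four Gaussian terms")
        if any(bi < 0 for bi in self.b):
            raise ValueError("Gaussian exponents b_i must be >= 0")

    def evaluate(self, s):
        s2 = np.asarray(s, dtype=float) ** 2
        out = np.full_like(s2, self.c, dtype=float)
        for ai, bi in zip(self.a, self.b):
            out = out + ai * np.exp(-bi * s2)
        if np.ndim(s) == 0:
            return float(out)
        return out

    def as_flat(self) -> tuple[float, ...]:
        """(a1, b1, a2, b2, a3, b3, a4, b4, c) — SFAC card order."""
        flat = []
        for ai, bi in zip(self.a, self.b):
            flat.extend((ai, bi))
        flat.append(self.c)
        return tuple(flat)

    @classmethod
    def from_flat(cls, values) -> "CromerMann9":
        v = [float(x) for x in values]
        if len(v) != 9:
            raise ValueError("expected 9 coefficients a1 b1 ... a4 b4 c")
        return cls(c=v[8], a=(v[0], v[2], v[4], v[6]), b=(v[1], v[3], v[5], v[7]))


@dataclass(frozen=True)
class IonSpec:
    """An element plus an integer charge offset; dZ=0 is the neutral species."""

    element: str
    Z0: int
    dZ: int = 0

    def __post_init__(self):
        if self.Z0 < 1:
            raise ValueError("Z0 must be >= 1")
        if self.element.capitalize() == "H" and self.Z0 != 1:
            raise ValueError("hydrogen species must have Z0 = 1")

    @classmethod
    def neutral(cls, element: str) -> "IonSpec":
        return cls(element=element, Z0=_atomic_number(element), dZ=0)

    @classmethod
    def from_charge(cls, element: str, charge: int) -> "IonSpec":
        return cls(element=element, Z0=_atomic_number(element), dZ=charge)

    @property
    def label(self) -> str:
        if self.dZ == 0:
            return self.element
        sign = "+" if self.dZ > 0 else "-"
        mag = "" if abs(self.dZ) == 1 else str(abs(self.dZ))
        return f"{self.element}{mag}{sign}"

    def neutral_partner(self) -> "IonSpec":
        return IonSpec(self.element, self.Z0, 0)


@dataclass(frozen=True)
class FitWindow:
    """Resolution window for scattering-factor fits, in d-spacing (Angstrom)."""

    d_max: float = 15.0
    d_min: float = 0.75
    n_points: int = 200

    def __post_init__(self):
        if not self.d_max > self.d_min > 0:
            raise ValueError("require d_max > d_min > 0")
        if self.n_points < 20:
            raise ValueError("need at least 20 sample points")

    @property
    def s_min(self) -> float:
        return 1.0 / (2.0 * self.d_max)

    @property
    def s_max(self) -> float:
        return 1.0 / (2.0 * self.d_min)

    def s_grid(self, n: int | None = None) -> np.ndarray:
        return np.linspace(self.s_min, self.s_max, n or self.n_points)


def _atomic_number(element: str) -> int:
    el = gemmi.Element(element.capitalize())
    if el.atomic_number == 0:
        raise UnsupportedElementError(f"unknown element symbol {element!r}")
    return el.atomic_number


def xray_form_factor(element: str, s) -> float | np.ndarray:
    """Neutral-atom X-ray form factor f_X(s) from the International Tables
    four-Gaussian coefficients (as distributed with gemmi).

    ``s`` is sin(theta)/lambda in 1/Angstrom; f_X(0) equals the electron count.
    """
    el = gemmi.Element(element.capitalize())
    if el.atomic_number == 0 or el.it92 is None:
        raise UnsupportedElementError(f"no X-ray form factor for {element!r}")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("s must be >= 0")
    coef = el.it92
    s2 = s_arr**2
    out = np.full_like(s2, coef.c, dtype=float)
    for ai, bi in zip(coef.a, coef.b):
        out = out + ai * np.exp(-bi * s2)
    if np.ndim(s) == 0:
        return float(out)
    return out


def mott_bethe(ion: IonSpec, s) -> float | np.ndarray:
    """Electron scattering factor of ``ion`` via the charge-offset Mott-Bethe
    formula.  Diverges at s=0 for charged species, so requires s > 0."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0):
        raise ValueError("mott_bethe requires s > 0 (divergent at s = 0)")
    fx = xray_form_factor(ion.element, s_arr)
    out = MOTT_BETHE_K * (ion.Z0 + ion.dZ - fx) / s_arr**2
    if np.ndim(s) == 0:
        return float(out)
    return out


def make_ion_pair(element: str, magnitude: int) -> tuple[IonSpec, IonSpec]:
    """Cation/anion pair with dZ = +/-magnitude, for sign-flip protocols."""
    if magnitude < 1:
        raise ValueError("charge magnitude must be >= 1")
    z0 = _atomic_number(element)
    return IonSpec(element, z0, +magnitude), IonSpec(element, z0, -magnitude)


@dataclass
class FitReport:
    max_abs: float
    rms: float
    max_rel: float
    max_rel_pointwise: float
    converged: bool = True


def _initial_guesses(ion: IonSpec, s: np.ndarray, target: np.ndarray):
    """Candidate starting vectors for the damped least-squares fit.

    First candidate: the element's published 5-Gaussian electron-scattering
    coefficients collapsed to four terms.  Further candidates: log-spaced
    Gaussian-width ladders with amplitudes and constant obtained by a linear
    solve (the model is linear in a_i and c for fixed b_i), which places one
    sharp Gaussian on the divergent low-s part of ionic curves.
    """
    guesses = []
    el = gemmi.Element(ion.element.capitalize())
    c43 = el.c4322
    if c43 is not None and all(math.isfinite(x) for x in c43.a):
        terms = sorted(zip(c43.a, c43.b), key=lambda t: -abs(t[0]))[:4]
        a = [t[0] for t in terms]
        b = [max(t[1], 1e-3) for t in terms]
        guesses.append(np.array([a[0], b[0], a[1], b[1], a[2], b[2], a[3], b[3], 0.0]))
    for ladder in (
        (0.8, 8.0, 80.0, 800.0),
        (0.3, 3.0, 30.0, 300.0),
        (1.5, 15.0, 150.0, 1500.0),
        (0.5, 2.0, 20.0, 200.0),
    ):
        b = np.array(ladder)
        design = np.column_stack(
            [np.exp(-bi * s**2) for bi in b] + [np.ones_like(s)]
        )
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        a = coef[:4]
        guesses.append(np.array([a[0], b[0], a[1], b[1], a[2], b[2], a[3], b[3], coef[4]]))
    return guesses


def fit_cromer_mann(
    ion: IonSpec,
    window: FitWindow = FitWindow(),
    max_iter: int = 20000,
) -> tuple[CromerMann9, FitReport]:
    """Fit the 9 Cromer-Mann coefficients to the Mott-Bethe curve of ``ion``
    over ``window`` by damped least squares with b_i >= 0 enforced.

    The report's ``max_rel`` is max|df| normalized by max|f| over the window:
    ionic curves pass through zero inside the window (the neutral form factor
    decays through Z0+dZ), so a pointwise |df/f| is unbounded at the crossing
    and is reported separately as ``max_rel_pointwise``.
    """
    s = window.s_grid()
    target = np.asarray(mott_bethe(ion, s))
    cm, success = fit_curve(s, target, _initial_guesses(ion, s, target),
                            max_iter=max_iter)
    # dense out-of-window-grid re-evaluation for the report
    s_dense = window.s_grid(max(4 * window.n_points, 800))
    f_ref = np.asarray(mott_bethe(ion, s_dense))
    df = cm.evaluate(s_dense) - f_ref
    scale = float(np.max(np.abs(f_ref)))
    report = FitReport(
        max_abs=float(np.max(np.abs(df))),
        rms=float(np.sqrt(np.mean(df**2))),
        max_rel=float(np.max(np.abs(df)) / scale),
        max_rel_pointwise=float(np.max(np.abs(df / f_ref))),
        converged=success,
    )
    if not success:
        raise FitFailureError(
            f"Cromer-Mann fit for {ion.label} did not converge",
            report.max_abs, report.max_rel,
        )
    return cm, report


def fit_curve(s: np.ndarray, target: np.ndarray,
              starts: list[np.ndarray] | None = None,
              max_iter: int = 20000) -> tuple[CromerMann9, bool]:
    """Fit the 9 coefficients to an arbitrary sampled curve; used by
    :func:`fit_cromer_mann` and directly when re-fitting parsed curves."""
    s = np.asarray(s, dtype=float)
    target = np.asarray(target, dtype=float)
    if starts is None:
        design_b = (0.8, 8.0, 80.0, 800.0)
        design = np.column_stack(
            [np.exp(-bi * s**2) for bi in design_b] + [np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        starts = [np.array([coef[0], design_b[0], coef[1], design_b[1],
                            coef[2], design_b[2], coef[3], design_b[3],
                            coef[4]])]

    def residual(p):
        a = p[0::2][:4]
        b = p[1::2][:4]
        model = p[8] + np.sum(
            a[:, None] * np.exp(-b[:, None] * s[None, :] ** 2), axis=0)
        return model - target

    lo = np.full(9, -np.inf)
    hi = np.full(9, np.inf)
    lo[1:8:2] = 0.0  # b_i >= 0
    best = None
    for x0 in starts:
        sol = least_squares(
            residual, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
            max_nfev=max_iter, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return CromerMann9.from_flat(best.x), bool(best.success)


# -- SFAC card text records --------------------------------------------------

def export_sfac_card(label: str, cm: CromerMann9, element: str | None = None,
                     dZ: int = 0) -> str:
    """One extended SFAC text record: label, element tag, charge offset, the
    nine coefficients in a1 b1 ... a4 b4 c order, then placeholder physical
    columns (f' f" mu r weight, all zero)."""
    if not label:
        raise ValueError("label must be non-empty")
    el = element or label
    nums = " ".join(f"{v:.6f}" for v in cm.as_flat())
    return f"SFAC {label} {el} {dZ:d} {nums} 0 0 0 0 0"


def parse_sfac_card(line: str) -> tuple[str, str, int, CromerMann9]:
    """Inverse of :func:`export_sfac_card`; returns (label, element, dZ, cm)."""
    tok = line.split()
    if not tok or tok[0].upper() != "SFAC":
        raise ValueError(f"not an SFAC record: {line!r}")
    if len(tok) < 13:
        raise ValueError(f"SFAC record too short: {line!r}")
    label, element, dz = tok[1], tok[2], int(tok[3])
    cm = CromerMann9.from_flat(tok[4:13])
    return label, element, dz, cm


class ScatteringLibrary:
    """Cache of fitted Cromer-Mann curves keyed by (element, dZ)."""

    def __init__(self, window: FitWindow = FitWindow()):
        self.window = window
        self._curves: dict[tuple[str, int], CromerMann9] = {}
        self._reports: dict[tuple[str, int], FitReport] = {}

    def get(self, ion: IonSpec) -> CromerMann9:
        key = (ion.element.capitalize(), ion.dZ)
        if key not in self._curves:
            cm, rep = fit_cromer_mann(ion, self.window)
            self._curves[key] = cm
            self._reports[key] = rep
        return self._curves[key]

    def put(self, ion: IonSpec, cm: CromerMann9) -> None:
        self._curves[(ion.element.capitalize(), ion.dZ)] = cm

    def report(self, ion: IonSpec) -> FitReport:
        self.get(ion)
        return self._reports[(ion.element.capitalize(), ion.dZ)]


def curve_table(ion: IonSpec, window: FitWindow = FitWindow(),
                n: int | None = None) -> np.ndarray:
    """Two-column (s, f) array of the Mott-Bethe curve for plotting/diagnostics."""
    s = window.s_grid(n)
    return np.column_stack([s, np.asarray(mott_bethe(ion, s))])
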