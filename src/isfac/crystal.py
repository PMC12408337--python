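"""Unit cell, symmetry, atom sites and reflection bookkeeping.

Geometry follows the usual crystallographic conventions: fractional
coordinates, the reciprocal metric tensor for d-spacings, and
``s = sin(theta)/lambda = 1/(2d)``.  Symmetry is supplied explicitly as
coordinate-triplet operator strings plus a lattice-centering code (SHELX
LATT convention: positive = centrosymmetric, |code| 1..7 = P, I, R, F, A,
B, C), not via space-group-symbol lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .scattering import IonSpec

_CENTERING_VECTORS = {
    1: [(0.0, 0.0, 0.0)],
    2: [(0.0, 0.0, 0.0), (0.5, 0.5, 0.5)],
    3: [(0.0, 0.0, 0.0), (2 / 3, 1 / 3, 1 / 3), (1 / 3, 2 / 3, 2 / 3)],
    4: [(0.0, 0.0, 0.0), (0.0, 0.5, 0.5), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0)],
    5: [(0.0, 0.0, 0.0), (0.0, 0.5, 0.5)],
    6: [(0.0, 0.0, 0.0), (0.5, 0.0, 0.5)],
    7: [(0.0, 0.0, 0.0), (0.5, 0.5, 0.0)],
}


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180) degrees")
        if self.to_gemmi().volume <= 0:
            raise ValueError("cell volume must be positive")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self.to_gemmi().volume

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """3x3 reciprocal metric tensor G* (1/Angstrom^2): d*^2 = h G* h."""
        frac = np.array(self.to_gemmi().frac.mat.tolist())  # fractionalization matrix
        return frac @ frac.T

    @property
    def orthogonalization(self) -> np.ndarray:
        """Fractional -> Cartesian (Angstrom) matrix."""
        return np.array(self.to_gemmi().orth.mat.tolist())

    def d_spacing(self, hkl) -> float:
        return self.to_gemmi().calculate_d(tuple(int(i) for i in hkl))


def s_magnitude(cell: UnitCell, hkl) -> float | np.ndarray:
    """|s| = sin(theta)/lambda = d*(hkl)/2 in 1/Angstrom; 0 for (0,0,0)."""
    h = np.atleast_2d(np.asarray(hkl, dtype=float))
    gstar = cell.reciprocal_metric
    dstar2 = np.einsum("ni,ij,nj->n", h, gstar, h)
    s = 0.5 * np.sqrt(dstar2)
    if np.ndim(hkl) == 1:
        return float(s[0])
    return s


@dataclass(frozen=True)
class SymmetryOp:
    """Rotation (integer 3x3) plus translation, acting on fractional coords."""

    rot: tuple
    tran: tuple

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        op = gemmi.Op(triplet.lower().replace(" ", ""))
        rot = np.array(op.rot) / op.DEN
        tran = (np.array(op.tran) / op.DEN) % 1.0
        if not np.allclose(rot, np.round(rot)):
            raise ValueError(f"non-integer rotation part in {triplet!r}")
        det = round(float(np.linalg.det(rot)))
        if det not in (1, -1):
            raise ValueError(f"operator determinant must be +/-1, got {det}")
        return cls(rot=tuple(map(tuple, np.round(rot).astype(int))),
                   tran=tuple(tran))

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls.from_triplet("x,y,z")

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    @property
    def tran_array(self) -> np.ndarray:
        return np.asarray(self.tran, dtype=float)

    def apply(self, xyz) -> np.ndarray:
        return (self.rot_array @ np.asarray(xyz, dtype=float) + self.tran_array) % 1.0

    def triplet(self) -> str:
        den = 12
        rot = np.round(self.rot_array * den).astype(int)
        tran = np.round(self.tran_array * den).astype(int)
        op = gemmi.Op()
        op.rot = [[int(v * op.DEN / den) for v in row] for row in rot]
        op.tran = [int(v * op.DEN / den) for v in tran]
        return op.triplet()


def full_symmetry_ops(ops: list[SymmetryOp], latt: int = -1) -> list[SymmetryOp]:
    """Expand the generator list by lattice centering and, for positive LATT
    codes, the inversion through the origin.  Identity is ensured."""
    base = [SymmetryOp.identity()]
    for op in ops:
        if op not in base:
            base.append(op)
    centro = latt > 0
    centering = _CENTERING_VECTORS[abs(latt)]
    out: list[SymmetryOp] = []
    seen = set()
    for op in base:
        variants = [(op.rot_array, op.tran_array)]
        if centro:
            variants.append((-op.rot_array, (-op.tran_array) % 1.0))
        for rot, tran in variants:
            for cv in centering:
                t = (tran + np.asarray(cv)) % 1.0
                key = (tuple(np.round(rot.ravel()).astype(int)),
                       tuple(np.round(t * 24).astype(int) % 24))
                if key in seen:
                    continue
                seen.add(key)
                out.append(SymmetryOp(rot=tuple(map(tuple, np.round(rot).astype(int))),
                                      tran=tuple(t)))
    return out


@dataclass
class AtomSite:
    """One crystallographically independent site.

    ``nu`` is the refined fraction of the ionic scattering factor; the partial
    charge is nu * dZ.  ``adp`` is either a scalar U_iso or a 6-vector
    (U11, U22, U33, U23, U13, U12), all in Angstrom^2.
    """

    label: str
    ion: IonSpec
    xyz: tuple[float, float, float]
    adp: float | tuple = 0.02
    occupancy: float = 1.0
    nu: float = 0.0
    is_hydrogen: bool = False
    nu_fixed: bool = False
    coordinates_fixed: bool = False
    adp_fixed: bool = False
    special_position: bool = False

    def __post_init__(self):
        if not 0 < self.occupancy <= 1:
            raise ValueError(f"occupancy of {self.label} must be in (0, 1]")
        if self.ion.element.capitalize() == "H":
            self.is_hydrogen = True

    @property
    def is_isotropic(self) -> bool:
        return np.isscalar(self.adp)

    @property
    def u_matrix(self) -> np.ndarray:
        """Symmetric U tensor; isotropic U is not converted (use adp directly)."""
        if self.is_isotropic:
            raise ValueError("site is isotropic")
        u11, u22, u33, u23, u13, u12 = self.adp
        return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])

    def copy(self) -> "AtomSite":
        return replace(self, xyz=tuple(self.xyz),
                       adp=self.adp if np.isscalar(self.adp) else tuple(self.adp))


@dataclass
class CrystalModel:
    cell: UnitCell
    sites: list[AtomSite]
    symmetry: list[SymmetryOp] = field(default_factory=lambda: [SymmetryOp.identity()])
    latt: int = -1  # SHELX convention; negative = non-centrosymmetric

    def all_ops(self) -> list[SymmetryOp]:
        return full_symmetry_ops(self.symmetry, self.latt)

    @property
    def is_centrosymmetric(self) -> bool:
        return self.latt > 0

    def copy(self) -> "CrystalModel":
        return CrystalModel(cell=self.cell, sites=[s.copy() for s in self.sites],
                            symmetry=list(self.symmetry), latt=self.latt)

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r}")


@dataclass
class ReflectionData:
    """Observed intensities with standard uncertainties, one row per unique hkl."""

    hkl: np.ndarray       # (n, 3) int
    i_obs: np.ndarray     # (n,)
    sigma: np.ndarray     # (n,)

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.i_obs = np.asarray(self.i_obs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma(I) must be positive")
        if len({tuple(h) for h in self.hkl}) != len(self.hkl):
            raise ValueError("duplicate reflection indices")

    def __len__(self) -> int:
        return len(self.i_obs)

    def s_values(self, cell: UnitCell) -> np.ndarray:
        return s_magnitude(cell, self.hkl)

    def select(self, mask) -> "ReflectionData":
        return ReflectionData(self.hkl[mask], self.i_obs[mask], self.sigma[mask])

    def resolution_cut(self, cell: UnitCell, d_min: float | None = None,
                       d_max: float | None = None) -> "ReflectionData":
        s = self.s_values(cell)
        mask = np.ones(len(self), dtype=bool)
        if d_min is not None:
            mask &= s <= 1.0 / (2.0 * d_min) + 1e-12
        if d_max is not None:
            mask &= s >= 1.0 / (2.0 * d_max) - 1e-12
        return self.select(mask)


def expand_to_p1(sites: list[AtomSite], ops: list[SymmetryOp],
                 cell: UnitCell | None = None,
                 merge_tol: float = 0.01) -> list[AtomSite]:
    """All symmetry images of ``sites`` with coordinates reduced into [0, 1).

    Images of the same site that coincide within ``merge_tol`` (Angstrom, when
    a cell is given; fractional otherwise) are merged — such sites sit on
    special positions and keep their stated occupancy on each distinct image.
    """
    if SymmetryOp.identity() not in ops:
        raise ValueError("operator list must include the identity")
    orth = cell.orthogonalization if cell is not None else np.eye(3)
    dstar = np.sqrt(np.diag(cell.reciprocal_metric)) if cell is not None else np.ones(3)
    out: list[AtomSite] = []
    for site in sites:
        images: list[list] = []  # [pos, op, dup_count]
        for op in ops:
            pos = op.apply(site.xyz)
            dup = False
            for entry in images:
                delta = (pos - entry[0] + 0.5) % 1.0 - 0.5
                if np.linalg.norm(orth @ delta) < merge_tol:
                    entry[2] += 1
                    dup = True
                    break
            if not dup:
                images.append([pos, op, 1])
        for i, (pos, op, count) in enumerate(images):
            img = site.copy()
            img.label = site.label if i == 0 else f"{site.label}#{i}"
            img.xyz = tuple(pos % 1.0)
            # merged duplicates mark a special position; the stated occupancy
            # is per symmetry copy (SHELX convention), so the single retained
            # image absorbs the multiplicity
            img.occupancy = min(site.occupancy * count, 1.0)
            img.special_position = count > 1
            if not np.isscalar(site.adp):
                img.adp = tuple(_transform_adp(site.adp, op, dstar))
            out.append(img)
    return out


def _transform_adp(adp6, op: SymmetryOp, dstar: np.ndarray) -> np.ndarray:
    """Rotate a reciprocal-basis-referenced U tensor (U11 U22 U33 U23 U13 U12)
    into the frame of a symmetry image so that the image reproduces the
    original site's Debye-Waller factor at the transformed index."""
    u11, u22, u33, u23, u13, u12 = adp6
    u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    d = np.diag(dstar)
    dinv = np.diag(1.0 / dstar)
    r = op.rot_array
    u_img = dinv @ r @ d @ u @ d @ r.T @ dinv
    return np.array([u_img[0, 0], u_img[1, 1], u_img[2, 2],
                     u_img[1, 2], u_img[0, 2], u_img[0, 1]])


def site_stabilizer(model: "CrystalModel", site: AtomSite,
                    tol: float = 0.01) -> list[SymmetryOp]:
    """Symmetry operators that map the site onto itself within ``tol``
    Angstrom; more than the identity means a special position."""
    orth = model.cell.orthogonalization
    out = []
    for op in model.all_ops():
        delta = (op.apply(site.xyz) - np.asarray(site.xyz) + 0.5) % 1.0 - 0.5
        if np.linalg.norm(orth @ delta) < tol:
            out.append(op)
    return out


def free_coordinate_mask(model: "CrystalModel", site: AtomSite) -> np.ndarray:
    """Which fractional coordinates of a site are refinable.

    The site-symmetry projector P = mean(R over the stabilizer) maps shifts
    onto the symmetry-allowed subspace; a component is fixed when its
    diagonal projector entry vanishes (axis-aligned constraint, e.g. a
    coordinate pinned on a mirror plane).  Non-axis-aligned constraints are
    left free (outside the supported symmetry scope).
    """
    ops = site_stabilizer(model, site)
    if len(ops) <= 1:
        return np.ones(3, dtype=bool)
    proj = np.mean([op.rot_array for op in ops], axis=0)
    mask = np.ones(3, dtype=bool)
    for m in range(3):
        off = sum(abs(proj[m, k]) for k in range(3) if k != m)
        if abs(proj[m, m]) < 1e-6 and off < 1e-6:
            mask[m] = False
    return mask


def _canonical_index(hkl: np.ndarray, rot_list: list[np.ndarray]) -> tuple:
    """Lexicographically largest equivalent index over ops and Friedel pair."""
    best = None
    for rot in rot_list:
        for sign in (1, -1):
            cand = tuple(int(round(v)) for v in sign * (hkl @ rot))
            if best is None or cand > best:
                best = cand
    return best


def unique_reflections(cell: UnitCell, ops: list[SymmetryOp], d_min: float,
                       d_max: float = float("inf"), latt: int = -1) -> np.ndarray:
    """One representative per symmetry-equivalence class (Friedel merged)
    with d_min <= d <= d_max; (0,0,0) excluded.  Systematically absent
    classes (phase-inconsistent under their own symmetry) are removed."""
    if not d_max > d_min:
        raise ValueError("d_max must exceed d_min")
    full = full_symmetry_ops(ops, latt)
    rot_list = [op.rot_array for op in full]
    # hkl search box from the reciprocal cell axes
    gstar = cell.reciprocal_metric
    s_max = 1.0 / (2.0 * d_min)
    lim = [int(np.floor(2.0 * s_max / np.sqrt(gstar[i, i]))) + 1 for i in range(3)]
    hh, kk, ll = np.meshgrid(np.arange(-lim[0], lim[0] + 1),
                             np.arange(-lim[1], lim[1] + 1),
                             np.arange(-lim[2], lim[2] + 1), indexing="ij")
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = s_magnitude(cell, hkl)
    sel = (s <= s_max + 1e-12)
    if np.isfinite(d_max):
        sel &= s >= 1.0 / (2.0 * d_max) - 1e-12
    hkl = hkl[sel]
    reps = set()
    for row in hkl:
        reps.add(_canonical_index(row, rot_list))
    out = [k for k in sorted(reps) if not _is_absent(np.asarray(k), full)]
    return np.array(out, dtype=int)


def _is_absent(hkl: np.ndarray, full_ops: list[SymmetryOp]) -> bool:
    """Systematic absence: some op maps hkl to itself with a non-integral
    phase shift h.t, forcing F = 0 for any atom content."""
    for op in full_ops:
        himg = hkl @ op.rot_array
        if np.allclose(himg, hkl):
            phase = float(hkl @ op.tran_array)
            if abs(phase - round(phase)) > 1e-9:
                return True
    return False
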