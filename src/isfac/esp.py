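"""Electrostatic-potential maps by Fourier synthesis, CUBE I/O, comparison.

For electron diffraction the structure factors are Fourier coefficients of
the crystal's electrostatic potential, so a map synthesized from them is an
experimental ESP on the (arbitrary) crystallographic scale:

    rho(r) = (1/V) * sum_hkl F(hkl) exp(-2 pi i h.x)

The s = 0 coefficient is ill-defined under ionic scattering factors (the
ionic Mott-Bethe curves diverge there), so F(000) must always be supplied
explicitly, typically taken from a conventional neutral-atom refinement.

Grids are compared with the Pearson coefficient after trilinear resampling
of one grid onto the other's points, because experimental and
quantum-chemical maps generally use different spacings and scales; Pearson
is invariant to the affine scale difference.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .crystal import CrystalModel, SymmetryOp, UnitCell, full_symmetry_ops
from .scattering import ScatteringLibrary
from .structure_factors import f_calc

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class MissingF000Error(ValueError):
    """Ionic scattering factors leave F(000) undefined; it must be overridden."""


@dataclass
class ESPGrid:
    """Scalar field on a regular 3D grid.

    ``origin`` is Cartesian (Angstrom); ``axes`` rows are the step vectors in
    Angstrom; ``values`` is indexed [i, j, k] along the three axes.
    """

    origin: np.ndarray
    axes: np.ndarray            # (3, 3), rows = step vectors
    values: np.ndarray          # (n1, n2, n3)
    atoms: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 points per axis")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("axis vectors must be linearly independent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def points(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates of all grid points."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx @ self.axes

    def statistics(self) -> dict[str, float]:
        v = self.values
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "sigma": float(v.std())}


def fourier_esp(model: CrystalModel, library: ScatteringLibrary | None,
                grid_dims: tuple[int, int, int], f000: float,
                hkl: np.ndarray | None = None,
                f_values: np.ndarray | None = None) -> ESPGrid:
    """Synthesize the potential map on a ``grid_dims`` grid over the unit
    cell from unique structure factors (computed from the model unless
    ``f_values`` for ``hkl`` are given).

    ``f000`` is mandatory: with ionic scattering factors the s = 0 term does
    not exist and must come from a conventional refinement.  The unique list
    is expanded over the symmetry operators and Friedel mates before the
    inverse Fourier transform, so the synthesized map is real.
    """
    if f000 is None:
        raise MissingF000Error("F(000) must be supplied explicitly")
    if hkl is None:
        raise ValueError("a reflection list is required")
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    if f_values is None:
        if library is None:
            raise ValueError("need a scattering library to compute F values")
        f_values = f_calc(model, library, hkl)
    f_values = np.asarray(f_values, dtype=complex)
    n1, n2, n3 = grid_dims
    ops = model.all_ops()
    hmax = np.max([np.max(np.abs(hkl @ op.rot_array), axis=0) for op in ops],
                  axis=0)
    needed = (2 * hmax + 1).astype(int)
    if n1 < needed[0] or n2 < needed[1] or n3 < needed[2]:
        raise ValueError(
            f"grid {grid_dims} too coarse for index range {tuple(hmax)}; "
            f"need at least {tuple(int(v) for v in needed)} to avoid aliasing")
    grid = np.zeros((n1, n2, n3), dtype=complex)
    filled: set[tuple[int, int, int]] = set()

    def put(h, F):
        key = (int(h[0]) % n1, int(h[1]) % n2, int(h[2]) % n3)
        if key not in filled:
            filled.add(key)
            grid[key] = F

    put((0, 0, 0), complex(f000))
    for row, F in zip(hkl, f_values):
        for op in ops:
            # F(h^T R) = exp(-2 pi i h.t) F(h) for symmetry op (R, t)
            himg = np.round(row @ op.rot_array).astype(int)
            shift = float(row @ op.tran_array)
            Fimg = F * np.exp(-2j * np.pi * shift)
            put(himg, Fimg)
            put(-himg, np.conj(Fimg))
    rho = np.fft.fftn(grid) / model.cell.volume
    imag_max = float(np.max(np.abs(rho.imag)))
    scale_ref = max(float(np.max(np.abs(rho.real))), 1e-300)
    if imag_max > 1e-6 * scale_ref:
        import warnings
        warnings.warn(f"synthesis not Friedel-complete (max imag {imag_max:g})")
    orth = model.cell.orthogonalization
    axes = (orth / np.array([n1, n2, n3])[None, :]).T
    return ESPGrid(origin=np.zeros(3), axes=axes, values=rho.real)


def default_grid_dims(cell: UnitCell, d_min: float,
                      points_per_element: int = 3) -> tuple[int, int, int]:
    """At least ``points_per_element`` grid points per minimum resolution
    element along each cell axis."""
    dims = []
    for length in (cell.a, cell.b, cell.c):
        dims.append(max(int(np.ceil(points_per_element * length / d_min)), 2))
    return tuple(dims)


# -- Gaussian CUBE format ----------------------------------------------------

def write_cube(grid: ESPGrid, comment: str = "ESP map") -> str:
    """Gaussian CUBE text: lengths in Bohr, z fastest-varying, six values
    per line."""
    buf = _io.StringIO()
    buf.write(f"{comment}\n")
    buf.write("generated by isfac\n")
    natoms = len(grid.atoms)
    o = grid.origin * BOHR_PER_ANGSTROM
    buf.write(f"{max(natoms, 1):5d} {o[0]:11.6f} {o[1]:11.6f} {o[2]:11.6f}\n")
    for n, axis in zip(grid.shape, grid.axes):
        v = axis * BOHR_PER_ANGSTROM
        buf.write(f"{n:5d} {v[0]:11.6f} {v[1]:11.6f} {v[2]:11.6f}\n")
    if natoms:
        for z, pos in grid.atoms:
            p = np.asarray(pos) * BOHR_PER_ANGSTROM
            buf.write(f"{z:5d} {float(z):11.6f} {p[0]:11.6f} {p[1]:11.6f} {p[2]:11.6f}\n")
    else:
        buf.write(f"{1:5d} {0.0:11.6f} {0.0:11.6f} {0.0:11.6f} {0.0:11.6f}\n")
    flat = grid.values.reshape(-1)  # C order: last axis fastest, as CUBE wants
    for start in range(0, len(flat), 6):
        chunk = flat[start:start + 6]
        buf.write(" ".join(f"{v:13.6E}" for v in chunk) + "\n")
    return buf.getvalue()


def read_cube(text: str) -> ESPGrid:
    """Parse a Gaussian CUBE file back into an :class:`ESPGrid`."""
    lines = text.splitlines()
    if len(lines) < 7:
        raise ValueError("CUBE file too short (line 1)")
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) / BOHR_PER_ANGSTROM
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed CUBE header at line 3: {exc}") from exc
    dims, axes = [], []
    for i in range(3):
        try:
            parts = lines[3 + i].split()
            dims.append(abs(int(parts[0])))
            axes.append([float(x) / BOHR_PER_ANGSTROM for x in parts[1:4]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed CUBE header at line {4 + i}: {exc}") from exc
    atoms = []
    for i in range(abs(natoms)):
        parts = lines[6 + i].split()
        atoms.append((int(parts[0]),
                      np.array([float(x) for x in parts[2:5]]) / BOHR_PER_ANGSTROM))
    data_lines = lines[6 + abs(natoms):]
    flat = []
    for ln in data_lines:
        flat.extend(float(x) for x in ln.split())
    n_expected = dims[0] * dims[1] * dims[2]
    if len(flat) < n_expected:
        raise ValueError(
            f"CUBE data truncated: {len(flat)} of {n_expected} values")
    values = np.array(flat[:n_expected]).reshape(dims)
    return ESPGrid(origin=origin, axes=np.array(axes), values=values,
                   atoms=atoms)


# -- grid comparison ---------------------------------------------------------

def grid_pearson(grid_a: ESPGrid, grid_b: ESPGrid,
                 mask_centers: np.ndarray | None = None,
                 mask_radius: float = 2.5) -> float:
    """Pearson coefficient between two fields over grid_a's points, with
    grid_b trilinearly resampled; points outside grid_b's support are
    excluded.  With ``mask_centers`` (Cartesian, Angstrom), only points
    within ``mask_radius`` of some center enter the comparison."""
    pts = grid_a.points()
    rel = pts - grid_b.origin
    frac_idx = rel @ np.linalg.inv(grid_b.axes)  # point -> fractional index
    shape = np.array(grid_b.shape)
    inside = np.all((frac_idx >= 0) & (frac_idx <= shape - 1), axis=1)
    if mask_centers is not None:
        centers = np.atleast_2d(mask_centers)
        d2 = np.min(np.sum((pts[:, None, :] - centers[None, :, :]) ** 2,
                           axis=2), axis=1)
        inside &= d2 <= mask_radius**2
    if not np.any(inside):
        raise ValueError("grids have no overlapping support")
    sampled = map_coordinates(grid_b.values, frac_idx[inside].T, order=1,
                              mode="nearest")
    ref = grid_a.values.reshape(-1)[inside]
    if np.ptp(ref) == 0 or np.ptp(sampled) == 0:
        raise ValueError("Pearson undefined: constant field in overlap")
    return float(np.corrcoef(ref, sampled)[0, 1])
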