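"""Shared fixtures: a session-wide scattering library (curve fits are the
expensive step, so they are cached once) and small reference crystals."""

import cmath

import numpy as np
import pytest

from isfac.crystal import (AtomSite, CrystalModel, SymmetryOp, UnitCell,
                           expand_to_p1)
from isfac.scattering import IonSpec, ScatteringLibrary
from isfac.structure_factors import debye_waller


@pytest.fixture(scope="session")
def library():
    return ScatteringLibrary()


@pytest.fixture()
def p21_model():
    """Two-atom model in P2(1) (unique axis b), monoclinic cell."""
    cell = UnitCell(6.0, 8.0, 10.0, 90.0, 97.0, 90.0)
    symm = [SymmetryOp.from_triplet(t) for t in ("x,y,z", "-x,y+1/2,-z")]
    sites = [
        AtomSite("C1", IonSpec.from_charge("C", -1), (0.15, 0.22, 0.31),
                 adp=0.02, nu=0.1),
        AtomSite("O1", IonSpec.from_charge("O", -1), (0.35, 0.40, 0.12),
                 adp=0.025, nu=0.3),
    ]
    return CrystalModel(cell, sites, symm, latt=-1)


@pytest.fixture()
def pnma_model():
    """Centrosymmetric Pnma-like framework with one special position."""
    cell = UnitCell(9.0, 6.0, 9.5)
    symm = [SymmetryOp.from_triplet(t) for t in
            ("x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z", "x+1/2,-y+1/2,-z+1/2")]
    sites = [
        AtomSite("SI1", IonSpec.from_charge("Si", 4), (0.185, 0.060, 0.210),
                 adp=0.010, nu=0.10),
        AtomSite("O1", IonSpec.from_charge("O", -1), (0.330, 0.130, 0.310),
                 adp=0.020, nu=0.20),
        AtomSite("O2", IonSpec.from_charge("O", -1), (0.105, 0.250, 0.095),
                 adp=0.020, nu=0.40, occupancy=0.5),
    ]
    return CrystalModel(cell, sites, symm, latt=1)


def brute_force_f(model, library, hkl):
    """Oracle: scalar-loop structure-factor sum over the expanded P1 cell.

    Independent of the vectorized engine: complex exponentials via cmath,
    explicit per-atom loop, same mixing rule.
    """
    p1_sites = expand_to_p1(model.sites, model.all_ops(), model.cell)
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    out = []
    for h in hkl:
        F = 0.0 + 0.0j
        for site in p1_sites:
            s = float(np.sqrt(
                h @ model.cell.reciprocal_metric @ h)) / 2.0
            if site.is_hydrogen:
                fmix = site.nu * library.get(IonSpec("H", 1, +1)).evaluate(s)
            else:
                f_neu = library.get(site.ion.neutral_partner()).evaluate(s)
                f_ion = (library.get(site.ion).evaluate(s)
                         if site.ion.dZ != 0 else f_neu)
                fmix = site.nu * f_ion + (1 - site.nu) * f_neu
            dw = debye_waller(site, h, model.cell)
            phase = cmath.exp(2j * cmath.pi * float(h @ np.asarray(site.xyz)))
            F += site.occupancy * fmix * dw * phase
        out.append(F)
    return np.array(out)


def plain_iam_f(model, library, hkl):
    """Oracle: conventional neutral-atom IAM sum (non-H only, nu ignored)."""
    neutral = model.copy()
    neutral.sites = [s.copy() for s in neutral.sites if not s.is_hydrogen]
    for s in neutral.sites:
        s.nu = 0.0
        s.ion = s.ion.neutral_partner()
    return brute_force_f(neutral, library, hkl)
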