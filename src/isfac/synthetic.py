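"""Ground-truth toy crystals and simulated noisy intensity datasets.

Every pipeline stage is testable without any experimental download: the
templates below provide a single neutral atom, an ionic pair, a zwitterionic
amino-acid-like molecule in P2(1)2(1)2(1) (separated NH3+/COO- charge
pattern, hydrogens present) and a centrosymmetric Pnma framework with
positively charged tetrahedral sites bridged by negatively charged oxygens.
True ionic fractions are stored on the sites; callers keep their own copy of
the truth before perturbing or refining.

The noise model is Gaussian on intensities with a multiplicative fraction
plus an additive floor, sigma_I = max(noise * I, floor), matching how
sigma(I) columns behave in integrated diffraction data at the crude level a
toy study needs.  Intensities are scaled so that the mean simulated I is
about 100; the default floor is one intensity unit at that scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .charges import ChargeSet, extract_charges
from .crystal import (AtomSite, CrystalModel, ReflectionData, SymmetryOp,
                      UnitCell, unique_reflections)
from .refine import (RefinementConfig, apply_parameters, refine_with_protocols)
from .scattering import IonSpec, ScatteringLibrary
from .structure_factors import f_calc

TEMPLATES = ("one-atom-P1", "ionic-pair-P1", "toy-zwitterion-P212121",
             "framework-Pnma")


@dataclass
class SyntheticSpec:
    template: str = "toy-zwitterion-P212121"
    d_min: float = 0.75
    d_max: float = 15.0
    completeness: float = 1.0
    noise: float = 0.02
    noise_floor: float = 1.0
    n_crystals: int = 1
    seed: int = 0
    target_mean_intensity: float = 100.0

    def __post_init__(self):
        if not 0 < self.completeness <= 1:
            raise ValueError("completeness must be in (0, 1]")
        if self.noise < 0:
            raise ValueError("noise fraction must be non-negative")

    def spec_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _ion(element: str, charge: int) -> IonSpec:
    return IonSpec.from_charge(element, charge)


def make_structure(spec: SyntheticSpec) -> tuple[CrystalModel, dict[str, float]]:
    """Template crystal plus the ground-truth charge per site label.

    The truth dict maps label -> delta_q (electrons); the model's sites carry
    the matching nu and ion assignment.  Total true charge is zero for every
    template.
    """
    if spec.template == "one-atom-P1":
        # P1 has a floating origin, so the single atom anchors it
        cell = UnitCell(6.0, 7.0, 8.0)
        sites = [AtomSite("C1", _ion("C", -1), (0.25, 0.30, 0.35),
                          adp=0.02, nu=0.0, coordinates_fixed=True)]
        model = CrystalModel(cell, sites, [SymmetryOp.identity()], latt=-1)
    elif spec.template == "ionic-pair-P1":
        # rock-salt-like pair; the arrangement is inversion-symmetric, so
        # both positions are stationary points and are kept fixed
        cell = UnitCell(5.0, 5.0, 5.0)
        sites = [
            AtomSite("NA1", _ion("Na", 1), (0.0, 0.0, 0.0), adp=0.015,
                     nu=0.5, coordinates_fixed=True),
            AtomSite("CL1", _ion("Cl", -1), (0.5, 0.5, 0.5), adp=0.018,
                     nu=0.5, coordinates_fixed=True),
        ]
        model = CrystalModel(cell, sites, [SymmetryOp.identity()], latt=-1)
    elif spec.template == "toy-zwitterion-P212121":
        model = _zwitterion_model()
    elif spec.template == "framework-Pnma":
        model = _framework_model()
    else:
        raise ValueError(f"unknown template {spec.template!r}")
    truth = {s.label: s.nu * s.ion.dZ for s in model.sites}
    assert abs(cell_charge(model)) < 1e-9
    return model, truth


def cell_charge(model: CrystalModel) -> float:
    """Total charge of the full unit cell: per-site delta_q weighted by
    occupancy and symmetry multiplicity (occupancy is per symmetry copy,
    so special positions are counted correctly)."""
    n_ops = len(model.all_ops())
    return float(sum(s.nu * s.ion.dZ * s.occupancy * n_ops
                     for s in model.sites))


def _zwitterion_model() -> CrystalModel:
    """Glycine-like zwitterion, five heavy atoms + five hydrogens, general
    positions of P2(1)2(1)2(1).  Bond lengths: N-C 1.47, C-C 1.52, C-O 1.25,
    N-H 1.01, C-H 1.09 Angstrom.  NH3+ protons carry +0.2e each, the
    carboxylate oxygens -0.35e each; totals cancel exactly."""
    cell = UnitCell(7.0, 9.0, 11.0)
    symm = [SymmetryOp.from_triplet(t) for t in
            ("x,y,z", "1/2-x,-y,1/2+z", "1/2+x,1/2-y,-z", "-x,1/2+y,1/2-z")]
    # Cartesian build, then fractionalize into the orthorhombic cell
    cart = {
        "N1": (0.000, 0.000, 0.000),
        "C1": (1.470, 0.000, 0.000),          # C-alpha
        "C2": (2.010, 1.420, 0.000),          # carboxyl C
        "O1": (1.350, 2.350, 0.480),
        "O2": (3.150, 1.640, -0.480),
        "H1": (-0.350, -0.500, 0.800),
        "H2": (-0.350, -0.450, -0.850),
        "H3": (-0.380, 0.940, 0.050),
        "H4": (1.830, -0.540, 0.870),
        "H5": (1.830, -0.510, -0.900),
    }
    charge = {"N1": ("N", -1, 0.45), "C1": ("C", -1, 0.05),
              "C2": ("C", +1, 0.35), "O1": ("O", -1, 0.35),
              "O2": ("O", -1, 0.35),
              "H1": ("H", +1, 0.20), "H2": ("H", +1, 0.20),
              "H3": ("H", +1, 0.20), "H4": ("H", +1, 0.10),
              "H5": ("H", +1, 0.15)}
    offset = np.array([1.8, 2.2, 4.5])
    abc = np.array([cell.a, cell.b, cell.c])
    sites = []
    for label, xyz in cart.items():
        el, dz, nu = charge[label]
        frac = (np.asarray(xyz) + offset) / abc
        adp = 0.04 if el == "H" else 0.02
        sites.append(AtomSite(label, _ion(el, dz), tuple(frac), adp=adp, nu=nu))
    return CrystalModel(cell, sites, symm, latt=-1)


def _framework_model() -> CrystalModel:
    """Pnma-like framework: a tetrahedral Si site (+0.4e) bridged by two
    oxygens, one on the y=1/4 mirror with half occupancy.  Charges cancel
    over the full cell: 8(+0.4) + 8(-0.2) + 4(-0.4) = 0."""
    cell = UnitCell(9.0, 6.0, 9.5)
    symm = [SymmetryOp.from_triplet(t) for t in
            ("x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z", "x+1/2,-y+1/2,-z+1/2")]
    sites = [
        AtomSite("SI1", _ion("Si", 4), (0.185, 0.060, 0.210),
                 adp=0.010, nu=0.10),
        AtomSite("O1", _ion("O", -1), (0.330, 0.130, 0.310),
                 adp=0.020, nu=0.20),
        AtomSite("O2", _ion("O", -1), (0.105, 0.250, 0.095),
                 adp=0.020, nu=0.40, occupancy=0.5),
    ]
    return CrystalModel(cell, sites, symm, latt=1)


def simulate_dataset(model: CrystalModel, spec: SyntheticSpec,
                     library: ScatteringLibrary,
                     replicate: int = 0) -> ReflectionData:
    """Unique reflections to d_min with kinematical intensities, seeded
    Gaussian noise and random completeness thinning.

    Replicates derive their seed from (spec.seed, replicate), so the same
    spec regenerates byte-identical data.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, replicate]))
    hkl = unique_reflections(model.cell, model.symmetry, spec.d_min,
                             spec.d_max, latt=model.latt)
    F = f_calc(model, library, hkl)
    i_true = np.abs(F) ** 2
    mean_i = float(np.mean(i_true))
    scale = spec.target_mean_intensity / mean_i if mean_i > 0 else 1.0
    i_true = scale * i_true
    sigma = np.maximum(spec.noise * i_true, spec.noise_floor)
    if spec.noise == 0:
        i_obs = i_true
        sigma = np.maximum(0.01 * np.sqrt(np.maximum(i_true, 1.0)), 1e-3)
    else:
        i_obs = i_true + rng.normal(0.0, sigma)
    if spec.completeness < 1.0:
        keep = rng.random(len(hkl)) < spec.completeness
        keep[np.argmax(i_true)] = True  # never lose the strongest reflection
        hkl, i_obs, sigma = hkl[keep], i_obs[keep], sigma[keep]
    return ReflectionData(hkl, i_obs, sigma)


def simulate_replicates(model: CrystalModel, spec: SyntheticSpec,
                        library: ScatteringLibrary) -> list[ReflectionData]:
    return [simulate_dataset(model, spec, library, replicate=i)
            for i in range(spec.n_crystals)]


def perturb_start(model: CrystalModel, rng: np.random.Generator,
                  coord_jitter: float = 0.02, nu_start: float = 0.1) -> None:
    """In-place perturbed refinement start: coordinates jittered by
    ``coord_jitter`` Angstrom, every free fraction reset to ``nu_start`` with
    the generating sign convention kept on the ion assignment."""
    from .crystal import free_coordinate_mask
    abc = np.array([model.cell.a, model.cell.b, model.cell.c])
    for site in model.sites:
        if not site.coordinates_fixed:
            # symmetry-pinned components (special positions) stay exact
            mask = free_coordinate_mask(model, site)
            frac_jitter = rng.normal(0.0, coord_jitter, 3) / abc * mask
            site.xyz = tuple((np.asarray(site.xyz) + frac_jitter) % 1.0)
        if not site.nu_fixed:
            site.nu = nu_start


@dataclass
class RecoveryReport:
    per_atom: dict[str, dict[str, float]]   # bias, rmse, coverage
    coverage: float                         # fraction of atom x seed cells
    n_replicates: int
    n_unconverged: int
    mean_esu: float
    seed: int
    spec_hash: str
    charge_sets: list[ChargeSet] = field(default_factory=list)


def recovery_experiment(spec: SyntheticSpec, config: RefinementConfig,
                        library: ScatteringLibrary,
                        n_replicates: int = 10) -> RecoveryReport:
    """Simulate -> perturb start -> refine (with protocols) -> compare with
    truth, over seeded replicates.  Coverage counts |dq - truth| <= 3 esu."""
    base_model, truth = make_structure(spec)
    labels = [s.label for s in base_model.sites if not s.nu_fixed]
    err = {lb: [] for lb in labels}
    cover = {lb: [] for lb in labels}
    esus = []
    n_unconverged = 0
    charge_sets = []
    for rep in range(n_replicates):
        model_rep, _ = make_structure(spec)
        data = simulate_dataset(model_rep, spec, library, replicate=rep)
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 7919, rep]))
        perturb_start(model_rep, rng)
        result = refine_with_protocols(model_rep, data, config, library)
        if not result.converged:
            n_unconverged += 1
            continue
        charges = extract_charges(result, model_rep,
                                  provenance=f"replicate-{rep}")
        charge_sets.append(charges)
        for lb in labels:
            dq, esu = charges.value(lb), charges.esu(lb)
            err[lb].append(dq - truth[lb])
            cover[lb].append(abs(dq - truth[lb]) <= 3.0 * esu)
            esus.append(esu)
    per_atom = {}
    for lb in labels:
        e = np.asarray(err[lb]) if err[lb] else np.array([np.nan])
        per_atom[lb] = {
            "truth": truth[lb],
            "bias": float(np.mean(e)),
            "rmse": float(np.sqrt(np.mean(e**2))),
            "coverage": float(np.mean(cover[lb])) if cover[lb] else float("nan"),
        }
    all_cells = [c for lb in labels for c in cover[lb]]
    return RecoveryReport(
        per_atom=per_atom,
        coverage=float(np.mean(all_cells)) if all_cells else float("nan"),
        n_replicates=n_replicates,
        n_unconverged=n_unconverged,
        mean_esu=float(np.mean(esus)) if esus else float("nan"),
        seed=spec.seed,
        spec_hash=spec.spec_hash(),
        charge_sets=charge_sets,
    )
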