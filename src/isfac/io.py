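"""Readers and writers for the toolkit's text formats.

Three formats matter: fixed-width HKLF-4 reflection lists (3I4 + 2F8.2 per
line, ``0 0 0`` terminator), an instruction-file dialect for the crystal
model and refinement settings, and CIF for final models.  The instruction
dialect is a documented subset of the familiar SHELX-style grammar with one
extension: SFAC cards carry an element tag and an integer charge offset, and
each atom's ionic fraction lives in an FVAR-style list (first value the
overall scale), so no two-pseudo-atom constraint bookkeeping is needed.

Records understood::

    TITL text                      title, passthrough
    CELL wl a b c alpha beta gamma
    ZERR ...                       ignored
    LATT n                        SHELX centering code (+ centrosymmetric)
    SYMM triplet                   e.g. SYMM 1/2-X, -Y, 1/2+Z
    SFAC label element dZ a1 b1 a2 b2 a3 b3 a4 b4 c  <5 placeholder cols>
    SHEL dmax dmin                 resolution cuts
    L.S. n                         cycle cap
    SUMP target sigma c1 m1 c2 m2 ...   (m = 2-based free-variable index)
    FVAR scale nu1 nu2 ...         one nu per atom, file order
    NFIX label [label ...]         nu fixed at its FVAR value
    XFIX label [label ...]         coordinates fixed (origin anchors etc.)
    FREEH 0|1                      riding vs freely refined hydrogens
    DFIX d sigma label1 label2     distance restraint
    REM text                       passthrough (REM OVERRIDEF000 x is parsed)
    atom records: label sfac# x y z occ U  (or U11 U22 U33 U23 U13 U12 with
                  '=' continuation), free whitespace
    HKLF 4 / END                   data format marker / terminator

All writers are deterministic: identical inputs give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import AtomSite, CrystalModel, ReflectionData, SymmetryOp, UnitCell
from .refine import (DistanceRestraint, RefinementConfig, RefinementResult,
                     SumpRestraint)
from .scattering import (CromerMann9, IonSpec, ScatteringLibrary,
                         export_sfac_card, parse_sfac_card)


class ParseError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# -- HKLF-4 reflections ------------------------------------------------------

def read_hkl(text: str) -> ReflectionData:
    """Fixed-width HKLF-4: columns 3I4 then 2F8; ``0 0 0`` ends the file;
    trailing batch columns are ignored."""
    hkl, i_obs, sigma = [], [], []
    saw_batch = False
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if len(line) < 28:
            # allow a short terminator line
            if line.split()[:3] == ["0", "0", "0"]:
                break
            raise ParseError(f"record shorter than 28 columns: {line!r}", ln)
        try:
            h = int(line[0:4])
            k = int(line[4:8])
            l = int(line[8:12])
            i = float(line[12:20])
            s = float(line[20:28])
        except ValueError as exc:
            raise ParseError(f"bad fixed-width fields: {exc}", ln) from exc
        if h == 0 and k == 0 and l == 0:
            break
        if len(line) > 28 and line[28:].strip():
            saw_batch = True
        hkl.append((h, k, l))
        i_obs.append(i)
        sigma.append(s)
    if not hkl:
        raise ParseError("no reflections found")
    data = ReflectionData(np.array(hkl), np.array(i_obs), np.array(sigma))
    if saw_batch:
        data.note = "trailing batch columns ignored"  # type: ignore[attr-defined]
    return data


def write_hkl(data: ReflectionData) -> str:
    lines = []
    for (h, k, l), i, s in zip(data.hkl, data.i_obs, data.sigma):
        lines.append(f"{h:4d}{k:4d}{l:4d}{i:8.2f}{s:8.2f}")
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    return "\n".join(lines) + "\n"


# -- instruction dialect -----------------------------------------------------

@dataclass
class InstructionDocument:
    model: CrystalModel
    config: RefinementConfig
    library: ScatteringLibrary
    scale: float = 1.0
    title: str = ""
    wavelength: float = 0.0251
    remarks: list[str] = field(default_factory=list)
    f000_override: float | None = None
    sfac_cards: list[tuple[str, str, int, CromerMann9]] = field(default_factory=list)


def read_instruction(text: str) -> InstructionDocument:
    """Parse the dialect into a model + config + fitted-curve library."""
    cell = None
    wavelength = 0.0251
    latt = -1
    symm: list[SymmetryOp] = []
    cards: list[tuple[str, str, int, CromerMann9]] = []
    atoms: list[dict] = []
    remarks: list[str] = []
    title = ""
    sump_raw = None
    fvar: list[float] | None = None
    nfix_labels: list[str] = []
    xfix_labels: list[str] = []
    free_h = True
    d_min = d_max = None
    cycles = 200
    f000 = None
    dfix: list[DistanceRestraint] = []

    lines = text.splitlines()
    # join '=' continuations
    joined: list[tuple[int, str]] = []
    pending = None
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if pending is not None:
            pending = (pending[0], pending[1].rstrip("=").rstrip() + " " + line.strip())
            if not line.rstrip().endswith("="):
                joined.append(pending)
                pending = None
            continue
        if line.rstrip().endswith("="):
            pending = (ln, line)
        else:
            joined.append((ln, line))
    if pending is not None:
        joined.append(pending)

    for ln, line in joined:
        stripped = line.strip()
        if not stripped:
            continue
        tok = stripped.split()
        key = tok[0].upper()
        try:
            if key == "TITL":
                title = stripped[4:].strip()
            elif key == "CELL":
                vals = [float(x) for x in tok[1:8]]
                if len(vals) != 7:
                    raise ParseError("CELL needs wavelength + 6 values", ln)
                wavelength = vals[0]
                cell = UnitCell(*vals[1:])
            elif key == "ZERR":
                pass
            elif key == "LATT":
                latt = int(tok[1])
            elif key == "SYMM":
                symm.append(SymmetryOp.from_triplet(stripped[4:].strip()))
            elif key == "SFAC":
                cards.append(parse_sfac_card(stripped))
            elif key == "SHEL":
                d_max, d_min = float(tok[1]), float(tok[2])
            elif key in ("L.S.", "LS"):
                cycles = int(tok[1])
            elif key == "SUMP":
                sump_raw = [float(x) for x in tok[1:]]
            elif key == "FVAR":
                fvar = [float(x) for x in tok[1:]]
            elif key == "NFIX":
                nfix_labels.extend(tok[1:])
            elif key == "XFIX":
                xfix_labels.extend(tok[1:])
            elif key == "FREEH":
                free_h = bool(int(tok[1]))
            elif key == "DFIX":
                dfix.append(DistanceRestraint(tok[3], tok[4],
                                              float(tok[1]), float(tok[2])))
            elif key == "REM":
                remarks.append(stripped[3:].strip())
                up = stripped.upper().split()
                if len(up) >= 3 and up[1] == "OVERRIDEF000":
                    f000 = float(up[2])
            elif key in ("HKLF", "END", "UNIT", "WGHT"):
                pass
            else:
                # atom record: label sfac# x y z occ U...
                if len(tok) < 7:
                    raise ParseError(f"unrecognized record {key!r}", ln)
                atoms.append({
                    "line": ln, "label": tok[0], "sfac": int(tok[1]),
                    "x": float(tok[2]), "y": float(tok[3]), "z": float(tok[4]),
                    "occ": float(tok[5]), "u": [float(x) for x in tok[6:12]],
                })
        except ParseError:
            raise
        except (ValueError, IndexError) as exc:
            raise ParseError(f"cannot parse record {stripped!r}: {exc}", ln) from exc

    if cell is None:
        raise ParseError("mandatory CELL record missing")
    if not cards:
        raise ParseError("at least one SFAC card is required")
    if not atoms:
        raise ParseError("at least one atom record is required")

    library = ScatteringLibrary()
    ions: list[IonSpec] = []
    for label, element, dz, cm in cards:
        ion = IonSpec.from_charge(element, dz)
        library.put(ion, cm)
        ions.append(ion)

    sites: list[AtomSite] = []
    for rec in atoms:
        idx = rec["sfac"]
        if not 1 <= idx <= len(ions):
            raise ParseError(
                f"atom {rec['label']!r} references SFAC {idx} "
                f"but only {len(ions)} cards exist", rec["line"])
        u = rec["u"]
        adp = u[0] if len(u) < 6 else tuple(u[:6])
        sites.append(AtomSite(
            label=rec["label"], ion=ions[idx - 1],
            xyz=(rec["x"], rec["y"], rec["z"]),
            adp=adp, occupancy=rec["occ"]))

    scale = 1.0
    if fvar:
        scale = fvar[0]
        for site, nu in zip(sites, fvar[1:]):
            site.nu = nu
    for record, labels, attr in (("NFIX", nfix_labels, "nu_fixed"),
                                 ("XFIX", xfix_labels, "coordinates_fixed")):
        for lb in labels:
            matched = [s for s in sites if s.label == lb]
            if not matched:
                raise ParseError(f"{record} references unknown atom {lb!r}")
            setattr(matched[0], attr, True)

    sump = None
    if sump_raw is not None:
        target, sigma = sump_raw[0], sump_raw[1]
        coeffs: dict[str, float] = {}
        pairs = sump_raw[2:]
        if len(pairs) % 2:
            raise ParseError("SUMP needs coefficient/fv-number pairs")
        for c, m in zip(pairs[0::2], pairs[1::2]):
            slot = int(m) - 2  # fv 1 is the scale; fv 2 is the first atom
            if not 0 <= slot < len(sites):
                raise ParseError(f"SUMP references free variable {int(m)} "
                                 f"but only {len(sites)} atoms exist")
            coeffs[sites[slot].label] = float(c)
        sump = SumpRestraint(target=target, sigma=sigma, coefficients=coeffs)

    config = RefinementConfig(
        max_cycles=cycles, sump=sump, distance_restraints=dfix,
        d_min=d_min, d_max=d_max, free_hydrogens=free_h)
    model = CrystalModel(cell=cell, sites=sites, symmetry=symm or
                         [SymmetryOp.identity()], latt=latt)
    return InstructionDocument(
        model=model, config=config, library=library, scale=scale,
        title=title, wavelength=wavelength, remarks=remarks,
        f000_override=f000, sfac_cards=cards)


def write_instruction(doc: InstructionDocument) -> str:
    model, config = doc.model, doc.config
    out = []
    if doc.title:
        out.append(f"TITL {doc.title}")
    c = model.cell
    out.append(f"CELL {doc.wavelength:.5f} {c.a:.4f} {c.b:.4f} {c.c:.4f} "
               f"{c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}")
    out.append(f"LATT {model.latt}")
    for op in model.symmetry:
        trip = op.triplet().upper()
        if trip != "X,Y,Z":
            out.append(f"SYMM {trip}")
    card_index: dict[tuple[str, int], int] = {}
    for i, (label, element, dz, cm) in enumerate(doc.sfac_cards, start=1):
        card_index[(element.capitalize(), dz)] = i
        out.append(export_sfac_card(label, cm, element, dz))
    for rem in doc.remarks:
        out.append(f"REM {rem}")
    if doc.f000_override is not None and not any(
            "OVERRIDEF000" in r.upper() for r in doc.remarks):
        out.append(f"REM OVERRIDEF000 {doc.f000_override:.2f}")
    if config.d_min is not None and config.d_max is not None:
        out.append(f"SHEL {config.d_max:.2f} {config.d_min:.2f}")
    out.append(f"L.S. {config.max_cycles}")
    out.append(f"FREEH {int(config.free_hydrogens)}")
    for r in config.distance_restraints:
        out.append(f"DFIX {r.target:.4f} {r.sigma:.4f} {r.label_a} {r.label_b}")
    if config.sump is not None:
        terms = []
        for i, site in enumerate(model.sites):
            if site.nu_fixed:
                continue
            coeff = config.sump.coefficient(site)
            terms.append(f"{coeff:g} {i + 2}")
        out.append(f"SUMP {config.sump.target:g} {config.sump.sigma:g} "
                   + " ".join(terms))
    fvar = [f"{doc.scale:.5f}"] + [f"{s.nu:.5f}" for s in model.sites]
    out.append("FVAR " + " ".join(fvar))
    nfixed = [s.label for s in model.sites if s.nu_fixed]
    if nfixed:
        out.append("NFIX " + " ".join(nfixed))
    xfixed = [s.label for s in model.sites if s.coordinates_fixed]
    if xfixed:
        out.append("XFIX " + " ".join(xfixed))
    for site in model.sites:
        key = (site.ion.element.capitalize(), site.ion.dZ)
        if key not in card_index:
            raise ValueError(f"no SFAC card for site {site.label!r} "
                             f"({key[0]}, dZ={key[1]})")
        x, y, z = site.xyz
        head = (f"{site.label} {card_index[key]} {x:.6f} {y:.6f} {z:.6f} "
                f"{site.occupancy:.4f}")
        if site.is_isotropic:
            out.append(f"{head} {float(site.adp):.5f}")
        else:
            u = site.adp
            out.append(f"{head} {u[0]:.5f} {u[1]:.5f} =")
            out.append(f"   {u[2]:.5f} {u[3]:.5f} {u[4]:.5f} {u[5]:.5f}")
    out.append("HKLF 4")
    out.append("END")
    return "\n".join(out) + "\n"


def document_for_model(model: CrystalModel, config: RefinementConfig,
                       library: ScatteringLibrary, scale: float = 1.0,
                       title: str = "", f000: float | None = None,
                       ) -> InstructionDocument:
    """Build a writable document from in-memory objects, fitting any curves
    the sites need that the library has not produced yet."""
    cards = []
    seen: set[tuple[str, int]] = set()

    def add(ion: IonSpec):
        key = (ion.element.capitalize(), ion.dZ)
        if key not in seen:
            seen.add(key)
            cards.append((ion.label, ion.element, ion.dZ, library.get(ion)))

    for site in model.sites:
        if site.is_hydrogen:
            add(IonSpec("H", 1, +1))
        else:
            add(site.ion.neutral_partner())
            if site.ion.dZ != 0:
                add(site.ion)
    return InstructionDocument(model=model, config=config, library=library,
                               scale=scale, title=title, f000_override=f000,
                               sfac_cards=cards)


# -- CIF output --------------------------------------------------------------

def write_cif(model: CrystalModel, result: RefinementResult,
              data_name: str = "isfac") -> str:
    """Deposition-style CIF with a custom loop for the refined charges."""
    c = model.cell
    out = [f"data_{data_name}"]
    out.append(f"_cell_length_a    {c.a:.4f}")
    out.append(f"_cell_length_b    {c.b:.4f}")
    out.append(f"_cell_length_c    {c.c:.4f}")
    out.append(f"_cell_angle_alpha {c.alpha:.4f}")
    out.append(f"_cell_angle_beta  {c.beta:.4f}")
    out.append(f"_cell_angle_gamma {c.gamma:.4f}")
    out.append(f"_cell_volume      {c.volume:.4f}")
    out.append("loop_")
    out.append("_space_group_symop_operation_xyz")
    for op in model.all_ops():
        out.append(f"  '{op.triplet()}'")
    out.append("loop_")
    out.append("_atom_site_label")
    out.append("_atom_site_type_symbol")
    out.append("_atom_site_fract_x")
    out.append("_atom_site_fract_y")
    out.append("_atom_site_fract_z")
    out.append("_atom_site_occupancy")
    out.append("_atom_site_U_iso_or_equiv")
    for s in model.sites:
        u_eq = float(s.adp) if s.is_isotropic else float(np.mean(s.adp[:3]))
        x, y, z = s.xyz
        out.append(f"  {s.label} {s.ion.element} {x:.6f} {y:.6f} {z:.6f} "
                   f"{s.occupancy:.4f} {u_eq:.5f}")
    aniso = [s for s in model.sites if not s.is_isotropic]
    if aniso:
        out.append("loop_")
        out.append("_atom_site_aniso_label")
        for tag in ("11", "22", "33", "23", "13", "12"):
            out.append(f"_atom_site_aniso_U_{tag}")
        for s in aniso:
            u = s.adp
            out.append(f"  {s.label} " + " ".join(f"{v:.5f}" for v in u))
    out.append("loop_")
    out.append("_isfac_charge_label")
    out.append("_isfac_charge_delta_Z")
    out.append("_isfac_charge_nu")
    out.append("_isfac_charge_dq")
    out.append("_isfac_charge_esu")
    for s in model.sites:
        if s.nu_fixed:
            nu, esu = s.nu, 0.0
        else:
            nu = result.nu(s.label)
            esu = result.nu_esd(s.label)
        out.append(f"  {s.label} {s.ion.dZ} {nu:.5f} {nu * s.ion.dZ:.5f} "
                   f"{esu * abs(s.ion.dZ):.5f}")
    out.append(f"_refine_ls_R_factor_all        {result.r1:.5f}")
    out.append(f"_refine_ls_wR_factor_ref       {result.wr2:.5f}")
    if result.goof is not None:
        out.append(f"_refine_ls_goodness_of_fit_ref {result.goof:.4f}")
    out.append(f"_refine_ls_number_reflns       {result.n_data}")
    out.append(f"_refine_ls_number_parameters   {result.n_params}")
    return "\n".join(out) + "\n"
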